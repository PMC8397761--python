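"""Count normalization, absolute-abundance scaling and alpha diversity.

Sequencing counts are compositional: library size and community-wide
abundance shifts are confounded with per-genus signal. Two complementary
rescalings are provided:

* **median-of-ratios size factors** (the DESeq normalization): per sample,
  the median ratio of its counts to the per-genus geometric means — robust
  to a minority of changing genera, removing both depth and community-wide
  compositional shifts;
* **absolute-abundance scaling**: relative abundances multiplied by the
  sample's total 16S cDNA copies per gram from qPCR, turning proportions
  into activity-weighted copy numbers.

Alpha diversity is summarised by the Shannon entropy (nats by default) and
the bias-corrected Chao1 richness estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .core_data import CountTable, QpcrTable

__all__ = [
    "SizeFactors",
    "AbundanceMatrix",
    "size_factors_median_of_ratios",
    "normalize_counts",
    "absolute_abundance",
    "relative_abundance",
    "shannon_index",
    "chao1_index",
]


class Scale(str, Enum):
    normalized_counts = "normalized_counts"
    relative = "relative"
    absolute_copies = "absolute_copies"


@dataclass
class SizeFactors:
    """Per-sample size factors, rescaled to geometric mean 1."""

    sample_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class AbundanceMatrix:
    """Real-valued abundances, samples × genera, tagged with their scale."""

    sample_ids: list[str]
    genus_ids: list[str]
    values: np.ndarray
    scale: Scale

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scale = Scale(self.scale)
        if self.values.shape != (len(self.sample_ids), len(self.genus_ids)):
            raise ValueError("values shape does not match ids")
        if (self.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.scale is Scale.relative:
            rs = self.values.sum(axis=1)
            if not np.allclose(rs, 1.0, atol=1e-9):
                raise ValueError("relative-scale rows must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)


def size_factors_median_of_ratios(
    counts: CountTable, pseudocount: float = 0.0
) -> SizeFactors:
    """Median-of-ratios size factors.

    Per sample j: factor_j = median over reference genera g of
    counts[j,g] / geomean_g, where the reference set is every genus with a
    positive count in all samples (positive geometric mean). Factors are
    rescaled to geometric mean 1. If no genus is present in every sample
    the reference is empty; pass ``pseudocount=1`` to compute factors on
    counts + 1 instead.
    """
    mat = counts.counts.astype(float)
    if pseudocount:
        mat = mat + pseudocount
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    reference = np.isfinite(logmat).all(axis=0)
    if not reference.any():
        raise ValueError(
            "no genus has nonzero counts in every sample; the median-of-ratios "
            "reference is empty — rerun with pseudocount=1"
        )
    geomean = np.exp(logmat[:, reference].mean(axis=0))
    ratios = mat[:, reference] / geomean
    factors = np.median(ratios, axis=1)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return SizeFactors(list(counts.sample_ids), factors)


def normalize_counts(counts: CountTable, factors: SizeFactors | None = None) -> AbundanceMatrix:
    """Counts divided by their sample's size factor (DESeq-style)."""
    if factors is None:
        factors = size_factors_median_of_ratios(counts)
    if factors.sample_ids != counts.sample_ids:
        raise ValueError("size-factor sample ids do not match count table")
    values = counts.counts / factors.factors[:, None]
    return AbundanceMatrix(
        list(counts.sample_ids), list(counts.genus_ids), values, Scale.normalized_counts
    )


def relative_abundance(counts: CountTable) -> AbundanceMatrix:
    rs = counts.counts.sum(axis=1, keepdims=True).astype(float)
    return AbundanceMatrix(
        list(counts.sample_ids), list(counts.genus_ids), counts.counts / rs, Scale.relative
    )


def absolute_abundance(counts: CountTable, qpcr: QpcrTable) -> AbundanceMatrix:
    """Rescale each sample's relative abundances to its qPCR 16S total.

    value[j, g] = (counts[j, g] / rowsum_j) × copies_per_g_j, so output row
    sums equal the qPCR totals exactly.
    """
    totals = qpcr.as_series()
    missing = [s for s in counts.sample_ids if s not in totals.index]
    if missing:
        raise ValueError(f"samples without qPCR totals: {missing}")
    rowsums = counts.counts.sum(axis=1).astype(float)
    if (rowsums == 0).any():
        raise ValueError("zero row sum; cannot form relative abundances")
    t = totals.loc[list(counts.sample_ids)].to_numpy()
    values = counts.counts / rowsums[:, None] * t[:, None]
    return AbundanceMatrix(
        list(counts.sample_ids), list(counts.genus_ids), values, Scale.absolute_copies
    )


def shannon_index(abundances: Sequence[float], base: float | None = None) -> float:
    """Shannon entropy H = −Σ p ln p of one sample's abundances.

    Natural log by default; pass ``base=2`` for bits. Zeros are dropped
    (0·ln 0 = 0); an all-zero sample is an error.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1_index(counts: Sequence[float], bias_corrected: bool = True) -> float:
    """Chao1 richness from one sample's integer counts.

    Bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) by default (finite when
    there are no doubletons); classical form S_obs + F1²/(2 F2) with
    ``bias_corrected=False``. Undefined on normalized (non-integer) values.
    """
    x = np.asarray(counts, dtype=float)
    if not np.allclose(x, np.rint(x), rtol=0, atol=1e-9):
        raise ValueError("Chao1 requires integer counts, not normalized abundances")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    x = np.rint(x).astype(np.int64)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        # classical form diverges; fall back to the bias-corrected estimate
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)
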