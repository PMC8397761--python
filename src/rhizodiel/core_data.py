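"""Domain types, validation and I/O for diel microbial community datasets.

The central container is a :class:`CountTable` — an integer matrix of
amplicon (16S cDNA) read counts with samples in rows and genera in columns —
accompanied by per-sample design metadata (light regime, soil compartment,
time point, diel phase, replicate), a qPCR table of total 16S copy numbers
per gram of soil, and an optional taxonomy table carrying phylum and
oxygen-requirement annotations.

Orientation is part of the format contract: TSV tables have sample ids in
the first column and genus ids in the header row; BIOM 2.x tables (HDF5,
observations × samples on disk) are transposed to samples × genera on read.
No orientation auto-detection is attempted — silent transposition is a
classic microbiome bug.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountTable",
    "SampleMetadata",
    "QpcrTable",
    "TaxonomyTable",
    "ValidationReport",
    "REGIMES",
    "COMPARTMENTS",
    "PHASES",
    "OXYGEN_CLASSES",
    "phase_of_timepoint",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_qpcr",
    "write_qpcr",
    "read_taxonomy",
    "write_taxonomy",
    "metadata_to_frame",
    "validate_dataset",
    "collapse_otu_to_genus",
]

REGIMES = ("LD", "DD")
COMPARTMENTS = ("rhizosphere", "bulk")
PHASES = ("AM", "PM")
OXYGEN_CLASSES = ("obligate_aerobe", "obligate_anaerobe", "facultative", "unknown")


def phase_of_timepoint(timepoint: int) -> str:
    """Diel phase implied by a 1-based time point under the default design.

    Harvests alternate every 12 h starting at 8 am, so odd time points are
    AM (end of dark) and even time points are PM (end of light).
    """
    return "AM" if timepoint % 2 == 1 else "PM"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Integer read counts, samples × genera.

    Invariants (enforced on construction): unique sample and genus ids, all
    entries non-negative integers, at least 2 samples and 2 genera, and a
    positive row sum for every sample.
    """

    sample_ids: list[str]
    genus_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.genus_ids = [str(g) for g in self.genus_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got ndim={counts.ndim}")
        if counts.shape != (len(self.sample_ids), len(self.genus_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.genus_ids)} genera"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, rtol=0, atol=1e-9):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.genus_ids)) != len(self.genus_ids):
            raise ValueError("duplicate genus ids")
        if len(self.sample_ids) < 2 or len(self.genus_ids) < 2:
            raise ValueError("need at least 2 samples and 2 genera")
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"genus {self.genus_ids[bad[1]]!r}"
            )
        rowsums = self.counts.sum(axis=1)
        if (rowsums == 0).any():
            empty = [s for s, r in zip(self.sample_ids, rowsums) if r == 0]
            raise ValueError(f"samples with zero total counts: {empty}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.genus_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(sample_ids), list(self.genus_ids), self.counts[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.genus_ids == other.genus_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Design labels for one sample."""

    sample_id: str
    regime: str
    compartment: str
    timepoint: int
    phase: str
    replicate: int

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.timepoint < 1:
            raise ValueError("timepoint must be ≥ 1")
        if self.replicate < 1:
            raise ValueError("replicate must be ≥ 1")
        if self.phase != phase_of_timepoint(self.timepoint):
            raise ValueError(
                f"sample {self.sample_id!r}: phase {self.phase} inconsistent with "
                f"timepoint {self.timepoint} (expected {phase_of_timepoint(self.timepoint)})"
            )


@dataclass
class QpcrTable:
    """Total 16S cDNA copies per gram of dry soil, one row per sample."""

    sample_ids: list[str]
    copies_per_g: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.copies_per_g = np.asarray(self.copies_per_g, dtype=float)
        if len(self.sample_ids) != len(self.copies_per_g):
            raise ValueError("sample_ids and copies_per_g length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in qPCR table")
        if not (self.copies_per_g > 0).all():
            raise ValueError("copies_per_g must be positive")

    def as_series(self) -> pd.Series:
        return pd.Series(self.copies_per_g, index=self.sample_ids, name="copies_per_g")


@dataclass
class TaxonomyTable:
    """Genus → phylum and oxygen-requirement class annotations.

    Genera missing from the table are reported as oxygen_class ``unknown``
    rather than raising — annotations are routinely incomplete.
    """

    genus_ids: list[str]
    phylum: list[str]
    oxygen_class: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genus_ids)) != len(self.genus_ids):
            raise ValueError("duplicate genus ids in taxonomy table")
        if not (len(self.genus_ids) == len(self.phylum) == len(self.oxygen_class)):
            raise ValueError("taxonomy column length mismatch")
        for oc in self.oxygen_class:
            if oc not in OXYGEN_CLASSES:
                raise ValueError(f"unknown oxygen class {oc!r}")

    def oxygen_class_of(self, genus_id: str) -> str:
        try:
            return self.oxygen_class[self.genus_ids.index(genus_id)]
        except ValueError:
            return "unknown"


@dataclass
class ValidationReport:
    """Cross-reference report for a (counts, metadata, qPCR) triple."""

    ok: bool
    missing_metadata: list[str] = field(default_factory=list)
    extra_metadata: list[str] = field(default_factory=list)
    missing_qpcr: list[str] = field(default_factory=list)
    extra_qpcr: list[str] = field(default_factory=list)
    duplicate_metadata: list[str] = field(default_factory=list)
    replicate_counts: pd.DataFrame | None = None
    imbalanced_cells: list[tuple] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# count-table I/O
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a count table from TSV or BIOM 2.x.

    TSV: UTF-8, tab-separated, first column sample ids, header row genus
    ids, lines starting with ``#`` skipped. BIOM: HDF5 per the 2.x layout,
    transposed on read so samples are in rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_count_tsv(path)
    if format == "biom":
        return _read_count_biom(path)
    raise ValueError(f"format must be 'tsv' or 'biom', got {format!r}")


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        table.to_frame().to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom":
        _write_count_biom(table, path)
    else:
        raise ValueError(f"format must be 'tsv' or 'biom', got {format!r}")


def _read_count_tsv(path: Path) -> CountTable:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse {path} as TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no genus columns found")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer entry {raw!r} at row "
                    f"{df.index[i]!r}, column {col!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: negative entry {v} at row {df.index[i]!r}, column {col!r}"
                )
            values[i, j] = v
    return CountTable(list(df.index), list(df.columns), values)


_BIOM_URL = "http://biom-format.org"


def _read_count_biom(path: Path) -> CountTable:
    with h5py.File(path, "r") as h5:
        for key in ("observation/ids", "sample/ids", "observation/matrix/data"):
            if key not in h5:
                raise ValueError(f"{path}: not a BIOM 2.x file (missing {key})")
        obs_ids = [_as_str(x) for x in h5["observation/ids"][:]]
        sample_ids = [_as_str(x) for x in h5["sample/ids"][:]]
        shape = tuple(int(x) for x in h5.attrs["shape"])
        mat = sp.csr_matrix(
            (
                h5["observation/matrix/data"][:],
                h5["observation/matrix/indices"][:],
                h5["observation/matrix/indptr"][:],
            ),
            shape=shape,
        )
    dense = np.asarray(mat.todense())
    if not np.allclose(dense, np.rint(dense)):
        raise ValueError(f"{path}: BIOM matrix has non-integer entries")
    # on-disk orientation is observations (genera) × samples
    return CountTable(sample_ids, obs_ids, dense.T.astype(np.int64))


def _write_count_biom(table: CountTable, path: Path) -> None:
    obs_matrix = sp.csr_matrix(table.counts.T.astype(float))  # genera × samples
    sample_matrix = sp.csr_matrix(table.counts.astype(float))  # samples × genera
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = _BIOM_URL
        h5.attrs["format-version"] = (2, 1)
        h5.attrs["generated-by"] = "rhizodiel"
        h5.attrs["creation-date"] = datetime.datetime.now().isoformat()
        h5.attrs["shape"] = obs_matrix.shape
        h5.attrs["nnz"] = int(obs_matrix.nnz)
        str_dt = h5py.string_dtype(encoding="utf-8")
        h5.create_dataset("observation/ids", data=table.genus_ids, dtype=str_dt)
        h5.create_dataset("sample/ids", data=table.sample_ids, dtype=str_dt)
        for group, mat in (("observation", obs_matrix), ("sample", sample_matrix)):
            h5.create_dataset(f"{group}/matrix/data", data=mat.data.astype(float))
            h5.create_dataset(f"{group}/matrix/indices", data=mat.indices.astype(np.int64))
            h5.create_dataset(f"{group}/matrix/indptr", data=mat.indptr.astype(np.int64))
            for sub in ("metadata", "group-metadata"):
                h5.create_group(f"{group}/{sub}")


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


# ---------------------------------------------------------------------------
# metadata / qPCR / taxonomy I/O (plain TSV, deterministic column order)
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "regime", "compartment", "timepoint", "phase", "replicate"]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return [
        SampleMetadata(
            sample_id=row.sample_id,
            regime=row.regime,
            compartment=row.compartment,
            timepoint=int(row.timepoint),
            phase=row.phase,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_metadata(meta: Iterable[SampleMetadata], path: str | Path) -> None:
    metadata_to_frame(meta).to_csv(path, sep="\t", index=False, columns=_META_COLS)


def metadata_to_frame(meta: Iterable[SampleMetadata] | pd.DataFrame) -> pd.DataFrame:
    """Collection of metadata rows as a DataFrame indexed like the input order."""
    if isinstance(meta, pd.DataFrame):
        return meta
    return pd.DataFrame([m.__dict__ for m in meta], columns=_META_COLS)


def read_qpcr(path: str | Path) -> QpcrTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample_id", "copies_per_g"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, copies_per_g")
    return QpcrTable(list(df["sample_id"].astype(str)), df["copies_per_g"].to_numpy(float))


def write_qpcr(qpcr: QpcrTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": qpcr.sample_ids, "copies_per_g": qpcr.copies_per_g}
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "genus_id" not in df.columns:
        raise ValueError(f"{path}: expected a genus_id column")
    phylum = df.get("phylum", pd.Series(["unknown"] * len(df))).fillna("unknown")
    oxy = df.get("oxygen_class", pd.Series(["unknown"] * len(df))).fillna("unknown")
    return TaxonomyTable(list(df["genus_id"]), list(phylum), list(oxy))


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    pd.DataFrame(
        {"genus_id": tax.genus_ids, "phylum": tax.phylum, "oxygen_class": tax.oxygen_class}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dataset validation
# ---------------------------------------------------------------------------


def validate_dataset(
    counts: CountTable,
    meta: Iterable[SampleMetadata],
    qpcr: QpcrTable | None = None,
) -> ValidationReport:
    """Cross-reference counts, metadata and qPCR totals.

    Report-based (never raises): lists samples missing from metadata or
    qPCR, metadata/qPCR rows without counts, duplicate metadata rows, and
    the replicate count per regime × compartment × timepoint design cell
    (cells flagged when unbalanced). ``ok`` is true iff every
    cross-reference resolves one-to-one. Pure function of its inputs.
    """
    mdf = metadata_to_frame(meta)
    count_samples = set(counts.sample_ids)
    meta_samples = list(mdf["sample_id"])
    report = ValidationReport(ok=True)

    dup = mdf["sample_id"][mdf["sample_id"].duplicated()].tolist()
    if dup:
        report.duplicate_metadata = sorted(set(dup))
        report.messages.append(f"duplicate metadata rows for {sorted(set(dup))}")
    report.missing_metadata = sorted(count_samples - set(meta_samples))
    report.extra_metadata = sorted(set(meta_samples) - count_samples)
    if report.missing_metadata:
        report.messages.append(f"samples without metadata: {report.missing_metadata}")
    if report.extra_metadata:
        report.messages.append(f"metadata without counts: {report.extra_metadata}")

    if qpcr is not None:
        qpcr_samples = set(qpcr.sample_ids)
        report.missing_qpcr = sorted(count_samples - qpcr_samples)
        report.extra_qpcr = sorted(qpcr_samples - count_samples)
        if report.missing_qpcr:
            report.messages.append(f"samples without qPCR totals: {report.missing_qpcr}")
        if report.extra_qpcr:
            report.messages.append(f"qPCR rows without counts: {report.extra_qpcr}")

    cells = (
        mdf.groupby(["compartment", "regime", "timepoint"], sort=True)
        .size()
        .rename("n_replicates")
        .reset_index()
    )
    report.replicate_counts = cells
    for comp, sub in cells.groupby("compartment"):
        if sub["n_replicates"].nunique() > 1:
            lo = sub["n_replicates"].min()
            bad = sub[sub["n_replicates"] == lo]
            report.imbalanced_cells.extend(
                (comp, r.regime, int(r.timepoint), int(r.n_replicates))
                for r in bad.itertuples()
            )
            report.messages.append(f"design imbalance in compartment {comp!r}")

    report.ok = not (
        report.missing_metadata
        or report.extra_metadata
        or report.missing_qpcr
        or report.extra_qpcr
        or report.duplicate_metadata
    )
    return report


def collapse_otu_to_genus(counts: CountTable, otu_to_genus: Mapping[str, str]) -> CountTable:
    """Sum OTU-level columns into genus-level columns.

    Helper for inputs that were not pre-aggregated; OTUs absent from the
    mapping are collapsed into a ``__unassigned__`` column.
    """
    frame = counts.to_frame()
    genera = [otu_to_genus.get(o, "__unassigned__") for o in counts.genus_ids]
    collapsed = frame.T.groupby(pd.Index(genera, name="genus")).sum().T
    collapsed = collapsed[sorted(collapsed.columns)]
    return CountTable(list(collapsed.index), list(collapsed.columns), collapsed.to_numpy())
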