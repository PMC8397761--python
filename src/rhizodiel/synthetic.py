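"""Synthetic diel community generator with planted ground truth.

Emulates a paired light–dark (LD) vs constant-dark (DD) pot experiment:
every 12 h for three days (6 time points alternating AM/PM), 7 replicate
pots per regime and soil compartment are harvested and profiled by 16S cDNA
amplicon sequencing plus a qPCR total-copy assay. Genera are planted into
four rhythm classes:

``entrained``
    oscillate only under LD (driven by the external light cycle),
``endogenous_masked``
    oscillate only under DD (clock-driven, but hidden under LD by the
    community-wide response to light),
``endogenous_robust``
    oscillate under both regimes,
``arrhythmic``
    flat everywhere.

Counts are compositional: expected abundances are lognormal genus baselines
times a square-wave rhythm multiplier (2^(±amplitude/2) at peak/trough),
overdispersed by gamma multipliers (negative-binomial marginals), then a
single multinomial draw per sample at fixed sequencing depth — so every
sample's counts sum exactly to the depth. qPCR totals are lognormal around
a base activity level, elevated by ``qpcr_day_boost_log2`` in LD daytime
(PM) samples: the community-wide activity rhythm the absolute-abundance
scaling is meant to capture.

Rhythms are square waves at the 12-h sampling resolution: with two phases
observed per cycle, waveform shape within a phase is unidentifiable, so no
finer structure is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .core_data import (
    CountTable,
    QpcrTable,
    SampleMetadata,
    phase_of_timepoint,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_community",
    "simulate_environment",
    "truth_to_frame",
]

RHYTHM_CLASSES = ("entrained", "endogenous_masked", "endogenous_robust", "arrhythmic")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted diel community experiment.

    Defaults encode the reference design: 2 regimes × 6 time points × 7
    replicates per soil compartment; 200 genera of which 20 are entrained,
    15 endogenous-masked and 5 endogenous-robust; a peak-to-trough log2
    fold change of 3 (8-fold); negative-binomial dispersion 0.1; 50 000
    reads per sample; and a 2-fold (1 log2 unit) daytime elevation of total
    16S activity under LD.
    """

    n_genera: int = 200
    n_timepoints: int = 6
    n_replicates: int = 7
    regimes: tuple[str, ...] = ("LD", "DD")
    compartments: tuple[str, ...] = ("rhizosphere", "bulk")
    frac_entrained: float = 0.10
    frac_endogenous_masked: float = 0.075
    frac_endogenous_robust: float = 0.025
    amplitude_log2: float = 3.0
    baseline_logmean: float = 0.0
    baseline_logsd: float = 1.0
    nb_dispersion: float = 0.1
    sequencing_depth: int = 50_000
    qpcr_base_copies: float = 1e9
    qpcr_day_boost_log2: float = 1.0
    qpcr_noise_logsd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_entrained,
            self.frac_endogenous_masked,
            self.frac_endogenous_robust,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("rhythm-class fractions must be ≥ 0 and sum to ≤ 1")
        if self.n_timepoints % 2 != 0:
            raise ValueError("n_timepoints must be even (AM/PM pairs)")
        for name in ("baseline_logsd", "nb_dispersion", "qpcr_noise_logsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.amplitude_log2 < 0:
            raise ValueError("amplitude_log2 must be ≥ 0")
        if self.sequencing_depth < 1 or self.n_genera < 2:
            raise ValueError("need sequencing_depth ≥ 1 and n_genera ≥ 2")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Planted rhythm label for one genus."""

    genus_id: str
    rhythm_class: str
    phase_sign: str  # day_high | night_high
    true_amplitude_log2: float


def truth_to_frame(truth: Iterable[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth])


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_genera
    n_ent = round(config.frac_entrained * n)
    n_mask = round(config.frac_endogenous_masked * n)
    n_rob = round(config.frac_endogenous_robust * n)
    classes = (
        ["entrained"] * n_ent
        + ["endogenous_masked"] * n_mask
        + ["endogenous_robust"] * n_rob
        + ["arrhythmic"] * (n - n_ent - n_mask - n_rob)
    )
    order = rng.permutation(n)
    return [classes[k] for k in order]


def _oscillates(rhythm_class: str, regime: str) -> bool:
    if rhythm_class == "entrained":
        return regime == "LD"
    if rhythm_class == "endogenous_masked":
        return regime == "DD"
    return rhythm_class == "endogenous_robust"


def simulate_community(
    config: SimulationConfig,
) -> tuple[CountTable, list[SampleMetadata], QpcrTable, list[GroundTruth]]:
    """Draw one full experiment: counts, metadata, qPCR totals, ground truth.

    Deterministic given ``config.seed`` — the same config yields
    bit-identical outputs. Class assignment is a seeded shuffle, so class
    proportions match the configured fractions exactly.
    """
    rng = np.random.default_rng(config.seed)
    genus_ids = [f"g{i:04d}" for i in range(config.n_genera)]

    classes = _assign_classes(config, rng)
    baselines = rng.lognormal(
        config.baseline_logmean, config.baseline_logsd, size=config.n_genera
    )
    # Peak phases balance the day- and night-peaking oscillator mass within
    # each rhythm class: members are sorted by baseline and assigned in
    # snake order (day, night, night, day, ...), which balances both the
    # total planted mass and its second moment between the two phases.
    # A balanced planting keeps the oscillating community mass — and its
    # sampling variance — symmetric between phases, so the compositional
    # closure of the multinomial draw does not leak a community-wide phase
    # shift into the arrhythmic genera. Deterministic given the class shuffle.
    phase_sign = ["day_high"] * config.n_genera
    snake = ("day_high", "night_high", "night_high", "day_high")
    for cls in ("entrained", "endogenous_masked", "endogenous_robust"):
        members = [i for i, c in enumerate(classes) if c == cls]
        members.sort(key=lambda i: -baselines[i])
        for k, i in enumerate(members):
            phase_sign[i] = snake[k % 4]
    truth = [
        GroundTruth(
            genus_id=g,
            rhythm_class=c,
            phase_sign=s,
            true_amplitude_log2=config.amplitude_log2 if c != "arrhythmic" else 0.0,
        )
        for g, c, s in zip(genus_ids, classes, phase_sign)
    ]
    half_amp = 2.0 ** (config.amplitude_log2 / 2.0)

    sample_ids: list[str] = []
    meta: list[SampleMetadata] = []
    count_rows: list[np.ndarray] = []
    qpcr_vals: list[float] = []

    comp_short = {"rhizosphere": "rz", "bulk": "bk"}
    for compartment in config.compartments:
        for regime in config.regimes:
            for t in range(1, config.n_timepoints + 1):
                phase = phase_of_timepoint(t)
                # rhythm multiplier per genus for this regime/phase
                mult = np.ones(config.n_genera)
                for i, (c, s) in enumerate(zip(classes, phase_sign)):
                    if c == "arrhythmic" or not _oscillates(c, regime):
                        continue
                    high_phase = "PM" if s == "day_high" else "AM"
                    mult[i] = half_amp if phase == high_phase else 1.0 / half_amp
                expected = baselines * mult
                for r in range(1, config.n_replicates + 1):
                    sid = f"{regime}_{comp_short[compartment]}_t{t}_r{r}"
                    sample_ids.append(sid)
                    meta.append(
                        SampleMetadata(
                            sample_id=sid,
                            regime=regime,
                            compartment=compartment,
                            timepoint=t,
                            phase=phase,
                            replicate=r,
                        )
                    )
                    shape = 1.0 / config.nb_dispersion
                    noisy = expected * rng.gamma(shape, 1.0 / shape, size=config.n_genera)
                    p = noisy / noisy.sum()
                    count_rows.append(rng.multinomial(config.sequencing_depth, p))
                    boost = (
                        config.qpcr_day_boost_log2
                        if (regime == "LD" and phase == "PM")
                        else 0.0
                    )
                    total = (
                        config.qpcr_base_copies
                        * 2.0**boost
                        * np.exp(rng.normal(0.0, config.qpcr_noise_logsd))
                    )
                    qpcr_vals.append(total)

    counts = CountTable(sample_ids, genus_ids, np.vstack(count_rows))
    qpcr = QpcrTable(list(sample_ids), np.array(qpcr_vals))
    return counts, meta, qpcr, truth


# ---------------------------------------------------------------------------
# rhizosphere environment waveforms (deterministic covariates)
# ---------------------------------------------------------------------------

# Target levels for the physicochemical series; day/night DOC levels sit at
# the centres of the observed day (231-270) and night (161-201) ranges.
_O2_LIGHT = 200.0  # µmol/L
_O2_DARK = 5.0
_O2_TAU_H = 3.0
_PH_DAY = 6.0
_PH_NIGHT = 6.4
_PH_LAG_H = 1.0
_PH_DD_END = 6.8
_DOC_DAY = 250.0  # mg/kg soil
_DOC_NIGHT = 181.0
_DOC_DD_END = 140.0


def simulate_environment(config: SimulationConfig, dt_h: float = 0.25) -> pd.DataFrame:
    """Deterministic rhizosphere O2 / pH / DOC series for each regime.

    LD: oxygen relaxes exponentially (3-h time constant) toward 200 µmol/L
    in the light and 5 µmol/L in the dark; pH ramps 6.4→6.0 over the day
    and back over the night with a 1-h lag behind the light switch; DOC is
    a day/night square wave at the centres of the observed ranges. DD:
    oxygen flat at 5 µmol/L, pH drifts monotonically toward 6.8, DOC decays
    toward ~140 mg/kg over the 72-h window.

    Columns: regime, time_h, light_on, o2_umol_l, ph, doc_mg_kg.
    """
    total_h = 12.0 * config.n_timepoints
    times = np.arange(0.0, total_h + dt_h / 2, dt_h)
    frames = []
    for regime in config.regimes:
        if regime == "LD":
            light = (times % 24.0) < 12.0
            o2 = np.empty_like(times)
            o2[0] = _O2_DARK
            for k in range(1, len(times)):
                target = _O2_LIGHT if light[k] else _O2_DARK
                o2[k] = target + (o2[k - 1] - target) * np.exp(-dt_h / _O2_TAU_H)
            lagged = (times - _PH_LAG_H) % 24.0
            day_frac = np.clip(lagged / 12.0, 0, 1)
            night_frac = np.clip((lagged - 12.0) / 12.0, 0, 1)
            ph = np.where(
                lagged < 12.0,
                _PH_NIGHT - (_PH_NIGHT - _PH_DAY) * day_frac,
                _PH_DAY + (_PH_NIGHT - _PH_DAY) * night_frac,
            )
            doc = np.where(light, _DOC_DAY, _DOC_NIGHT)
        else:
            light = np.zeros_like(times, dtype=bool)
            o2 = np.full_like(times, _O2_DARK)
            ph = _PH_DD_END - (_PH_DD_END - _PH_NIGHT) * np.exp(-times / 24.0)
            doc = _DOC_DD_END + (_DOC_DAY - _DOC_DD_END) * np.exp(-times / 24.0)
        frames.append(
            pd.DataFrame(
                {
                    "regime": regime,
                    "time_h": times,
                    "light_on": light,
                    "o2_umol_l": o2,
                    "ph": ph,
                    "doc_mg_kg": doc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
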