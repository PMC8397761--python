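"""Config-driven end-to-end runner.

Reproduces the full analysis shape on real or simulated inputs: load or
simulate a (counts, metadata, qPCR) dataset, normalize, compute alpha
diversity, call circadian taxa per regime, rank indicator taxa by
random-forest MDA, build the four meta-community co-occurrence networks
(regime × compartment) with Network Enhancement and an RMT-chosen cutoff,
derive per-time-point subnetworks and Erdős–Rényi null distributions, and
write everything as TSV/GraphML plus a JSON run manifest.

All stochastic stages draw their seed from the single global seed through
a documented splitting scheme (:func:`stage_seed`), so stages are
reproducible in isolation and a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import (
    CountTable,
    QpcrTable,
    SampleMetadata,
    metadata_to_frame,
    read_count_table,
    read_metadata,
    read_qpcr,
    validate_dataset,
)
from .indicators import (
    circadian_indicator_overlap,
    fit_phase_forest,
    mean_decrease_accuracy,
    top_indicators,
)
from .networks import (
    build_network,
    correlation_matrix,
    er_random_graph,
    network_enhancement,
    rmt_threshold,
    subnetwork_by_timepoint,
    topology_metrics,
    write_edge_list,
)
from .normalization import (
    AbundanceMatrix,
    absolute_abundance,
    chao1_index,
    normalize_counts,
    shannon_index,
)
from .rhythm import RhythmDetectionResult, detect_circadian_taxa
from .synthetic import SimulationConfig, simulate_community, truth_to_frame

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Child seed for a named stage: (seed·100003 + crc32(stage)) mod 2³¹."""
    return (global_seed * 100003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Declarative configuration for one run (YAML-serializable)."""

    seed: int = 0
    outdir: str = "rhizodiel_run"
    # inputs: either simulation (default) or file paths
    simulate: bool = True
    simulation: dict[str, Any] = field(default_factory=dict)
    counts_path: str | None = None
    counts_format: str = "tsv"
    metadata_path: str | None = None
    qpcr_path: str | None = None
    # detection
    alpha: float = 0.05
    detection_scale: str = "normalized"  # normalized | absolute
    bh_correct: bool = False
    # indicators
    n_trees: int = 1000
    top_n: dict[str, int] = field(default_factory=lambda: {"rhizosphere": 30, "bulk": 40})
    # networks
    correlation_method: str = "spearman"
    use_enhancement: bool = True
    ne_alpha: float = 0.9
    ne_k_neighbors: int | None = None
    ne_diffusion_order: int = 2
    rmt_grid_min: float = 0.30
    rmt_grid_max: float = 0.95
    rmt_grid_step: float = 0.01
    # one cutoff per compartment (estimated on the pooled samples) keeps the
    # LD and DD group networks comparable; "group" re-estimates per regime
    threshold_scope: str = "compartment"
    keep_isolated_nodes: bool = True
    n_null_graphs: int = 20
    regimes: tuple[str, ...] = ("LD", "DD")
    compartments: tuple[str, ...] = ("rhizosphere", "bulk")

    def __post_init__(self) -> None:
        if self.detection_scale not in ("normalized", "absolute"):
            raise ValueError("detection_scale must be 'normalized' or 'absolute'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.simulate:
            for p in ("counts_path", "metadata_path", "qpcr_path"):
                if getattr(self, p) is None:
                    raise ValueError(f"{p} required when simulate=false")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regimes", "compartments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["regimes"] = list(self.regimes)
        d["compartments"] = list(self.compartments)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", stage_seed(self.seed, "simulation"))
        params.setdefault("regimes", tuple(self.regimes))
        params.setdefault("compartments", tuple(self.compartments))
        return SimulationConfig(**params)


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run plus where they were written."""

    outdir: Path
    counts: CountTable
    meta: list[SampleMetadata]
    qpcr: QpcrTable
    rhythm_results: dict[tuple[str, str], RhythmDetectionResult]
    indicator_tables: dict[tuple[str, str], pd.DataFrame]
    overlaps: dict[tuple[str, str], tuple[list[str], float]]
    diversity: pd.DataFrame
    networks: dict[tuple[str, str], nx.Graph]
    network_metrics: pd.DataFrame
    manifest: dict[str, Any]


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim = config.simulation_config()
        counts, meta, qpcr, truth = simulate_community(sim)
        return counts, meta, qpcr, truth
    counts = read_count_table(config.counts_path, config.counts_format)
    meta = read_metadata(config.metadata_path)
    qpcr = read_qpcr(config.qpcr_path)
    return counts, meta, qpcr, None


def _subset(counts: CountTable, meta_frame: pd.DataFrame, **criteria) -> list[str]:
    mask = pd.Series(True, index=meta_frame.index)
    for key, value in criteria.items():
        mask &= meta_frame[key] == value
    return list(meta_frame.loc[mask, "sample_id"])


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "stage_seeds": {},
        "outputs": [],
    }

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"].append(name)

    # ------------------------------------------------------------------ data
    try:
        counts, meta, qpcr, truth = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load_inputs' failed: {exc}") from exc
    manifest["stage_seeds"]["simulation"] = stage_seed(config.seed, "simulation")
    report = validate_dataset(counts, meta, qpcr)
    if not report.ok:
        raise RuntimeError(f"stage 'validate' failed: {report.messages}")
    if truth is not None:
        emit("ground_truth.tsv", truth_to_frame(truth))
    mdf = metadata_to_frame(meta)
    emit("metadata.tsv", mdf)

    # -------------------------------------------------------- alpha diversity
    div_rows = []
    for i, sid in enumerate(counts.sample_ids):
        row = counts.counts[i]
        div_rows.append(
            {
                "sample_id": sid,
                "shannon": shannon_index(row),
                "chao1": chao1_index(row),
            }
        )
    diversity = pd.DataFrame(div_rows).merge(mdf, on="sample_id")
    emit("alpha_diversity.tsv", diversity)

    # ------------------------------------------------- per-compartment tables
    rhythm_results: dict[tuple[str, str], RhythmDetectionResult] = {}
    indicator_tables: dict[tuple[str, str], pd.DataFrame] = {}
    overlaps: dict[tuple[str, str], tuple[list[str], float]] = {}
    networks: dict[tuple[str, str], nx.Graph] = {}
    metric_rows: list[dict[str, Any]] = []

    grid = np.round(
        np.arange(config.rmt_grid_min, config.rmt_grid_max + config.rmt_grid_step / 2,
                  config.rmt_grid_step),
        6,
    )

    for compartment in config.compartments:
        comp_samples = _subset(counts, mdf, compartment=compartment)
        comp_counts = counts.select_samples(comp_samples)
        comp_meta = mdf[mdf["sample_id"].isin(comp_samples)]
        comp_qpcr = QpcrTable(
            comp_samples,
            qpcr.as_series().loc[comp_samples].to_numpy(),
        )
        normalized = normalize_counts(comp_counts)
        absolute = absolute_abundance(comp_counts, comp_qpcr)
        detect_abund = normalized if config.detection_scale == "normalized" else absolute

        pooled_threshold = None
        if config.threshold_scope == "compartment":
            pooled_corr = correlation_matrix(absolute, method=config.correlation_method)
            pooled_rmt = rmt_threshold(pooled_corr, grid=grid)
            pooled_threshold = pooled_rmt.threshold
            manifest.setdefault("rmt_thresholds", {})[compartment] = {
                "threshold": pooled_rmt.threshold,
                "reached_poisson": pooled_rmt.reached_poisson,
            }

        circ_frames = []
        for regime in config.regimes:
            key = (compartment, regime)
            try:
                result = detect_circadian_taxa(
                    detect_abund,
                    comp_meta,
                    regime=regime,
                    alpha=config.alpha,
                    compartment=compartment,
                    bh_correct=config.bh_correct,
                )
            except Exception as exc:
                raise RuntimeError(f"stage 'detect[{key}]' failed: {exc}") from exc
            rhythm_results[key] = result
            frame = result.to_frame()
            frame.insert(0, "compartment", compartment)
            circ_frames.append(frame)

            # indicators on absolute (activity-weighted) abundance
            fseed = stage_seed(config.seed, f"forest_{compartment}_{regime}")
            manifest["stage_seeds"][f"forest_{compartment}_{regime}"] = fseed
            try:
                forest = fit_phase_forest(
                    absolute,
                    comp_meta,
                    regime=regime,
                    n_trees=config.n_trees,
                    seed=fseed,
                    compartment=compartment,
                )
                records = mean_decrease_accuracy(forest)
            except Exception as exc:
                raise RuntimeError(f"stage 'indicators[{key}]' failed: {exc}") from exc
            n_top = config.top_n.get(compartment, 30)
            top = top_indicators(records, n=min(n_top, len(records)))
            table = pd.DataFrame(
                {
                    "compartment": compartment,
                    "regime": regime,
                    "genus_id": [r.genus_id for r in top],
                    "mda": [r.mda for r in top],
                    "mda_se": [r.mda_se for r in top],
                    "rank": [r.rank for r in top],
                    "oob_accuracy": forest.oob_accuracy,
                }
            )
            shared, mda_sum = circadian_indicator_overlap(top, result)
            table["is_circadian"] = table["genus_id"].isin(shared)
            indicator_tables[key] = table
            overlaps[key] = (shared, mda_sum)

            # ------------------------------------------------------ networks
            try:
                corr = correlation_matrix(
                    absolute,
                    method=config.correlation_method,
                    sample_ids=_subset(counts, comp_meta, regime=regime),
                )
                enhanced = (
                    network_enhancement(
                        np.abs(corr.values),
                        k_neighbors=config.ne_k_neighbors,
                        alpha=config.ne_alpha,
                        diffusion_order=config.ne_diffusion_order,
                    )
                    if config.use_enhancement
                    else None
                )
                if pooled_threshold is not None:
                    threshold = pooled_threshold
                else:
                    threshold = rmt_threshold(corr, grid=grid).threshold
                graph = build_network(
                    corr,
                    threshold,
                    weights=enhanced,
                    keep_isolated=config.keep_isolated_nodes,
                )
            except Exception as exc:
                raise RuntimeError(f"stage 'network[{key}]' failed: {exc}") from exc
            graph.graph.update(
                compartment=compartment,
                regime=regime,
                rmt_threshold=float(threshold),
                enhanced=bool(config.use_enhancement),
            )
            networks[key] = graph
            gname = f"network_{compartment}_{regime}"
            nx.write_graphml(graph, outdir / f"{gname}.graphml")
            write_edge_list(graph, outdir / f"{gname}_edges.tsv")
            manifest["outputs"] += [f"{gname}.graphml", f"{gname}_edges.tsv"]

            tseed = stage_seed(config.seed, f"topology_{compartment}_{regime}")
            manifest["stage_seeds"][f"topology_{compartment}_{regime}"] = tseed
            if graph.number_of_nodes() > 0:
                meta_metrics = topology_metrics(graph, seed=tseed)
                metric_rows.append(
                    {
                        "compartment": compartment,
                        "regime": regime,
                        "graph": "meta",
                        "timepoint": -1,
                        "null_id": -1,
                        **meta_metrics.as_dict(),
                    }
                )
            timepoints = sorted(comp_meta["timepoint"].unique())
            for t in timepoints:
                sub = subnetwork_by_timepoint(
                    graph, absolute, comp_meta, timepoint=int(t),
                    regime=regime, compartment=compartment,
                )
                if sub.number_of_nodes() == 0:
                    continue
                sub_metrics = topology_metrics(sub, seed=tseed)
                metric_rows.append(
                    {
                        "compartment": compartment,
                        "regime": regime,
                        "graph": "timepoint",
                        "timepoint": int(t),
                        "null_id": -1,
                        **sub_metrics.as_dict(),
                    }
                )
                nseed = stage_seed(config.seed, f"null_{compartment}_{regime}_t{t}")
                for k in range(config.n_null_graphs):
                    null = er_random_graph(
                        sub.number_of_nodes(), sub.number_of_edges(), seed=nseed + k
                    )
                    null_metrics = topology_metrics(null, seed=nseed + k)
                    metric_rows.append(
                        {
                            "compartment": compartment,
                            "regime": regime,
                            "graph": "null",
                            "timepoint": int(t),
                            "null_id": k,
                            **null_metrics.as_dict(),
                        }
                    )

        emit(
            f"circadian_taxa_{compartment}.tsv",
            pd.concat(circ_frames, ignore_index=True),
        )
        emit(
            f"indicator_taxa_{compartment}.tsv",
            pd.concat(
                [indicator_tables[(compartment, r)] for r in config.regimes],
                ignore_index=True,
            ),
        )

    network_metrics = pd.DataFrame(metric_rows)
    emit("network_topology.tsv", network_metrics)

    manifest["overlaps"] = {
        f"{c}_{r}": {"shared_genera": s, "mda_sum": m}
        for (c, r), (s, m) in overlaps.items()
    }
    manifest["circadian_fractions"] = {
        f"{c}_{r}": {
            "genus_count": res.fraction_genus_count,
            "abundance_weighted": res.fraction_abundance,
            "n_circadian": len(res.circadian_genera),
        }
        for (c, r), res in rhythm_results.items()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")

    return ReportBundle(
        outdir=outdir,
        counts=counts,
        meta=meta,
        qpcr=qpcr,
        rhythm_results=rhythm_results,
        indicator_tables=indicator_tables,
        overlaps=overlaps,
        diversity=diversity,
        networks=networks,
        network_metrics=network_metrics,
        manifest=manifest,
    )
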