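"""Correlation networks: enhancement, RMT thresholding, nulls, topology.

Pipeline for contrasting light–dark vs constant-dark community structure:

1. pairwise genus–genus correlation (Spearman by default) across the
   samples of one meta-community (regime × compartment);
2. Network Enhancement — a diffusion on a doubly-stochastic localized
   transition matrix that amplifies coherent (block-like) structure and
   suppresses incoherent noise in the weighted graph;
3. a correlation cutoff chosen by random-matrix theory: the smallest
   threshold at which the nearest-neighbour spacing distribution (NNSD) of
   the unfolded eigenvalues leaves the Gaussian-orthogonal-ensemble regime
   (level repulsion, Wigner surmise) and becomes Poisson (uncoupled
   modules);
4. hard-thresholded weighted graphs, per-time-point induced subgraphs on
   the genera present at that time point, and G(n, m) Erdős–Rényi null
   graphs matching node and edge counts;
5. topology metrics: degree, density, seeded Louvain modules/modularity,
   normalized closeness and betweenness, clustering coefficient.

Enhancement and the RMT scan operate on absolute correlation values (the
diffusion requires non-negative weights); the sign of each retained edge
is kept as an attribute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_data import SampleMetadata, metadata_to_frame
from .normalization import AbundanceMatrix

__all__ = [
    "CorrelationMatrix",
    "TopologyMetrics",
    "correlation_matrix",
    "network_enhancement",
    "doubly_stochastic",
    "rmt_threshold",
    "nnsd_statistics",
    "build_network",
    "subnetwork_by_timepoint",
    "er_random_graph",
    "topology_metrics",
    "write_edge_list",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric genus × genus correlation matrix with unit diagonal."""

    genus_ids: list[str]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genus_ids), len(self.genus_ids)):
            raise ValueError("correlation matrix shape mismatch")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(np.diag(v) - 1).max() > 1e-9:
            raise ValueError("correlation matrix must have unit diagonal")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.genus_ids)


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    n_modules: int
    modularity: float
    mean_normalized_closeness: float
    mean_normalized_betweenness: float
    mean_clustering_coefficient: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def correlation_matrix(
    abund: AbundanceMatrix,
    method: str = "spearman",
    sample_ids: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Pairwise genus correlations across samples (of one group).

    Genera with zero variance across the selected samples are excluded
    (logged) — their correlation is undefined. Requires ≥ 4 samples.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be spearman or pearson, got {method!r}")
    values = abund.values
    genus_ids = list(abund.genus_ids)
    if sample_ids is not None:
        values = values[abund.sample_index(list(sample_ids))]
    if values.shape[0] < 4:
        raise ValueError(f"need ≥ 4 samples for correlations, got {values.shape[0]}")
    # relative tolerance: columns constant up to float jitter are excluded
    scale = np.maximum(np.abs(values).max(axis=0), 1.0)
    keep = values.std(axis=0) > 1e-12 * scale
    if not keep.all():
        dropped = [g for g, k in zip(genus_ids, keep) if not k]
        logger.info("excluding %d zero-variance genera from correlation", len(dropped))
        values = values[:, keep]
        genus_ids = [g for g, k in zip(genus_ids, keep) if k]
    if len(genus_ids) < 2:
        raise ValueError("fewer than 2 genera with variance")
    if method == "spearman":
        ranked = np.apply_along_axis(stats.rankdata, 0, values)
        corr = np.corrcoef(ranked, rowvar=False)
    else:
        corr = np.corrcoef(values, rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(genus_ids, corr, method)


# ---------------------------------------------------------------------------
# Network Enhancement
# ---------------------------------------------------------------------------


def _knn_localize(W: np.ndarray, k: int) -> np.ndarray:
    """Keep each row's k largest off-diagonal weights, symmetrized by max."""
    n = W.shape[0]
    P = np.zeros_like(W)
    for i in range(n):
        row = W[i].copy()
        row[i] = -np.inf
        nn = np.argpartition(row, -k)[-k:]
        P[i, nn] = W[i, nn]
    return np.maximum(P, P.T)


def doubly_stochastic(
    W: np.ndarray, tol: float = 1e-10, max_iter: int = 5000
) -> np.ndarray:
    """Symmetric Sinkhorn (iterative proportional fitting) scaling.

    Returns D W D with positive diagonal D such that all row and column
    sums are 1 within ``tol`` (the symmetric scaling preserves symmetry,
    so row and column sums coincide).
    """
    if np.abs(W - W.T).max() > 1e-8:
        raise ValueError("doubly_stochastic requires a symmetric matrix")
    if W.min() < 0:
        raise ValueError("doubly_stochastic requires non-negative entries")
    T = W.astype(float).copy()
    for _ in range(max_iter):
        r = T.sum(axis=1)
        if np.abs(r - 1.0).max() < tol:
            return T
        if (r <= 0).any():
            raise ValueError("matrix has an empty row; cannot scale")
        d = 1.0 / np.sqrt(r)
        T *= np.outer(d, d)
    raise RuntimeError("Sinkhorn scaling did not converge")


def network_enhancement(
    W: np.ndarray,
    k_neighbors: int | None = None,
    alpha: float = 0.9,
    diffusion_order: int = 2,
    return_intermediate: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Diffusion-based denoising of a symmetric non-negative weight matrix.

    Steps: (i) localize to each node's ``k_neighbors`` strongest links
    (default min(20, ⌈n/10⌉)) and add a self-link of each node's retained
    strength so the kernel has full support; (ii) rescale to a symmetric
    doubly-stochastic transition matrix T by iterative proportional
    fitting; (iii) apply the regularized diffusion in closed form through
    the eigen-decomposition of T, mapping each eigenvalue λ to
    (1 − α)·λ / (1 − α·λ^order). Large coherent eigen-modes (blocks) are
    preserved while small noisy ones are shrunk. Output is symmetric,
    non-negative, zero-diagonal.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("W must be square")
    if np.abs(W - W.T).max() > 1e-8:
        raise ValueError("W must be symmetric")
    if W.min() < 0:
        raise ValueError("W must be non-negative (use |r| for correlations)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k_neighbors is None:
        k_neighbors = min(20, int(np.ceil(n / 10)))
    if k_neighbors >= n:
        warnings.warn(f"k_neighbors={k_neighbors} ≥ n={n}; clipping to n-1")
        k_neighbors = n - 1
    k_neighbors = max(1, k_neighbors)

    W0 = W.copy()
    np.fill_diagonal(W0, 0.0)
    P = _knn_localize(W0, k_neighbors)
    # self-link keeps Sinkhorn support even for weakly connected nodes
    np.fill_diagonal(P, P.sum(axis=1) + 1e-12)
    T = doubly_stochastic(P, tol=1e-10)

    eigvals, eigvecs = np.linalg.eigh(T)
    enhanced_vals = (1.0 - alpha) * eigvals / (1.0 - alpha * eigvals**diffusion_order)
    out = (eigvecs * enhanced_vals) @ eigvecs.T
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    out[out < 0] = 0.0
    if return_intermediate:
        return out, T
    return out


# ---------------------------------------------------------------------------
# random-matrix-theory threshold
# ---------------------------------------------------------------------------


@dataclass
class RmtDiagnostics:
    threshold: float
    reached_poisson: bool
    per_grid: pd.DataFrame = field(repr=False, default=None)


def _unfold_spacings(eigvals: np.ndarray, degeneracy_tol: float = 1e-8) -> np.ndarray:
    """Unit-mean nearest-neighbour spacings of an unfolded spectrum.

    Degenerate eigenvalues are collapsed first; the cumulative spectral
    density is smoothed with a Gaussian kernel (Silverman bandwidth) and
    the unfolded levels are m·F̂(λ_i).
    """
    lam = np.sort(eigvals)
    keep = np.concatenate([[True], np.diff(lam) > degeneracy_tol])
    lam = lam[keep]
    m = len(lam)
    if m < 3:
        return np.array([])
    sd = lam.std(ddof=1)
    iqr = np.subtract(*np.percentile(lam, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return np.array([])
    h = 0.9 * spread * m ** (-0.2)
    F = stats.norm.cdf((lam[:, None] - lam[None, :]) / h).mean(axis=1)
    unfolded = m * F
    spac = np.diff(unfolded)
    spac = spac[spac > 0]
    if spac.size == 0:
        return spac
    return spac / spac.mean()


def nnsd_statistics(spacings: np.ndarray, nnsd_bins: int = 10) -> dict[str, float]:
    """Chi-squared goodness of fit of unit-mean spacings vs Poisson and GOE.

    Bins are equal-width on [0, 3] plus an overflow bin; expected
    probabilities come from the exponential (Poisson statistics) and the
    Wigner surmise (GOE). Returns chi² statistics and p-values.
    """
    s = np.asarray(spacings, dtype=float)
    n = s.size
    if n < nnsd_bins:
        return {
            "n_spacings": n,
            "chi2_poisson": np.nan,
            "p_poisson": np.nan,
            "chi2_goe": np.nan,
            "p_goe": np.nan,
        }
    edges = np.linspace(0.0, 3.0, nnsd_bins)
    edges = np.append(edges, np.inf)
    observed, _ = np.histogram(s, bins=edges)

    def chi2_against(cdf) -> tuple[float, float]:
        probs = np.diff([cdf(e) for e in edges])
        expected = n * np.asarray(probs)
        ok = expected > 0
        stat = float(((observed[ok] - expected[ok]) ** 2 / expected[ok]).sum())
        dof = max(int(ok.sum()) - 1, 1)
        return stat, float(stats.chi2.sf(stat, dof))

    poisson_cdf = lambda x: 1.0 - np.exp(-x) if np.isfinite(x) else 1.0
    goe_cdf = lambda x: 1.0 - np.exp(-np.pi * x**2 / 4.0) if np.isfinite(x) else 1.0
    chi2_p, p_p = chi2_against(poisson_cdf)
    chi2_g, p_g = chi2_against(goe_cdf)
    return {
        "n_spacings": n,
        "chi2_poisson": chi2_p,
        "p_poisson": p_p,
        "chi2_goe": chi2_g,
        "p_goe": p_g,
    }


def rmt_threshold(
    corr: CorrelationMatrix,
    grid: Sequence[float] | None = None,
    nnsd_bins: int = 10,
    p_threshold: float = 0.05,
    min_spacings: int = 20,
) -> RmtDiagnostics:
    """Correlation cutoff at the GOE → Poisson transition of the NNSD.

    For each candidate s (default grid 0.30–0.95, step 0.01) the matrix
    with |r| < s zeroed is diagnosed: eigenvalues, degeneracy-collapsed
    and unfolded, give a spacing distribution whose chi-squared fit is
    compared against Poisson and GOE. The chosen threshold is the smallest
    s whose NNSD is consistent with Poisson (p > ``p_threshold``). If no
    grid point qualifies the grid maximum is returned with
    ``reached_poisson=False``. Matrices smaller than 20 genera are
    rejected — spectral statistics are meaningless there.
    """
    if corr.n < 20:
        raise ValueError(f"matrix size {corr.n} < 20; NNSD statistics unreliable")
    if grid is None:
        grid = np.round(np.arange(0.30, 0.951, 0.01), 4)
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("grid values must lie in (0, 1)")

    rows = []
    chosen = None
    absr = np.abs(corr.values)
    for s in grid:
        A = np.where(absr >= s, corr.values, 0.0)
        np.fill_diagonal(A, 1.0)
        eigvals = np.linalg.eigvalsh(A)
        spacings = _unfold_spacings(eigvals)
        d = nnsd_statistics(spacings, nnsd_bins=nnsd_bins)
        d["threshold"] = float(s)
        d["enough_spacings"] = bool(d["n_spacings"] >= min_spacings)
        rows.append(d)
        if (
            chosen is None
            and d["enough_spacings"]
            and np.isfinite(d["p_poisson"])
            and d["p_poisson"] > p_threshold
        ):
            chosen = float(s)
    per_grid = pd.DataFrame(rows)
    if chosen is None:
        warnings.warn("no grid point reached Poisson consistency; using grid max")
        return RmtDiagnostics(float(grid.max()), False, per_grid)
    return RmtDiagnostics(chosen, True, per_grid)


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


def build_network(
    corr: CorrelationMatrix,
    threshold: float,
    keep_isolated: bool = False,
    weights: np.ndarray | None = None,
) -> nx.Graph:
    """Hard-threshold a correlation matrix into a weighted simple graph.

    Edge (g, h) iff |r_gh| ≥ threshold (g ≠ h); weight = |r_gh| (or the
    matching entry of ``weights``, e.g. an enhanced matrix); the sign of r
    is stored on the edge. Isolated nodes are dropped unless
    ``keep_isolated``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = corr.n
    wmat = np.abs(corr.values) if weights is None else np.asarray(weights, dtype=float)
    graph = nx.Graph(threshold=float(threshold), method=corr.method)
    graph.add_nodes_from(corr.genus_ids)
    absr = np.abs(corr.values)
    for i in range(n):
        for j in range(i + 1, n):
            if absr[i, j] >= threshold:
                graph.add_edge(
                    corr.genus_ids[i],
                    corr.genus_ids[j],
                    weight=float(wmat[i, j]) if wmat[i, j] > 0 else float(absr[i, j]),
                    sign=int(np.sign(corr.values[i, j])),
                )
    if not keep_isolated:
        graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def subnetwork_by_timepoint(
    graph: nx.Graph,
    abund: AbundanceMatrix,
    meta: Iterable[SampleMetadata] | pd.DataFrame,
    timepoint: int,
    regime: str | None = None,
    compartment: str | None = None,
    min_presence: int = 1,
) -> nx.Graph:
    """Induced subgraph on the genera present at one time point.

    Presence means a nonzero abundance in at least ``min_presence``
    replicates of that time point (within the regime/compartment the
    parent graph describes, when given).
    """
    mdf = metadata_to_frame(meta)
    mask = mdf["timepoint"] == timepoint
    if regime is not None:
        mask &= mdf["regime"] == regime
    if compartment is not None:
        mask &= mdf["compartment"] == compartment
    sel = mdf[mask]
    if sel.empty:
        raise ValueError(f"no samples at timepoint {timepoint}")
    idx = abund.sample_index(list(sel["sample_id"]))
    present_counts = (abund.values[idx] > 0).sum(axis=0)
    present = {
        g for g, c in zip(abund.genus_ids, present_counts) if c >= min_presence
    }
    nodes = [v for v in graph.nodes if v in present]
    if not nodes:
        warnings.warn(f"no present genera at timepoint {timepoint}; empty subgraph")
    return graph.subgraph(nodes).copy()


def er_random_graph(n_nodes: int, n_edges: int, seed: int) -> nx.Graph:
    """Uniform G(n, m) simple graph with unit edge weights (seeded)."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    graph = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    nx.set_edge_attributes(graph, 1.0, "weight")
    return graph


def topology_metrics(graph: nx.Graph, seed: int = 0) -> TopologyMetrics:
    """Topology summary of a weighted undirected graph.

    Modules and modularity from seeded Louvain on edge weights; closeness
    normalized as (n_c − 1)/Σ distances within each connected component;
    betweenness normalized by (n − 1)(n − 2)/2 pairs; both on unweighted
    shortest paths. A single-node graph has centralities 0 and one module.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("graph is empty")
    m = graph.number_of_edges()
    avg_degree = 2.0 * m / n
    density = nx.density(graph) if n > 1 else 0.0
    if m > 0:
        communities = nx.community.louvain_communities(graph, weight="weight", seed=seed)
        modularity = float(nx.community.modularity(graph, communities, weight="weight"))
    else:
        communities = [{v} for v in graph.nodes]
        modularity = 0.0
    closeness = nx.closeness_centrality(graph, wf_improved=False) if n > 1 else {0: 0.0}
    betweenness = nx.betweenness_centrality(graph, normalized=True) if n > 2 else {
        v: 0.0 for v in graph.nodes
    }
    clustering = nx.average_clustering(graph) if n > 1 else 0.0
    return TopologyMetrics(
        n_nodes=n,
        n_edges=m,
        average_degree=avg_degree,
        density=density,
        n_modules=len(communities),
        modularity=modularity,
        mean_normalized_closeness=float(np.mean(list(closeness.values()))),
        mean_normalized_betweenness=float(np.mean(list(betweenness.values()))),
        mean_clustering_coefficient=float(clustering),
    )


def write_edge_list(graph: nx.Graph, path) -> None:
    """Edge list as TSV (source, target, weight, sign), deterministic order."""
    rows = [
        {
            "source": min(u, v),
            "target": max(u, v),
            "weight": d.get("weight", 1.0),
            "sign": d.get("sign", 1),
        }
        for u, v, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])
    if len(df):
        df = df.sort_values(["source", "target"])
    df.to_csv(path, sep="\t", index=False)
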