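"""Correlation networks, enhancement, RMT threshold, topology vs oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rhizodiel import (
    AbundanceMatrix,
    CorrelationMatrix,
    build_network,
    correlation_matrix,
    doubly_stochastic,
    er_random_graph,
    network_enhancement,
    rmt_threshold,
    subnetwork_by_timepoint,
    topology_metrics,
)


def abund_from(X):
    X = np.asarray(X, dtype=float)
    return AbundanceMatrix(
        [f"s{i}" for i in range(X.shape[0])],
        [f"g{j}" for j in range(X.shape[1])],
        X - X.min() + 1e-6,
        "normalized_counts",
    )


# ---------------------------------------------------------------- oracles


def brute_betweenness(G):
    """Normalized betweenness by explicit shortest-path enumeration."""
    nodes = list(G.nodes)
    n = len(nodes)
    acc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            acc[v] += sum(v in p for p in paths) / len(paths)
    scale = (n - 1) * (n - 2) / 2
    return {v: acc[v] / scale for v in nodes} if scale > 0 else acc


def brute_closeness(G):
    """(n_component − 1) / Σ distances within each connected component."""
    out = {}
    for v in G.nodes:
        lengths = nx.single_source_shortest_path_length(G, v)
        total = sum(lengths.values())
        out[v] = (len(lengths) - 1) / total if total > 0 else 0.0
    return out


def brute_modularity(G, communities):
    m = G.number_of_edges()
    deg = dict(G.degree())
    q = 0.0
    for block in communities:
        for u in block:
            for v in block:
                a = 1.0 if G.has_edge(u, v) else 0.0
                q += a - deg[u] * deg[v] / (2 * m)
    return q / (2 * m)


def all_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in all_partitions(items[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


# ---------------------------------------------------------------- tests


class TestCorrelation:
    def test_duplicate_genus_correlates_perfectly(self, rng):
        x = rng.normal(size=10)
        corr = correlation_matrix(abund_from(np.column_stack([x, x, rng.normal(size=10)])))
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_antirank_pair_is_minus_one_spearman(self, rng):
        x = np.arange(10, dtype=float)
        corr = correlation_matrix(abund_from(np.column_stack([x, -x])))
        assert corr.values[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_mostly_uncorrelated(self, rng):
        X = rng.standard_normal((200, 30))
        corr = correlation_matrix(abund_from(X))
        off = np.abs(corr.values[np.triu_indices(30, 1)])
        assert np.quantile(off, 0.95) < 0.2

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="≥ 4 samples"):
            correlation_matrix(abund_from(rng.normal(size=(3, 5))))

    def test_zero_variance_genus_excluded(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 2.0
        corr = correlation_matrix(abund_from(X))
        assert corr.genus_ids == ["g0", "g2"]


class TestNetworkEnhancement:
    def test_doubly_stochastic_contract(self, rng):
        W = np.abs(rng.normal(size=(30, 30)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        _, T = network_enhancement(W, return_intermediate=True)
        assert np.abs(T.sum(axis=1) - 1).max() < 1e-8
        assert np.abs(T.sum(axis=0) - 1).max() < 1e-8

    def test_output_symmetric_nonnegative(self, rng):
        W = np.abs(rng.normal(size=(25, 25)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        out = network_enhancement(W)
        assert np.abs(out - out.T).max() < 1e-10
        assert out.min() >= 0

    def test_two_block_ratio_increases(self, rng):
        n, half = 40, 20
        W = 0.1 + 0.05 * rng.random((n, n))
        W[:half, :half] += 0.7
        W[half:, half:] += 0.7
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        out = network_enhancement(W)
        iu = np.triu_indices(half, 1)

        def ratio(M):
            within = np.r_[M[:half, :half][iu], M[half:, half:][iu]].mean()
            between = M[:half, half:].mean()
            return within / max(between, 1e-300)

        assert ratio(out) > ratio(W)

    def test_asymmetric_input_rejected(self, rng):
        W = rng.random((10, 10))
        with pytest.raises(ValueError, match="symmetric"):
            network_enhancement(W)

    def test_large_k_clipped_with_warning(self, rng):
        W = np.abs(rng.normal(size=(8, 8)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        with pytest.warns(UserWarning, match="clipping"):
            network_enhancement(W, k_neighbors=10)

    def test_sinkhorn_requires_support(self):
        with pytest.raises(ValueError, match="empty row"):
            doubly_stochastic(np.zeros((3, 3)))


class TestRmtThreshold:
    def test_small_matrix_rejected(self):
        cm = CorrelationMatrix([f"g{i}" for i in range(5)], np.eye(5), "pearson")
        with pytest.raises(ValueError, match="< 20"):
            rmt_threshold(cm)

    def test_uncoupled_blocks_poisson_at_grid_minimum(self, rng):
        n, b = 60, 10
        M = np.zeros((n, n))
        for k in range(n // b):
            blk = rng.uniform(0.5, 0.9, (b, b))
            M[k * b:(k + 1) * b, k * b:(k + 1) * b] = (blk + blk.T) / 2
        np.fill_diagonal(M, 1.0)
        cm = CorrelationMatrix([f"g{i}" for i in range(n)], M, "pearson")
        res = rmt_threshold(cm)
        assert res.reached_poisson
        assert res.threshold == pytest.approx(0.30)

    def test_goe_like_matrix_warns_and_returns_grid_max(self, rng):
        X = rng.standard_normal((400, 50))
        corr = np.corrcoef(X, rowvar=False)
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        cm = CorrelationMatrix([f"g{i}" for i in range(50)], corr, "pearson")
        grid = [0.05, 0.10]  # well inside the correlated (GOE) regime
        with pytest.warns(UserWarning, match="grid max"):
            res = rmt_threshold(cm, grid=grid)
        assert not res.reached_poisson
        assert res.threshold == pytest.approx(0.10)

    @pytest.mark.filterwarnings("ignore:no grid point reached")
    def test_diagnostics_cover_grid(self, rng):
        X = rng.standard_normal((100, 25))
        cm = correlation_matrix(abund_from(X), method="pearson")
        res = rmt_threshold(cm, grid=np.arange(0.3, 0.61, 0.05))
        assert len(res.per_grid) == 7


class TestBuildNetwork:
    def test_extreme_thresholds(self, rng):
        X = rng.standard_normal((100, 10))
        corr = correlation_matrix(abund_from(X), method="pearson")
        assert build_network(corr, 0.999).number_of_edges() == 0
        dense = build_network(corr, 1e-9)
        assert dense.number_of_edges() == 10 * 9 / 2

    def test_planted_modules_recovered(self, rng):
        """Louvain communities on the thresholded graph recover the two
        planted sample-correlation blocks."""
        n_samples, half = 300, 10
        shared_a = rng.standard_normal(n_samples)
        shared_b = rng.standard_normal(n_samples)
        X = np.column_stack(
            [shared_a + 0.4 * rng.standard_normal(n_samples) for _ in range(half)]
            + [shared_b + 0.4 * rng.standard_normal(n_samples) for _ in range(half)]
        )
        corr = correlation_matrix(abund_from(X), method="pearson")
        g = build_network(corr, 0.5)
        comms = nx.community.louvain_communities(g, seed=1)
        assert len(comms) == 2
        planted = [{f"g{j}" for j in range(half)}, {f"g{j}" for j in range(half, 2 * half)}]
        assert {frozenset(c) for c in comms} == {frozenset(p) for p in planted}

    def test_isolated_nodes_dropped_or_kept(self, rng):
        X = rng.standard_normal((50, 12))
        corr = correlation_matrix(abund_from(X), method="pearson")
        dropped = build_network(corr, 0.95)
        kept = build_network(corr, 0.95, keep_isolated=True)
        assert dropped.number_of_nodes() <= kept.number_of_nodes() == 12


class TestSubnetwork:
    def make_graph_and_presence(self, rng, absent_half=False):
        X = np.abs(rng.normal(size=(12, 8))) + 0.5
        if absent_half:
            X[:, 4:] = 0.0
        sids, meta = [], []
        from rhizodiel import SampleMetadata

        k = 0
        for t in range(1, 7):
            for r in (1, 2):
                sid = f"s{k}"
                k += 1
                sids.append(sid)
                meta.append(
                    SampleMetadata(sid, "LD", "rhizosphere", t, "AM" if t % 2 else "PM", r)
                )
        abund = AbundanceMatrix(sids, [f"g{j}" for j in range(8)], X, "normalized_counts")
        graph = nx.complete_graph(8)
        graph = nx.relabel_nodes(graph, {i: f"g{i}" for i in range(8)})
        nx.set_edge_attributes(graph, 1.0, "weight")
        return graph, abund, meta

    def test_all_present_returns_parent(self, rng):
        graph, abund, meta = self.make_graph_and_presence(rng)
        sub = subnetwork_by_timepoint(graph, abund, meta, 1)
        assert set(sub.nodes) == set(graph.nodes)
        assert sub.number_of_edges() == graph.number_of_edges()

    def test_absent_half_excluded(self, rng):
        graph, abund, meta = self.make_graph_and_presence(rng, absent_half=True)
        sub = subnetwork_by_timepoint(graph, abund, meta, 3)
        assert set(sub.nodes) == {f"g{j}" for j in range(4)}

    def test_monotone_in_parent(self, rng):
        graph, abund, meta = self.make_graph_and_presence(rng, absent_half=True)
        sub = subnetwork_by_timepoint(graph, abund, meta, 2)
        assert sub.number_of_nodes() <= graph.number_of_nodes()
        assert sub.number_of_edges() <= graph.number_of_edges()


class TestErGraph:
    def test_complete_and_empty(self):
        assert er_random_graph(10, 45, seed=0).number_of_edges() == 45
        assert nx.density(er_random_graph(10, 45, seed=0)) == 1.0
        assert er_random_graph(10, 0, seed=0).number_of_edges() == 0

    def test_infeasible_edge_count(self):
        with pytest.raises(ValueError, match="infeasible"):
            er_random_graph(5, 11, seed=0)

    def test_exact_edge_count_and_determinism(self):
        g1 = er_random_graph(30, 100, seed=9)
        g2 = er_random_graph(30, 100, seed=9)
        assert g1.number_of_edges() == 100
        assert set(g1.edges) == set(g2.edges)


class TestTopologyMetrics:
    def test_star_center_betweenness(self):
        star = nx.star_graph(4)  # center 0 + 4 leaves
        nx.set_edge_attributes(star, 1.0, "weight")
        m = topology_metrics(star, seed=0)
        bc = nx.betweenness_centrality(star, normalized=True)
        assert bc[0] == pytest.approx(1.0)
        assert all(bc[v] == 0 for v in range(1, 5))
        assert m.average_degree == pytest.approx(2 * 4 / 5)

    def test_complete_k4_closeness_one_single_module(self):
        k4 = nx.complete_graph(4)
        nx.set_edge_attributes(k4, 1.0, "weight")
        m = topology_metrics(k4, seed=0)
        assert m.mean_normalized_closeness == pytest.approx(1.0)
        assert m.n_modules == 1
        assert m.mean_clustering_coefficient == pytest.approx(1.0)
        assert m.density == pytest.approx(1.0)

    def test_bridged_cliques_modules_and_bridge_betweenness(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        nx.set_edge_attributes(g, 1.0, "weight")
        m = topology_metrics(g, seed=0)
        assert m.n_modules == 2
        bc = brute_betweenness(g)
        ref = nx.betweenness_centrality(g, normalized=True)
        for v in g.nodes:
            assert ref[v] == pytest.approx(bc[v], abs=1e-12)
        top2 = sorted(g.nodes, key=lambda v: -bc[v])[:2]
        assert set(top2) == {0, 5}

    def test_matches_brute_force_on_small_graphs(self, rng):
        """Centralities equal path enumeration; the Louvain partition's
        modularity equals its brute-force evaluation and is bounded by the
        exhaustive maximum over all partitions."""
        for _ in range(25):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, rng.uniform(0.3, 0.8), seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            nx.set_edge_attributes(g, 1.0, "weight")
            m = topology_metrics(g, seed=1)
            bc = brute_betweenness(g)
            cc = brute_closeness(g)
            assert m.mean_normalized_betweenness == pytest.approx(
                np.mean(list(bc.values())), abs=1e-12
            )
            assert m.mean_normalized_closeness == pytest.approx(
                np.mean(list(cc.values())), abs=1e-12
            )
            comms = nx.community.louvain_communities(g, weight="weight", seed=1)
            assert m.modularity == pytest.approx(brute_modularity(g, comms), abs=1e-12)
            best = max(
                brute_modularity(g, [set(b) for b in part])
                for part in all_partitions(list(g.nodes))
            )
            assert m.modularity <= best + 1e-9

    def test_single_node_conventions(self):
        g = nx.Graph()
        g.add_node("a")
        m = topology_metrics(g, seed=0)
        assert m.n_modules == 1
        assert m.mean_normalized_closeness == 0.0
        assert m.mean_normalized_betweenness == 0.0
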