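"""Connectome construction, Leiden partitioning, HITS and its bootstrap."""

import numpy as np
import pytest

from ecokit import network, simulate
from ecokit.exceptions import ConfigurationError, InputError
from ecokit.network import (
    _hits_matrix,
    bootstrap_hits,
    build_network,
    hits_scores,
    partition_leiden,
    top_edge_filter,
)


def oracle_hits(w, tol=1e-13):
    """Independent power iteration: a <- W^T h, h <- W a, L1-normalized."""
    n = w.shape[0]
    h = np.ones(n) / n
    while True:
        a = w.T @ h
        a /= a.sum()
        h_new = w @ a
        h_new /= h_new.sum()
        if np.abs(h_new - h).sum() < tol:
            return h_new, a
        h = h_new


class TestBuildNetwork:
    def test_self_loop_removed_and_counted(self):
        conn = build_network(["A", "B"], [("A", "A", 0.5), ("A", "B", 1.0)])
        assert conn.removed_self_loops == 1
        assert list(conn.graph.edges) == [("A", "B")]

    def test_directionality_preserved(self):
        conn = build_network(["A", "B"], [("A", "B", 1.0), ("B", "A", 2.0)])
        assert conn.graph.edges["A", "B"]["weight"] == 1.0
        assert conn.graph.edges["B", "A"]["weight"] == 2.0

    def test_isolated_region_retained(self):
        conn = build_network(["A", "B", "C"], [("A", "B", 1.0)])
        assert "C" in conn.graph
        assert conn.graph.degree("C") == 0

    def test_negative_weight_rejected(self):
        with pytest.raises(InputError):
            build_network(["A", "B"], [("A", "B", -1.0)])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(InputError):
            build_network(["A"], [("A", "Z", 1.0)])

    def test_round_trip_lossless_except_self_loops(self):
        g = simulate.simulate_connectome(simulate.NetworkSimConfig(seed=5))
        edges = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
        conn = build_network(list(g.nodes), edges)
        out = [(u, v, d["weight"]) for u, v, d in conn.graph.edges(data=True)]
        assert sorted(out) == sorted(edges)
        assert conn.removed_self_loops == 0


class TestHits:
    def test_star_graph(self):
        conn = build_network(
            ["A", "B", "C", "D"], [("A", x, 1.0) for x in ("B", "C", "D")]
        )
        hubs, auths = hits_scores(conn)
        assert hubs["A"] == pytest.approx(1.0)
        for x in ("B", "C", "D"):
            assert hubs[x] == pytest.approx(0.0, abs=1e-9)
            assert auths[x] == pytest.approx(1 / 3)
        assert auths["A"] == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        edges = [("A", "B", 1.0), ("B", "C", 2.0), ("C", "A", 0.5), ("A", "C", 1.5)]
        scaled = [(u, v, 7.0 * w) for u, v, w in edges]
        h1, a1 = hits_scores(build_network(list("ABC"), edges))
        h2, a2 = hits_scores(build_network(list("ABC"), scaled))
        for n in "ABC":
            assert h1[n] == pytest.approx(h2[n], abs=1e-8)
            assert a1[n] == pytest.approx(a2[n], abs=1e-8)

    def test_no_edges_rejected(self):
        with pytest.raises(InputError):
            hits_scores(build_network(["A", "B"], []))

    def test_matches_power_iteration_oracle_small_graphs(self, rng):
        """Score equality with the independent oracle on random graphs of
        up to 8 nodes, for both the public API and the bootstrap kernel."""
        for _ in range(60):
            n = int(rng.integers(2, 9))
            w = (rng.random((n, n)) < 0.5) * rng.random((n, n))
            np.fill_diagonal(w, 0.0)
            if not w.any():
                continue
            h_o, a_o = oracle_hits(w)
            regions = [f"R{i}" for i in range(n)]
            edges = [
                (regions[i], regions[j], w[i, j])
                for i in range(n)
                for j in range(n)
                if w[i, j]
            ]
            hubs, auths = hits_scores(build_network(regions, edges))
            assert np.allclose([hubs[r] for r in regions], h_o, atol=1e-8)
            assert np.allclose([auths[r] for r in regions], a_o, atol=1e-8)
            h_m, a_m = _hits_matrix(w)
            assert np.allclose(h_m, h_o, atol=1e-10)
            assert np.allclose(a_m, a_o, atol=1e-10)

    def test_planted_source_has_zero_authority(self):
        # a node with out-edges only cannot be an authority
        conn = build_network(
            ["H", "X", "Y", "Z"],
            [("H", "X", 2.0), ("H", "Y", 2.0), ("X", "Y", 1.0), ("Y", "X", 1.0)],
        )
        _, auths = hits_scores(conn)
        assert auths["H"] == pytest.approx(0.0, abs=1e-9)


class TestLeiden:
    def test_two_cliques_recovered_exactly(self):
        regions = [f"R{i}" for i in range(10)]
        edges = []
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        edges.append((regions[i], regions[j], 1.0))
        part = partition_leiden(build_network(regions, edges), seed=1)
        assert part.n_communities == 2
        assert {frozenset(c) for c in part.communities()} == {
            frozenset(regions[:5]),
            frozenset(regions[5:]),
        }

    def test_single_node(self):
        part = partition_leiden(build_network(["A"], []), seed=0)
        assert part.n_communities == 1

    def test_uniform_complete_graph_one_community(self):
        regions = [f"R{i}" for i in range(8)]
        edges = [
            (a, b, 1.0) for a in regions for b in regions if a != b
        ]
        part = partition_leiden(build_network(regions, edges), seed=0)
        assert part.n_communities == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(InputError):
            partition_leiden(network.Connectome(graph=__import__("networkx").DiGraph()))

    def test_seed_determinism(self):
        g = simulate.simulate_connectome(simulate.NetworkSimConfig(seed=2))
        conn = build_network(
            list(g.nodes), [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
        )
        p1 = partition_leiden(conn, seed=9)
        p2 = partition_leiden(conn, seed=9)
        assert p1.membership == p2.membership

    def test_matches_sklearn_ari_oracle(self):
        """The in-package adjusted Rand index agrees with scikit-learn."""
        from sklearn.metrics import adjusted_rand_score

        from ecokit.validation import adjusted_rand_index

        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 4, size=30)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_quality_increases_with_module_contrast(self):
        qualities = []
        for p_within in (0.2, 0.4, 0.6, 0.8):
            vals = []
            for seed in range(5):
                g = simulate.simulate_connectome(
                    simulate.NetworkSimConfig(
                        n_nodes=30, module_sizes=(15, 15),
                        p_within=p_within, p_between=0.05, seed=seed,
                    )
                )
                conn = build_network(
                    list(g.nodes),
                    [(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
                )
                vals.append(partition_leiden(conn, seed=seed).quality)
            qualities.append(np.mean(vals))
        assert all(b > a for a, b in zip(qualities, qualities[1:]))


class TestBootstrap:
    def _setup(self):
        g = simulate.simulate_connectome(
            simulate.NetworkSimConfig(
                n_nodes=30, module_sizes=(30,), p_within=0.3, p_between=0.3, seed=4
            )
        )
        edges = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
        members = [f"N{i:03d}" for i in range(10)]
        return list(g.nodes), members, edges

    def test_reproducible_under_seed(self):
        pool, members, edges = self._setup()
        a = bootstrap_hits("N000", pool, members, edges, n_iter=50, seed=3)
        b = bootstrap_hits("N000", pool, members, edges, n_iter=50, seed=3)
        assert (a.z_hub, a.z_authority, a.p_hub) == (b.z_hub, b.z_authority, b.p_hub)

    def test_pool_must_exceed_network(self):
        pool, members, edges = self._setup()
        with pytest.raises(InputError):
            bootstrap_hits("N000", members, members, edges, n_iter=10, seed=0)

    def test_degenerate_sd_reported(self):
        # a pool whose every subgraph gives the target identical scores
        regions = [f"R{i}" for i in range(6)]
        edges = [("R0", r, 1.0) for r in regions[1:]]  # only R0 has out-edges
        res = bootstrap_hits("R0", regions, regions[:4], edges, n_iter=20, seed=0)
        assert res.sd_degenerate
        assert np.isnan(res.p_hub)

    def test_one_tailed_p_matches_z(self):
        from scipy.stats import norm

        pool, members, edges = self._setup()
        res = bootstrap_hits("N001", pool, members, edges, n_iter=100, seed=1)
        if not res.sd_degenerate:
            assert res.p_hub == pytest.approx(float(norm.sf(res.z_hub)))


class TestTopEdgeFilter:
    def test_top_five_of_hundred(self, rng):
        regions = [f"R{i}" for i in range(25)]
        edges = []
        pairs = [(a, b) for a in regions for b in regions if a != b]
        idx = rng.choice(len(pairs), size=100, replace=False)
        for rank, i in enumerate(idx):
            edges.append((*pairs[i], float(rank)))
        conn = build_network(regions, edges)
        top = top_edge_filter(conn, fraction=0.05)
        assert len(top) == 5
        assert sorted(w for _, _, w in top) == [95.0, 96.0, 97.0, 98.0, 99.0]

    def test_fraction_one_keeps_all(self):
        conn = build_network(["A", "B", "C"], [("A", "B", 1.0), ("B", "C", 2.0)])
        assert len(top_edge_filter(conn, fraction=1.0)) == 2

    def test_tie_break_deterministic_documented_order(self):
        conn = build_network(
            ["A", "B", "C", "D"],
            [("A", "B", 1.0), ("C", "D", 1.0), ("B", "C", 1.0)],
        )
        # all weights tie: the first two edges in the graph's documented
        # edge-iteration order (grouped by source node) are kept
        top = top_edge_filter(conn, fraction=0.34)  # ceil(0.34*3) = 2
        assert top == [("A", "B", 1.0), ("B", "C", 1.0)]
        assert top == top_edge_filter(conn, fraction=0.34)  # deterministic

    def test_bad_fraction_rejected(self):
        conn = build_network(["A", "B"], [("A", "B", 1.0)])
        with pytest.raises(ConfigurationError):
            top_edge_filter(conn, fraction=0.0)
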