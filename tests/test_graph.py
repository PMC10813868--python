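"""Graph measures vs brute-force oracles, networkx cross-checks and null models."""

import itertools

import networkx as nx
import numpy as np
import pytest

from connqc import (average_node_degree, make_null_ensemble, normalized_measures,
                    weighted_clustering, weighted_global_efficiency)
from connqc.graph import rewire_preserving_degree


def matrix(n, edges):
    W = np.zeros((n, n))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return W


def brute_force_clustering(W):
    """Onnela weighted clustering by explicit triangle enumeration."""
    n = W.shape[0]
    Wn = W / W.max()
    k = (W > 0).sum(axis=1)
    cs = []
    for i in range(n):
        if k[i] < 2:
            cs.append(0.0)
            continue
        tot = 0.0
        for j, h in itertools.combinations(range(n), 2):
            if j == i or h == i:
                continue
            tot += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1 / 3)
        cs.append(2 * tot / (k[i] * (k[i] - 1)))
    return float(np.mean(cs))


def brute_force_efficiency(W):
    """Mean inverse shortest path by exhaustive path enumeration (tiny n)."""
    n = W.shape[0]
    nodes = range(n)
    best = {}
    for i, j in itertools.combinations(nodes, 2):
        d = np.inf
        for k in range(n - 1):
            for mid in itertools.permutations(set(nodes) - {i, j}, k):
                path = (i, *mid, j)
                if all(W[a, b] > 0 for a, b in zip(path, path[1:])):
                    d = min(d, sum(1.0 / W[a, b] for a, b in zip(path, path[1:])))
        best[(i, j)] = d
    inv = [1.0 / d if np.isfinite(d) else 0.0 for d in best.values()]
    return float(np.mean(inv))


class TestDegree:
    def test_complete_and_path_graphs(self):
        K4 = matrix(4, [(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)])
        assert average_node_degree(K4) == 3.0
        P3 = matrix(3, [(0, 1, 1.0), (1, 2, 1.0)])
        assert average_node_degree(P3) == pytest.approx(4 / 3)

    def test_invariant_to_positive_reweighting(self, rng):
        W = matrix(6, [(0, 1, 0.5), (1, 2, 0.1), (3, 4, 2.0)])
        assert average_node_degree(3.7 * W) == average_node_degree(W)


class TestClustering:
    def test_triangle_and_star(self):
        tri = matrix(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        assert weighted_clustering(tri) == pytest.approx(1.0)
        star = matrix(5, [(0, i, 1.0) for i in range(1, 5)])
        assert weighted_clustering(star) == 0.0

    def test_weighted_toy_matches_triangle_enumeration(self):
        W = matrix(4, [(0, 1, 0.9), (0, 2, 0.4), (1, 2, 0.7), (2, 3, 0.2)])
        assert weighted_clustering(W) == pytest.approx(brute_force_clustering(W),
                                                       abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_graphs_match_oracle_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.random((8, 8)) * (rng.random((8, 8)) < 0.5)
        W = np.triu(W, 1)
        W = W + W.T
        if W.max() == 0:
            pytest.skip("empty draw")
        assert weighted_clustering(W) == pytest.approx(brute_force_clustering(W),
                                                       abs=1e-10)
        G = nx.from_numpy_array(W)
        assert weighted_clustering(W) == pytest.approx(
            nx.average_clustering(G, weight="weight"), abs=1e-10)

    def test_binary_weights_reduce_to_binary_clustering(self, rng):
        A = (rng.random((8, 8)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        G = nx.from_numpy_array(A)
        assert weighted_clustering(A) == pytest.approx(nx.average_clustering(G),
                                                       abs=1e-12)


class TestEfficiency:
    def test_complete_unit_graph(self):
        K5 = matrix(5, [(i, j, 1.0) for i, j in itertools.combinations(range(5), 2)])
        assert weighted_global_efficiency(K5) == pytest.approx(1.0)

    def test_three_node_path(self):
        P3 = matrix(3, [(0, 1, 1.0), (1, 2, 1.0)])
        assert weighted_global_efficiency(P3) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_disconnected_pairs_contribute_zero(self):
        two_dyads = matrix(4, [(0, 1, 1.0), (2, 3, 1.0)])
        # 2 of 6 pairs connected at distance 1
        assert weighted_global_efficiency(two_dyads) == pytest.approx(2 / 6)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.random((6, 6)) * (rng.random((6, 6)) < 0.6)
        W = np.triu(W, 1)
        W = W + W.T
        assert weighted_global_efficiency(W) == pytest.approx(
            brute_force_efficiency(W), abs=1e-10)
        # binary cross-check against networkx global_efficiency
        A = (W > 0).astype(float)
        assert weighted_global_efficiency(A) == pytest.approx(
            nx.global_efficiency(nx.from_numpy_array(A)), abs=1e-10)

    def test_monotone_under_weight_increase(self, rng):
        W = matrix(5, [(0, 1, 0.5), (1, 2, 0.3), (2, 3, 0.8), (3, 4, 0.2)])
        e0 = weighted_global_efficiency(W)
        W2 = W.copy()
        W2[0, 4] = W2[4, 0] = 0.1  # add edge
        assert weighted_global_efficiency(W2) >= e0
        W3 = W.copy()
        W3[1, 2] = W3[2, 1] = 0.9  # strengthen edge
        assert weighted_global_efficiency(W3) >= e0


class TestNullEnsemble:
    def test_degree_sequence_preserved(self, rng):
        W = rng.random((20, 20)) * (rng.random((20, 20)) < 0.3)
        W = np.triu(W, 1)
        W = W + W.T
        deg = (W > 0).sum(axis=1)
        Wn = rewire_preserving_degree(W, np.random.default_rng(5))
        np.testing.assert_array_equal((Wn > 0).sum(axis=1), deg)
        # weights travel with edges: the multiset of weights is unchanged
        np.testing.assert_allclose(np.sort(Wn[Wn > 0]), np.sort(W[W > 0]))

    def test_complete_graph_is_rigid(self):
        K6 = matrix(6, [(i, j, 1.0 + i + j)
                        for i, j in itertools.combinations(range(6), 2)])
        Wn = rewire_preserving_degree(K6, np.random.default_rng(0), swaps_per_edge=2)
        np.testing.assert_allclose(Wn, K6)

    def test_seeded_reproducibility(self, rng):
        W = rng.random((15, 15)) * (rng.random((15, 15)) < 0.4)
        W = np.triu(W, 1) + np.triu(W, 1).T
        e1 = make_null_ensemble(W, n_null=5, seed=42)
        e2 = make_null_ensemble(W, n_null=5, seed=42)
        np.testing.assert_array_equal(e1.clustering, e2.clustering)
        np.testing.assert_array_equal(e1.efficiency, e2.efficiency)

    def test_swap_sequence_matches_independent_trace(self):
        """Re-derive the rewired topology by replaying the documented
        algorithm (block-drawn indices, orientation flip, validity rules)
        against an identical RNG stream."""
        rng = np.random.default_rng(7)
        W = matrix(6, [(0, 1, 1.0), (2, 3, 1.0), (4, 5, 1.0), (0, 2, 1.0),
                       (1, 4, 1.0), (3, 5, 1.0)])
        got = rewire_preserving_degree(W, np.random.default_rng(99), swaps_per_edge=2)

        # independent trace with the same stream
        trace_rng = np.random.default_rng(99)
        iu = np.triu_indices(6, 1)
        present = W[iu] > 0
        u = list(iu[0][present])
        v = list(iu[1][present])
        edges = {tuple(sorted(e)) for e in zip(u, v)}
        m = len(u)
        target = 2 * m
        block = max(256, 2 * target)
        swaps = attempts = 0
        while swaps < target and attempts < 100 * target:
            ii = trace_rng.integers(m, size=block)
            jj = trace_rng.integers(m, size=block)
            cc = trace_rng.random(block) < 0.5
            for i, j, flip in zip(ii, jj, cc):
                attempts += 1
                if swaps >= target or attempts >= 100 * target:
                    break
                if i == j:
                    continue
                a, b = u[i], v[i]
                c, d = u[j], v[j]
                if flip:
                    c, d = d, c
                if a == d or c == b:
                    continue
                e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
                if e1 in edges or e2 in edges or e1 == e2:
                    continue
                edges.discard(tuple(sorted((a, b))))
                edges.discard(tuple(sorted((c, d))))
                edges.add(e1)
                edges.add(e2)
                u[i], v[i] = e1
                u[j], v[j] = e2
                swaps += 1
        expect = np.zeros((6, 6))
        for a, b in edges:
            expect[a, b] = expect[b, a] = 1.0
        np.testing.assert_array_equal(got > 0, expect > 0)

    def test_too_few_edges_rejected(self):
        W = matrix(4, [(0, 1, 1.0), (2, 3, 1.0)])
        with pytest.raises(ValueError):
            make_null_ensemble(W, n_null=3, seed=0)


class TestNormalization:
    def test_null_drawn_network_normalizes_to_one(self, rng):
        """gamma and e_global of a network drawn from the null family are ~1."""
        W = rng.random((40, 40)) * (rng.random((40, 40)) < 0.2)
        W = np.triu(W, 1) + np.triu(W, 1).T
        base = rewire_preserving_degree(W, np.random.default_rng(11))
        gammas, es = [], []
        for k in range(20):
            draw = rewire_preserving_degree(base, np.random.default_rng(100 + k))
            ens = make_null_ensemble(draw, n_null=20, seed=200 + k)
            g, e = normalized_measures(draw, ens)
            gammas.append(g)
            es.append(e)
        sd_g = np.std([g - 1 for g in gammas]) or 0.05
        sd_e = np.std([e - 1 for e in es]) or 0.02
        assert abs(np.mean(gammas) - 1.0) < 3 * max(sd_g, 0.02)
        assert abs(np.mean(es) - 1.0) < 3 * max(sd_e, 0.01)

    def test_clustered_lattice_has_gamma_above_one(self):
        # ring lattice: each node joined to 2 neighbours either side
        n = 24
        W = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                W[i, j] = W[j, i] = 1.0
        ens = make_null_ensemble(W, n_null=30, seed=1)
        gamma, _ = normalized_measures(W, ens)
        assert gamma > 1.0

    def test_zero_null_mean_is_an_error(self):
        # star graph: no triangles in any degree-preserving rewiring
        W = matrix(6, [(0, i, 1.0) for i in range(1, 6)])
        ens = make_null_ensemble(W, n_null=5, seed=0)
        with pytest.raises(ValueError):
            normalized_measures(W, ens)
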