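"""Connectome surrogates and topology metrics against brute-force oracles."""

import itertools

import numpy as np
import pytest

from neuroentropy import (
    Connectome,
    SurrogateSpec,
    degree_preserving_null,
    generate_connectome,
    rand_null,
    strength_preserving_null,
    topology_metrics,
)
from neuroentropy.nulls import make_surrogate
from neuroentropy.synthetic import SyntheticSpec


def _degrees(c: Connectome) -> np.ndarray:
    return (c.weights > 0).sum(axis=1)


def _edge_count(c: Connectome) -> int:
    return int((np.triu(c.weights) > 0).sum())


def _weight_multiset(c: Connectome) -> np.ndarray:
    w = np.triu(c.weights)
    return np.sort(w[w > 0])


@pytest.fixture(scope="module")
def toy20():
    return generate_connectome(SyntheticSpec(n_regions=20, density=0.25, seed=5))


class TestRandNull:
    def test_preserves_edge_count_and_total_weight(self, toy20):
        for k in range(5):
            sur = rand_null(toy20, rng=k)
            assert _edge_count(sur) == _edge_count(toy20)
            assert sur.weights.sum() == pytest.approx(toy20.weights.sum(), rel=1e-12)

    def test_complete_equal_weight_graph_unchanged_up_to_permutation(self):
        n = 6
        w = np.full((n, n), 0.3)
        np.fill_diagonal(w, 0)
        sur = rand_null(Connectome(weights=w), rng=0)
        np.testing.assert_allclose(sur.weights, w)

    def test_degree_sequence_destroyed(self, toy20):
        orig = np.sort(_degrees(toy20))
        changed = sum(
            not np.array_equal(np.sort(_degrees(rand_null(toy20, rng=k))), orig)
            for k in range(100)
        )
        assert changed > 95

    def test_surrogate_invariants(self, toy20):
        sur = rand_null(toy20, rng=1)
        assert np.allclose(sur.weights, sur.weights.T)
        assert np.all(np.diag(sur.weights) == 0)
        assert np.all(sur.weights >= 0)


class TestDegreePreservingNull:
    def test_preserves_degrees_exactly(self, toy20):
        for k in range(5):
            sur = degree_preserving_null(toy20, rng=k)
            np.testing.assert_array_equal(_degrees(sur), _degrees(toy20))

    def test_preserves_weight_multiset(self, toy20):
        sur = degree_preserving_null(toy20, rng=0)
        np.testing.assert_allclose(
            _weight_multiset(sur), _weight_multiset(toy20), rtol=1e-12
        )

    def test_strength_sequence_destroyed(self, toy20):
        orig = toy20.strength()
        changed = sum(
            not np.allclose(degree_preserving_null(toy20, rng=k).strength(), orig,
                            rtol=1e-6)
            for k in range(50)
        )
        assert changed > 47


class TestStrengthPreservingNull:
    def test_preserves_strengths_within_tolerance(self, toy20):
        for k in range(5):
            sur = strength_preserving_null(toy20, rng=k)
            rel = np.abs(sur.strength() - toy20.strength()) / toy20.strength()
            assert rel.max() <= 1e-3
            np.testing.assert_array_equal(_degrees(sur), _degrees(toy20))

    def test_regular_equal_weight_graph_reproduced_exactly(self):
        # ring lattice: every node degree 4, equal weights
        n = 10
        w = np.zeros((n, n))
        for i in range(n):
            for off in (1, 2):
                w[i, (i + off) % n] = 0.2
                w[(i + off) % n, i] = 0.2
        con = Connectome(weights=w)
        sur = strength_preserving_null(con, rng=0)
        np.testing.assert_allclose(sur.strength(), con.strength(), rtol=1e-12)
        np.testing.assert_allclose(np.unique(sur.weights[sur.weights > 0]), 0.2)

    def test_higher_order_structure_destroyed(self):
        # two dense modules joined by one bridge: clustering should drop
        import networkx as nx

        blocks = np.kron(np.eye(2), np.ones((6, 6)))
        np.fill_diagonal(blocks, 0)
        blocks[0, 6] = blocks[6, 0] = 1.0
        rng = np.random.default_rng(2)
        w = blocks * rng.uniform(0.5, 1.5, size=blocks.shape)
        w = (w + w.T) / 2 * (blocks > 0)
        con = Connectome(weights=w)
        orig_clust = nx.average_clustering(nx.from_numpy_array((w > 0).astype(int)))
        diffs = []
        for k in range(10):
            sur = strength_preserving_null(con, rng=k)
            c = nx.average_clustering(
                nx.from_numpy_array((sur.weights > 0).astype(int))
            )
            diffs.append(abs(c - orig_clust))
        assert max(diffs) > 0.05


class TestPreservationHierarchy:
    @pytest.mark.parametrize("scheme", ["RAND", "DPR", "DSPR"])
    def test_audited_invariants_per_scheme(self, toy20, scheme):
        """Machine-check the preservation ladder on every surrogate: RAND
        keeps edge count + total weight; DPR additionally the degree
        sequence; DSPR additionally the strength sequence."""
        spec = SurrogateSpec(scheme=scheme, n_surrogates=4, seed=11)
        for k in range(spec.n_surrogates):
            sur = make_surrogate(toy20, spec, index=k)
            assert np.allclose(sur.weights, sur.weights.T)
            assert np.all(np.diag(sur.weights) == 0)
            assert np.all(sur.weights >= 0)
            assert _edge_count(sur) == _edge_count(toy20)
            assert sur.weights.sum() == pytest.approx(
                toy20.weights.sum(), rel=1e-6
            )
            if scheme in ("DPR", "DSPR"):
                np.testing.assert_array_equal(_degrees(sur), _degrees(toy20))
            if scheme == "DSPR":
                rel = np.abs(sur.strength() - toy20.strength()) / toy20.strength()
                assert rel.max() <= 1e-3


# ---------------------------------------------------------------------------
# topology metrics vs. independent brute-force computations
# ---------------------------------------------------------------------------


def _all_paths(n, s, t):
    """Every simple path from s to t over nodes 0..n-1."""
    others = [v for v in range(n) if v not in (s, t)]
    for k in range(len(others) + 1):
        for mid in itertools.permutations(others, k):
            yield (s, *mid, t)


def _path_length(path, W):
    total = 0.0
    for a, b in zip(path, path[1:]):
        if W[a, b] == 0:
            return np.inf
        total += 1.0 / W[a, b]
    return total


def brute_betweenness(W):
    n = W.shape[0]
    btw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        lengths = {}
        for path in _all_paths(n, s, t):
            L = _path_length(path, W)
            if np.isfinite(L):
                lengths[path] = L
        best = min(lengths.values())
        shortest = [p for p, L in lengths.items() if np.isclose(L, best, rtol=1e-9)]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(v in p for p in shortest)
            btw[v] += through / len(shortest)
    return btw


def brute_distances(W):
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for s, t in itertools.combinations(range(n), 2):
        best = min(
            (_path_length(p, W) for p in _all_paths(n, s, t)), default=np.inf
        )
        D[s, t] = D[t, s] = best
    return D


def brute_expm(W, terms=80):
    n = W.shape[0]
    acc = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms):
        term = term @ W / k
        acc = acc + term
    return acc


def brute_pagerank(W, alpha=0.85, iters=50_000, tol=1e-14):
    n = W.shape[0]
    P = W / W.sum(axis=1, keepdims=True)
    v = np.full(n, 1.0 / n)
    for _ in range(iters):
        nv = alpha * (P.T @ v) + (1 - alpha) / n
        if np.abs(nv - v).max() < tol:
            return nv
        v = nv
    return v


def brute_eigvec(W, iters=100_000, tol=1e-15):
    v = np.ones(W.shape[0])
    for _ in range(iters):
        nv = W @ v
        nv = nv / np.linalg.norm(nv)
        if np.abs(nv - v).max() < tol:
            break
        v = nv
    return np.abs(v)


class TestTopologyMetrics:
    def test_star_graph_hand_count(self):
        w = np.zeros((5, 5))
        w[0, 1:] = 1.0
        w[1:, 0] = 1.0
        prof = topology_metrics(Connectome(weights=w))
        assert prof.betweenness[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        np.testing.assert_allclose(prof.betweenness[1:], 0.0)

    def test_path_graph_middle_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        prof = topology_metrics(Connectome(weights=w))
        assert prof.betweenness[1] == pytest.approx(1.0)

    def test_all_metrics_match_brute_force(self):
        rng = np.random.default_rng(8)
        n = 8
        w = rng.uniform(0.2, 1.0, size=(n, n)) * (rng.random((n, n)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        # ensure connectivity via a ring backbone
        for i in range(n):
            j = (i + 1) % n
            if w[i, j] == 0:
                w[i, j] = w[j, i] = 0.5
        con = Connectome(weights=w)
        prof = topology_metrics(con)

        np.testing.assert_allclose(
            prof.betweenness, brute_betweenness(w), atol=1e-8
        )
        D = brute_distances(w)
        closeness = (n - 1) / D.sum(axis=1)
        np.testing.assert_allclose(prof.closeness, closeness, rtol=1e-8)
        E = brute_expm(w)
        np.testing.assert_allclose(prof.communicability, E.sum(axis=1), rtol=1e-9)
        np.testing.assert_allclose(prof.subgraph, np.diag(E), rtol=1e-9)
        np.testing.assert_allclose(prof.pagerank, brute_pagerank(w), atol=1e-6)
        ev = brute_eigvec(w)
        np.testing.assert_allclose(
            prof.eigenvector / np.linalg.norm(prof.eigenvector), ev, atol=1e-6
        )
        assert np.all(prof.eigenvector >= 0)
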