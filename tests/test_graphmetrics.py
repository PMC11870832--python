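import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsgraph.connectivity import FCMatrix, WindowSpec, fisher_z
from nirsgraph.graphs import (
    DEFAULT_THRESHOLDS,
    BinaryGraph,
    average_degree,
    binarize,
    global_efficiency,
    metrics_for_subject,
)


def _fc_from_r(r, window=30.0, sid="s"):
    r = np.asarray(r, float)
    np.fill_diagonal(r, 1.0)
    return fisher_z(FCMatrix(r=r, z=np.zeros_like(r),
                             window=WindowSpec(end=window), subject_id=sid))


def _random_fc(rng, n=18):
    a = rng.uniform(-1, 1, (n, n))
    r = np.clip((a + a.T) / 2, -0.99, 0.99)
    return _fc_from_r(r)


def floyd_warshall_efficiency(adj):
    """Independent brute-force oracle: Floyd-Warshall over the dense matrix."""
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


# ---------------------------------------------------------------------------
# average degree
# ---------------------------------------------------------------------------

class TestAverageDegree:
    def test_uniform_offdiagonal_returns_that_value(self):
        fc = _fc_from_r(np.full((18, 18), 0.3))
        fc.z = np.full((18, 18), 0.5)
        np.fill_diagonal(fc.z, 0.0)
        assert average_degree(fc) == pytest.approx(0.5)

    def test_three_node_hand_case(self):
        # off-diagonals {0.1, 0.2, 0.3}: mean of the six entries = 0.2
        z = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]])
        fc = FCMatrix(r=np.tanh(z), z=z, window=WindowSpec(end=30.0))
        np.fill_diagonal(fc.r, 1.0)
        assert average_degree(fc) == pytest.approx(0.2)

    def test_matches_naive_double_loop_oracle(self, rng):
        for _ in range(50):
            fc = _random_fc(rng)
            n = fc.z.shape[0]
            total = sum(
                fc.z[i, j] for i in range(n) for j in range(n) if i != j
            )
            assert average_degree(fc) == pytest.approx(
                total / (n * (n - 1)), abs=1e-12
            )

    def test_permutation_invariance(self, rng):
        fc = _random_fc(rng)
        perm = rng.permutation(18)
        fc_p = FCMatrix(r=fc.r[np.ix_(perm, perm)], z=fc.z[np.ix_(perm, perm)],
                        window=fc.window)
        assert average_degree(fc_p) == pytest.approx(average_degree(fc), abs=1e-12)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

class TestBinarize:
    def test_high_r_gives_complete_graph(self):
        g = binarize(_fc_from_r(np.full((18, 18), 0.9)), 0.5)
        off = ~np.eye(18, dtype=bool)
        assert g.adjacency[off].all()
        assert not g.adjacency.diagonal().any()

    def test_low_r_gives_empty_graph(self):
        g = binarize(_fc_from_r(np.full((18, 18), 0.2)), 0.5)
        assert not g.adjacency.any()

    def test_hand_enumerated_four_node_edge_set(self):
        r = np.array(
            [
                [1.0, 0.6, 0.4, -0.3],
                [0.6, 1.0, 0.55, 0.2],
                [0.4, 0.55, 1.0, 0.7],
                [-0.3, 0.2, 0.7, 1.0],
            ]
        )
        g = binarize(_fc_from_r(r), 0.5)
        edges = {(i, j) for i in range(4) for j in range(i + 1, 4)
                 if g.adjacency[i, j]}
        assert edges == {(0, 1), (1, 2), (2, 3)}  # pairs with r >= 0.5

    def test_negative_correlations_never_make_edges(self, rng):
        r = -np.abs(rng.uniform(0.2, 0.9, (18, 18)))
        r = (r + r.T) / 2
        g = binarize(_fc_from_r(r), 0.1)
        assert not g.adjacency.any()


# ---------------------------------------------------------------------------
# global efficiency
# ---------------------------------------------------------------------------

class TestGlobalEfficiency:
    @pytest.mark.parametrize("n", [2, 5, 18])
    def test_complete_graph_is_one(self, n):
        adj = ~np.eye(n, dtype=bool)
        assert global_efficiency(BinaryGraph(adj, 0.1)) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        adj = np.zeros((18, 18), bool)
        assert global_efficiency(BinaryGraph(adj, 0.5)) == 0.0

    def test_three_node_path_is_five_sixths(self):
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        e = global_efficiency(BinaryGraph(adj, 0.3))
        assert e == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_matches_floyd_warshall_oracle_across_densities(self):
        rng = np.random.default_rng(202)
        for i in range(60):
            n = int(rng.integers(2, 19))
            density = rng.uniform(0, 1)
            a = rng.random((n, n)) < density
            adj = np.triu(a, 1)
            adj = adj | adj.T
            e = global_efficiency(BinaryGraph(adj, 0.1))
            assert e == pytest.approx(floyd_warshall_efficiency(adj), abs=1e-12)

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            adj = np.triu(rng.random((18, 18)) < 0.3, 1)
            adj = adj | adj.T
            g = nx.from_numpy_array(adj.astype(int))
            assert global_efficiency(BinaryGraph(adj, 0.1)) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_efficiency_non_increasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        fc = _random_fc(rng)
        values = [
            global_efficiency(binarize(fc, t)) for t in DEFAULT_THRESHOLDS
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_relabeling_invariance(self, rng):
        fc = _random_fc(rng)
        perm = rng.permutation(18)
        fc_p = FCMatrix(r=fc.r[np.ix_(perm, perm)], z=fc.z[np.ix_(perm, perm)],
                        window=fc.window)
        for t in DEFAULT_THRESHOLDS:
            assert global_efficiency(binarize(fc_p, t)) == pytest.approx(
                global_efficiency(binarize(fc, t)), abs=1e-12
            )


# ---------------------------------------------------------------------------
# per-subject assembly
# ---------------------------------------------------------------------------

class TestMetricsForSubject:
    def test_cardinality_eleven_windows_five_thresholds(self, rng):
        fcs = []
        for w in (1, 2, 3, 5, 8, 10, 12, 15, 20, 25, 30):
            fc = _random_fc(rng)
            fcs.append(FCMatrix(r=fc.r, z=fc.z, window=WindowSpec(end=float(w)),
                                subject_id="s"))
        out = metrics_for_subject(fcs)
        assert len(out) == 11
        assert all(len(m.eglob) == 5 for m in out)
        assert [m.window.end for m in out] == sorted(m.window.end for m in out)

    def test_single_window_single_record(self, rng):
        out = metrics_for_subject([_random_fc(rng)], thresholds=(0.3,))
        assert len(out) == 1
        assert set(out[0].eglob) == {0.3}
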