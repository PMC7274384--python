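from __future__ import annotations

import numpy as np
import pytest

import quantgraph as qg
from quantgraph.metrics import UndefinedMetricError
from quantgraph.segments import InvalidInputError

import oracles


def _ring(n):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = 1.0
        w[(i + 1) % n, i] = 1.0
    return w


def _complete(n):
    w = np.ones((n, n))
    np.fill_diagonal(w, 0.0)
    return w


def _two_triangles():
    w = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[i, j] = w[j, i] = 1.0
    return w


# ---------------------------------------------------------------------------
# closed forms


def test_clustering_coefficient_closed_forms():
    assert qg.clustering_coefficient(_ring(4)) == 0.0  # triangle-free
    assert qg.clustering_coefficient(_complete(3)) == pytest.approx(1.0)


def test_mean_jump_length_closed_forms():
    assert qg.mean_jump_length(np.eye(20)) == 0.0
    Q = 20
    uniform = np.full((Q, Q), 1.0 / Q)
    assert qg.mean_jump_length(uniform) == pytest.approx((Q**2 - 1) / (3 * Q))
    assert qg.mean_jump_length(uniform) == pytest.approx(6.65)
    assert qg.mean_jump_length(np.array([[0.0, 1.0], [1.0, 0.0]])) == 1.0


def test_betweenness_closed_forms():
    assert qg.betweenness_centrality(_complete(5)) == 0.0
    # bidirectional 3-path: the middle node carries both ordered pairs
    path = np.zeros((3, 3))
    path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
    assert qg.betweenness_centrality(path) == pytest.approx(1.0 / 3.0)


def test_modularity_closed_forms():
    part = qg.detect_modules(_two_triangles())
    assert part.modularity == pytest.approx(0.5)
    assert part.n_modules == 2
    # the two modules are exactly the triangles
    assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1
    assert qg.modularity_score(_complete(4), np.zeros(4)) == pytest.approx(0.0)
    # singleton modules with no intra-module edges: M = -sum (d_i/2E)^2 <= 0
    assert qg.modularity_score(_ring(4), np.arange(4)) < 0


def test_laplacian_estrada_closed_forms():
    assert qg.laplacian_estrada_index(np.zeros((7, 7))) == pytest.approx(7.0)
    edge = np.zeros((2, 2))
    edge[0, 1] = edge[1, 0] = 1.0
    assert qg.laplacian_estrada_index(edge) == pytest.approx(1.0 + np.e**2)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence


def _random_graphs(n, density=0.5, row_stochastic=False, min_q=2):
    rng = np.random.default_rng(123)
    for _ in range(n):
        Q = int(rng.integers(min_q, 8))
        yield oracles.random_weight_matrix(
            rng, Q, density=density, row_stochastic=row_stochastic
        )


@pytest.mark.parametrize(
    "fn,oracle,min_q",
    [
        (qg.clustering_coefficient, oracles.cc_brute, 2),
        (qg.mean_jump_length, oracles.mjl_brute, 2),
        (qg.betweenness_centrality, oracles.bc_brute, 3),
        (qg.laplacian_estrada_index, oracles.lee_brute, 2),
    ],
    ids=["CC", "MJL", "BC", "LEE"],
)
def test_metric_matches_brute_force(fn, oracle, min_q):
    for w in _random_graphs(120, min_q=min_q):
        assert fn(w) == pytest.approx(oracle(w), abs=1e-10)


def test_detected_modularity_is_self_consistent():
    """The score returned with a partition equals the definition recomputed."""
    for w in _random_graphs(120):
        if qg.metrics._symmetrized(w).sum() == 0:
            continue
        part = qg.detect_modules(w)
        assert part.modularity == pytest.approx(
            oracles.mo_brute(w, part.labels), abs=1e-10
        )


# ---------------------------------------------------------------------------
# random walk vs trace formula


def test_walk_identity_is_zero():
    est = qg.mean_jump_length_walk(np.eye(4), n_jumps=500, seed=0)
    assert est.mean == 0.0


def test_walk_two_state_swap_is_exactly_one():
    w = np.array([[0.0, 1.0], [1.0, 0.0]])
    est = qg.mean_jump_length_walk(w, n_jumps=1000, seed=1)
    assert est.mean == 1.0


def test_walk_restarts_at_dead_ends_without_counting():
    # node 1 always jumps to node 2; node 2 is a dead end, so the walk
    # restarts at node 1 and every counted jump has length exactly 1
    w = np.array([[0.0, 1.0], [0.0, 0.0]])
    est = qg.mean_jump_length_walk(w, n_jumps=200, seed=2)
    assert est.mean == 1.0


def test_walk_reproducible_and_errors():
    w = np.array([[0.5, 0.5], [0.5, 0.5]])
    a = qg.mean_jump_length_walk(w, n_jumps=2000, seed=9)
    b = qg.mean_jump_length_walk(w, n_jumps=2000, seed=9)
    assert a.mean == b.mean
    with pytest.raises(InvalidInputError):
        qg.mean_jump_length_walk(np.zeros((3, 3)), n_jumps=10, seed=0)


def test_walk_agrees_with_trace_on_doubly_stochastic():
    """With a uniform stationary law the walk estimate matches the closed form."""
    rng = np.random.default_rng(17)
    # symmetric row-stochastic => doubly stochastic
    m = rng.random((5, 5))
    m = (m + m.T) / 2
    w = m / m.sum(axis=1, keepdims=True)
    w = (w + w.T) / 2  # repair asymmetry from normalisation
    w = w / w.sum(axis=1, keepdims=True)
    for _ in range(60):  # Sinkhorn balancing to double stochasticity
        w = w / w.sum(axis=0, keepdims=True)
        w = w / w.sum(axis=1, keepdims=True)
    est = qg.mean_jump_length_walk(w, n_jumps=100_000, seed=4)
    assert abs(est.mean - qg.mean_jump_length(w)) < 3 * est.stderr


# ---------------------------------------------------------------------------
# invariances and bounds


def _permuted(w, perm):
    return w[np.ix_(perm, perm)]


def test_permutation_invariance_of_structural_metrics():
    rng = np.random.default_rng(21)
    w = oracles.random_weight_matrix(rng, 6, density=0.6)
    perm = rng.permutation(6)
    wp = _permuted(w, perm)
    for fn in (
        qg.clustering_coefficient,
        qg.betweenness_centrality,
        qg.laplacian_estrada_index,
        qg.modularity,
    ):
        assert fn(wp) == pytest.approx(fn(w), abs=1e-9)


def test_mean_jump_length_is_not_permutation_invariant():
    # MJL reads node indices as positions on the quantile axis
    w = np.zeros((3, 3))
    w[0, 1] = 1.0  # jump of length 1
    perm = np.array([0, 2, 1])  # now the arc is 1 -> 3: jump of length 2
    assert qg.mean_jump_length(w) != qg.mean_jump_length(_permuted(w, perm))


def test_mjl_bounds_and_zero_iff_diagonal():
    rng = np.random.default_rng(31)
    for _ in range(50):
        Q = int(rng.integers(2, 9))
        w = oracles.random_weight_matrix(rng, Q, row_stochastic=True)
        v = qg.mean_jump_length(w)
        assert 0.0 <= v <= Q - 1
        off = w.copy()
        np.fill_diagonal(off, 0.0)
        assert (v == 0.0) == (off.sum() == 0.0)


def test_all_metrics_finite_on_transition_matrices():
    rng = np.random.default_rng(8)
    for _ in range(10):
        values = rng.normal(size=128)
        for k in (1, 5, 20):
            w = qg.transition_matrix_for_segment(values, k)
            for name, fn in qg.METRICS.items():
                assert np.isfinite(fn(w)), name


def test_metric_error_cases():
    with pytest.raises(InvalidInputError):
        qg.betweenness_centrality(np.zeros((2, 2)))
    with pytest.raises(UndefinedMetricError):
        qg.modularity_score(np.zeros((4, 4)), np.zeros(4))
    # edgeless graph: detection falls back to one module with M = 0
    assert qg.detect_modules(np.zeros((4, 4))).modularity == 0.0
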