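from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quantgraph as qg
from quantgraph.core import DegeneratePartitionError
from quantgraph.segments import InvalidInputError

from conftest import REFERENCE_BOUNDARIES, REFERENCE_Q, REFERENCE_T


# ---------------------------------------------------------------------------
# quantile count rule


@pytest.mark.parametrize(
    "T,expected",
    [
        (1024, 20),  # the study's 8 s x 128 Hz segments
        (8, 4),      # 2 * 8^(1/3) = 4 exactly
        (1000, 20),  # 2 * 1000^(1/3) = 20 exactly
        (2, 3),      # 2 * 2^(1/3) = 2.52, rounded half-up
        (27, 6),
    ],
)
def test_default_num_quantiles(T, expected):
    assert qg.default_num_quantiles(T) == expected


def test_default_num_quantiles_rejects_short_series():
    with pytest.raises(InvalidInputError):
        qg.default_num_quantiles(1)


# ---------------------------------------------------------------------------
# partition fitting


def _series_with_sorted_anchors():
    """20 values whose sorted 0-based positions 0,4,8,12,16 and the maximum
    equal the reference boundaries."""
    b = REFERENCE_BOUNDARIES
    sorted_vals = np.concatenate(
        [
            [b[0]], np.linspace(b[0], b[1], 5)[1:4],
            [b[1]], np.linspace(b[1], b[2], 5)[1:4],
            [b[2]], np.linspace(b[2], b[3], 5)[1:4],
            [b[3]], np.linspace(b[3], b[4], 5)[1:4],
            [b[4]], np.linspace(b[4], b[5], 4)[1:3],
            [b[5]],
        ]
    )
    assert sorted_vals.size == 20
    rng = np.random.default_rng(0)
    return rng.permutation(sorted_vals)


def test_partition_boundaries_are_order_statistics():
    values = _series_with_sorted_anchors()
    part = qg.fit_partition(values, 5)
    assert part.boundaries == pytest.approx(REFERENCE_BOUNDARIES, abs=0)


def test_partition_uniform_ranks_equal_occupancy():
    part = qg.fit_partition(np.arange(1, 21, dtype=float), 5)
    idx = qg.quantile_index_sequence(np.arange(1, 21, dtype=float), part)
    counts = np.bincount(idx, minlength=6)[1:]
    assert list(counts) == [4, 4, 4, 4, 4]


def test_partition_occupancy_on_random_distinct_values():
    rng = np.random.default_rng(42)
    values = rng.random(1000)
    part = qg.fit_partition(values, 10)
    idx = qg.quantile_index_sequence(values, part)
    counts = np.bincount(idx, minlength=11)[1:]
    assert set(counts.tolist()) == {100}


def test_partition_errors():
    with pytest.raises(InvalidInputError):
        qg.fit_partition(np.arange(5.0), 6)  # Q > T
    with pytest.raises(DegeneratePartitionError, match="constant"):
        qg.fit_partition(np.ones(10), 2)


# ---------------------------------------------------------------------------
# quantile index sequence


def test_index_sequence_simple():
    part = qg.QuantilePartition(Q=2, boundaries=np.array([1.0, 2.5, 4.0]))
    idx = qg.quantile_index_sequence(np.array([1.0, 2.0, 3.0, 4.0]), part)
    assert idx.tolist() == [1, 1, 2, 2]


def test_index_sequence_monotone_one_per_bin():
    values = np.arange(10, dtype=float)
    part = qg.fit_partition(values, 10)
    idx = qg.quantile_index_sequence(values, part)
    assert idx.tolist() == list(range(1, 11))


def test_index_sequence_matches_interval_membership():
    """Bin assignment agrees with a per-sample brute-force interval search."""
    rng = np.random.default_rng(3)
    values = rng.normal(size=200)
    Q = 8
    part = qg.fit_partition(values, Q)
    idx = qg.quantile_index_sequence(values, part)
    b = part.boundaries
    for x, i in zip(values, idx):
        expected = Q  # last interval is closed above
        for m in range(1, Q + 1):
            if (x >= b[m - 1]) and (x < b[m]):
                expected = m
                break
        assert i == expected


def test_index_sequence_interior_boundary_goes_up():
    part = qg.QuantilePartition(Q=2, boundaries=np.array([0.0, 1.0, 2.0]))
    idx = qg.quantile_index_sequence(np.array([1.0]), part)
    assert idx.tolist() == [2]


def test_reference_partition_clamps_with_warning():
    part = qg.QuantilePartition(Q=2, boundaries=np.array([0.0, 1.0, 2.0]))
    with pytest.warns(RuntimeWarning, match="clamped"):
        idx = qg.quantile_index_sequence(np.array([-5.0, 0.5, 99.0]), part)
    assert idx.tolist() == [1, 1, 2]


# ---------------------------------------------------------------------------
# graph building


def test_build_graph_alternating():
    g = qg.build_quantile_graph(np.array([1, 2, 1, 2, 1]), k=1, Q=2)
    assert g.counts[0, 1] == 2 and g.counts[1, 0] == 2
    assert g.total_weight == 4


def test_build_graph_rejects_bad_lag():
    with pytest.raises(InvalidInputError):
        qg.build_quantile_graph(np.array([1, 2, 1]), k=3)
    with pytest.raises(InvalidInputError):
        qg.build_quantile_graph(np.array([1, 2, 1]), k=0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    data=st.lists(st.integers(min_value=1, max_value=5), min_size=4, max_size=60),
    k=st.integers(min_value=1, max_value=3),
)
def test_build_graph_matches_double_loop_and_conserves_weight(data, k):
    idx = np.array(data)
    g = qg.build_quantile_graph(idx, k, Q=5)
    naive = np.zeros((5, 5), dtype=int)
    for t in range(len(data) - k):
        naive[data[t] - 1, data[t + k] - 1] += 1
    assert np.array_equal(g.counts, naive)
    assert g.total_weight == len(data) - k


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    data=st.lists(st.integers(min_value=1, max_value=6), min_size=5, max_size=40),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_permutation_equivariance(data, seed):
    """Relabeling quantiles by a permutation permutes rows/columns of A_k."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(6)  # perm[i-1]+1 is the new label of quantile i
    idx = np.array(data)
    g = qg.build_quantile_graph(idx, 1, Q=6)
    relabeled = np.array([perm[i - 1] + 1 for i in data])
    g2 = qg.build_quantile_graph(relabeled, 1, Q=6)
    assert np.array_equal(g2.counts, g.counts[np.ix_(np.argsort(perm), np.argsort(perm))])


def test_determinism_bit_identical():
    rng = np.random.default_rng(11)
    values = rng.normal(size=300)
    w1 = qg.transition_matrix_for_segment(values, k=3)
    w2 = qg.transition_matrix_for_segment(values.copy(), k=3)
    assert np.array_equal(w1.weights, w2.weights)


# ---------------------------------------------------------------------------
# Markov normalisation and median aggregation


def test_to_markov_simple():
    g = qg.QuantileGraph(Q=2, k=1, counts=np.array([[2, 2], [0, 4]]), T=9)
    w = qg.to_markov(g)
    assert np.allclose(w.weights, [[0.5, 0.5], [0.0, 1.0]])
    assert w.row_support.tolist() == [True, True]


def test_to_markov_zero_rows_flagged_not_filled():
    g = qg.QuantileGraph(Q=3, k=1, counts=np.array([[0, 2, 0], [0, 0, 0], [1, 0, 1]]), T=5)
    w = qg.to_markov(g)
    assert w.row_support.tolist() == [True, False, True]
    assert np.all(w.weights[1] == 0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**16))
def test_row_stochasticity_on_random_series(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=64)
    w = qg.transition_matrix_for_segment(values, k=2)
    sums = w.weights.sum(axis=1)
    assert np.all(np.abs(sums[w.row_support] - 1.0) < 1e-12)
    assert np.all(sums[~w.row_support] == 0.0)
    assert np.all((w.weights >= 0) & (w.weights <= 1))


def test_median_of_one_graph_is_to_markov():
    rng = np.random.default_rng(0)
    idx = rng.integers(1, 5, size=50)
    g = qg.build_quantile_graph(idx, 1, Q=4)
    med = qg.median_transition_matrix([g])
    assert np.allclose(med.weights, qg.to_markov(g).weights)


def test_median_idempotent_on_duplicates():
    rng = np.random.default_rng(1)
    idx = rng.integers(1, 5, size=50)
    g = qg.build_quantile_graph(idx, 1, Q=4)
    med = qg.median_transition_matrix([g, g])
    assert np.allclose(med.weights, qg.to_markov(g).weights)


def test_median_matches_brute_force_over_24_graphs():
    rng = np.random.default_rng(2)
    graphs = [
        qg.build_quantile_graph(rng.integers(1, 6, size=40), 2, Q=5)
        for _ in range(24)
    ]
    med = qg.median_transition_matrix(graphs)
    stack = np.stack([g.counts for g in graphs]).astype(float)
    expected = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            expected[i, j] = np.median(stack[:, i, j])
    rowsum = expected.sum(axis=1)
    for i in range(5):
        if rowsum[i] > 0:
            expected[i] /= rowsum[i]
    assert np.allclose(med.weights, expected)


def test_median_rejects_mixed_q_or_k():
    g1 = qg.build_quantile_graph(np.array([1, 2, 1, 2]), 1, Q=2)
    g2 = qg.build_quantile_graph(np.array([1, 2, 1, 2]), 2, Q=2)
    with pytest.raises(InvalidInputError):
        qg.median_transition_matrix([g1, g2])


def test_graph_build_counter():
    with qg.count_graph_builds() as c:
        for k in (1, 2, 3):
            qg.build_quantile_graph(np.array([1, 2, 1, 2, 1]), k, Q=2)
    assert c.count == 3
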