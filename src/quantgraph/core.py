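"""Quantile-graph construction.

A time series ``X = {x(t)}`` of length ``T`` is discretised into ``Q``
quantile intervals; each interval becomes a node.  For a lag ``k`` a
directed arc ``i -> j`` is weighted by the number of times a sample in
quantile ``i`` is followed, ``k`` steps later, by a sample in quantile
``j``.  The resulting count matrix ``A_k`` has total weight ``T - k``;
row-normalising it yields the Markov transition matrix ``W_k`` whose row
``i`` is the empirical distribution of the quantile ``k`` steps after
quantile ``i``.

Conventions
-----------
* Quantile boundaries are type-1 (inverse-ECDF) empirical quantiles at
  probabilities ``i/Q``; the outer boundaries are the sample min and max.
* Intervals are half-open on the right, ``[b_{i-1}, b_i)``, with the last
  interval closed, ``[b_{Q-1}, b_Q]``; samples equal to an interior
  boundary therefore fall into the upper interval.
* Rows of ``W_k`` index the source quantile (time ``t``), columns the
  destination (time ``t + k``).  Quantile indices are 1-based in the API
  and in exports.
* Rows of ``A_k`` with no outgoing transition are kept as zero rows in
  ``W_k`` and flagged unsupported, rather than filled uniformly.
"""

from __future__ import annotations

import math
import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .segments import InvalidInputError, TimeSeriesSegment

__all__ = [
    "DegeneratePartitionError",
    "QuantilePartition",
    "QuantileGraph",
    "TransitionMatrix",
    "default_num_quantiles",
    "fit_partition",
    "quantile_index_sequence",
    "build_quantile_graph",
    "to_markov",
    "median_transition_matrix",
    "transition_matrix_for_segment",
    "count_graph_builds",
]


class DegeneratePartitionError(ValueError):
    """The sample range collapses (min == max): no quantile partition exists."""


def default_num_quantiles(T: int) -> int:
    """Default number of quantiles Q ~ 2 T^(1/3), rounded half-up, min 2.

    For the 8-second, 128 Hz EEG segments (T = 1024) this gives Q = 20.
    """
    T = int(T)
    if T < 2:
        raise InvalidInputError("T must be at least 2")
    q = 2.0 * T ** (1.0 / 3.0)
    return max(2, int(math.floor(q + 0.5)))


@dataclass(frozen=True)
class QuantilePartition:
    """Q quantile intervals given by Q+1 nondecreasing boundaries."""

    Q: int
    boundaries: np.ndarray  # shape (Q+1,), b_0 = min, b_Q = max

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size != self.Q + 1:
            raise InvalidInputError("partition needs Q+1 boundaries")
        if np.any(np.diff(b) < 0):
            raise InvalidInputError("boundaries must be nondecreasing")
        object.__setattr__(self, "boundaries", b)


@dataclass(frozen=True)
class QuantileGraph:
    """Lag-k quantile graph as a Q x Q matrix of exact transition counts."""

    Q: int
    k: int
    counts: np.ndarray  # (Q, Q) nonnegative integers, entry [i-1, j-1] = w_ij^k
    T: int  # length of the source series; counts sum to T - k

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (self.Q, self.Q):
            raise InvalidInputError("counts must be Q x Q")
        if np.any(c < 0):
            raise InvalidInputError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64, copy=False))

    @property
    def total_weight(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic Markov matrix W_k derived from a quantile graph.

    Rows without any outgoing transition are all-zero and marked
    unsupported in ``row_support``.
    """

    Q: int
    k: int
    weights: np.ndarray  # (Q, Q) in [0, 1]
    row_support: np.ndarray  # (Q,) bool

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.Q, self.Q):
            raise InvalidInputError("weights must be Q x Q")
        object.__setattr__(self, "weights", w)
        object.__setattr__(
            self, "row_support", np.asarray(self.row_support, dtype=bool)
        )


# ---------------------------------------------------------------------------
# graph-build accounting (used by the pipeline to log exact graph counts)

_build_counters: list["GraphBuildCounter"] = []


class GraphBuildCounter:
    def __init__(self) -> None:
        self.count = 0


@contextmanager
def count_graph_builds():
    """Context manager counting every quantile graph built inside it."""
    counter = GraphBuildCounter()
    _build_counters.append(counter)
    try:
        yield counter
    finally:
        _build_counters.remove(counter)


# ---------------------------------------------------------------------------


def _segment_values(segment) -> np.ndarray:
    if isinstance(segment, TimeSeriesSegment):
        return segment.values
    return np.asarray(segment, dtype=float)


def fit_partition(segment, Q: int) -> QuantilePartition:
    """Fit the Q-quantile partition of a segment's value range.

    Interior boundary ``b_i`` is the right-continuous inverse-ECDF quantile
    at probability ``i/Q`` — the order statistic of rank
    ``floor(T i / Q) + 1`` (the smallest sample strictly above the i-th
    Q-tile block); ``b_0`` and ``b_Q`` are the sample minimum and maximum.
    Together with right-open intervals this gives near-equal occupancy:
    with distinct values each interval receives between ``floor(T/Q)`` and
    ``ceil(T/Q)`` samples.
    """
    values = _segment_values(segment)
    T = values.size
    Q = int(Q)
    if Q < 2:
        raise InvalidInputError("Q must be at least 2")
    if Q > T:
        raise InvalidInputError(f"Q={Q} exceeds the number of samples T={T}")
    srt = np.sort(values)
    if srt[0] == srt[-1]:
        raise DegeneratePartitionError(
            "constant series: all samples equal, the quantile partition is "
            "degenerate (min == max)"
        )
    ranks = [T * i // Q for i in range(1, Q)]  # 0-based: rank floor(Ti/Q)+1
    boundaries = np.concatenate(([srt[0]], srt[ranks], [srt[-1]]))
    return QuantilePartition(Q=Q, boundaries=boundaries)


def quantile_index_sequence(segment, partition: QuantilePartition) -> np.ndarray:
    """Map each sample to its quantile index in 1..Q.

    Sample ``x`` falls in interval ``i`` when ``b_{i-1} <= x < b_i`` (the
    last interval is closed above).  When a *reference* partition fitted on
    another segment is reused, out-of-range samples are clamped to the end
    bins with a warning.
    """
    values = _segment_values(segment)
    b = partition.boundaries
    below = values < b[0]
    above = values > b[-1]
    if below.any() or above.any():
        warnings.warn(
            f"{int(below.sum() + above.sum())} sample(s) outside the "
            "partition range; clamped to the end bins",
            RuntimeWarning,
            stacklevel=2,
        )
    idx = np.searchsorted(b[1:-1], values, side="right") + 1
    return idx.astype(np.int64)


def build_quantile_graph(
    indices: Sequence[int], k: int, Q: int | None = None, *, T: int | None = None
) -> QuantileGraph:
    """Count lag-k transitions of a quantile index sequence.

    ``counts[i-1, j-1]`` is the number of positions ``t`` with
    ``index(t) = i`` and ``index(t + k) = j``; the total count is ``T - k``.
    """
    idx = np.asarray(indices, dtype=np.int64)
    n = idx.size
    k = int(k)
    if k < 1 or k >= n:
        raise InvalidInputError(f"lag k={k} must satisfy 1 <= k < T={n}")
    if Q is None:
        Q = int(idx.max())
    if idx.min() < 1 or idx.max() > Q:
        raise InvalidInputError("indices must lie in 1..Q")
    counts = np.zeros((Q, Q), dtype=np.int64)
    np.add.at(counts, (idx[:-k] - 1, idx[k:] - 1), 1)
    for c in _build_counters:
        c.count += 1
    return QuantileGraph(Q=Q, k=k, counts=counts, T=T if T is not None else n)


def _row_normalize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rowsum = counts.sum(axis=1, dtype=float)
    support = rowsum > 0
    weights = np.zeros_like(counts, dtype=float)
    weights[support] = counts[support] / rowsum[support, None]
    return weights, support


def to_markov(graph: QuantileGraph) -> TransitionMatrix:
    """Row-normalise the count matrix A_k into the Markov matrix W_k."""
    weights, support = _row_normalize(np.asarray(graph.counts, dtype=float))
    return TransitionMatrix(Q=graph.Q, k=graph.k, weights=weights, row_support=support)


def median_transition_matrix(graphs: Iterable[QuantileGraph]) -> TransitionMatrix:
    """Element-wise median of count matrices, then row-normalised.

    This is the group-level aggregate: the median is taken on the raw
    counts ``A_k`` across segments and only then converted to a Markov
    matrix, so one outlying segment cannot dominate any transition.
    """
    graphs = list(graphs)
    if not graphs:
        raise InvalidInputError("need at least one graph")
    Q, k = graphs[0].Q, graphs[0].k
    for g in graphs:
        if g.Q != Q or g.k != k:
            raise InvalidInputError("graphs must share the same Q and k")
    stack = np.stack([g.counts for g in graphs]).astype(float)
    med = np.median(stack, axis=0)
    weights, support = _row_normalize(med)
    return TransitionMatrix(Q=Q, k=k, weights=weights, row_support=support)


def transition_matrix_for_segment(
    segment, k: int, Q: int | None = None
) -> TransitionMatrix:
    """Convenience: partition, index, count and normalise in one step."""
    values = _segment_values(segment)
    if Q is None:
        Q = default_num_quantiles(values.size)
    partition = fit_partition(values, Q)
    idx = quantile_index_sequence(values, partition)
    return to_markov(build_quantile_graph(idx, k, Q))
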