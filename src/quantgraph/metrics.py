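"""Topological metrics of quantile-graph transition matrices.

Five summary metrics characterise a lag-k quantile network:

``CC``   weighted clustering coefficient (triangle density around a node,
         weighted by the mean weight of the two arcs anchored at it),
         averaged over nodes.
``MJL``  mean jump length: the expected |i - j| of a transition, where i, j
         are quantile indices.  Computed either in closed form from the
         transition matrix or by simulating a random walk.
``BC``   betweenness centrality on the directed unweighted arc structure,
         normalised per node by (Q-1)(Q-2) and averaged over nodes.
``MO``   modularity of the best partition found by greedy modularity
         maximisation on the symmetrised weighted graph.
``LEE``  Laplacian Estrada index: sum of exp(mu) over the eigenvalues of
         the symmetrised weighted Laplacian.

All five consume the Markov weights W_k (entries in [0, 1]); symmetrising
metrics use w'_ij = (w_ij + w_ji)/2 with self-loops dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg

from .core import TransitionMatrix
from .segments import InvalidInputError

__all__ = [
    "METRICS",
    "METRIC_NAMES",
    "clustering_coefficient",
    "mean_jump_length",
    "mean_jump_length_walk",
    "WalkEstimate",
    "betweenness_centrality",
    "ModulePartition",
    "detect_modules",
    "modularity_score",
    "modularity",
    "laplacian_estrada_index",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined for this input (e.g. E = 0)."""


def _weights(W) -> np.ndarray:
    if isinstance(W, TransitionMatrix):
        w = np.array(W.weights, dtype=float)
    else:
        w = np.array(W, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidInputError("weight matrix must be square")
    return w


def _offdiag(w: np.ndarray) -> np.ndarray:
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def _symmetrized(w: np.ndarray) -> np.ndarray:
    """Arithmetic-mean symmetrisation with self-loops removed."""
    return _offdiag((w + w.T) / 2.0)


# ---------------------------------------------------------------------------
# clustering coefficient


def clustering_coefficient(W) -> float:
    """Average weighted clustering coefficient.

    Per node i::

        CC_i = 1 / (s_i (d_i - 1)) * sum_{j,d} (w_ij + w_id)/2 * a_ij a_jd a_id

    with a_ij = 1 iff w_ij > 0, d_i the number of distinct neighbours over
    the union of in/out arcs, and s_i the out-strength.  Self-loops are
    excluded; nodes with d_i <= 1 or s_i = 0 contribute 0.  On a directed
    clique with symmetric unit arcs every neighbour pair is closed and
    CC = 1; a triangle-free graph gives CC = 0.
    """
    w = _offdiag(_weights(W))
    a = (w > 0).astype(float)
    und = ((a + a.T) > 0)
    d = und.sum(axis=1)  # distinct neighbours (in or out)
    s = w.sum(axis=1)  # out-strength
    # sum_{j,d} a_ij a_jd a_id * w_ij   and   ... * w_id
    t1 = np.einsum("ij,jd,id,ij->i", a, a, a, w)
    t2 = np.einsum("ij,jd,id,id->i", a, a, a, w)
    num = 0.5 * (t1 + t2)
    denom = s * np.maximum(d - 1.0, 1.0)
    cc = np.where((d > 1) & (s > 0) & (denom > 0), num / np.where(denom > 0, denom, 1.0), 0.0)
    return float(cc.mean())


# ---------------------------------------------------------------------------
# mean jump length


def mean_jump_length(W) -> float:
    """Mean jump length in closed form: (1/Q) tr(P W^T) with p_ij = |i - j|.

    Equals ``(1/Q) sum_ij |i - j| w_ij``.  Zero iff all transition mass sits
    on the diagonal; for a uniform matrix it approaches ``(Q^2 - 1)/(3 Q)``,
    the value for index-independent jumps.
    """
    w = _weights(W)
    Q = w.shape[0]
    idx = np.arange(Q)
    p = np.abs(idx[:, None] - idx[None, :])
    return float((p * w).sum() / Q)


# alias mirroring the "trace formula" name used in the docs
mean_jump_length_trace = mean_jump_length


@dataclass(frozen=True)
class WalkEstimate:
    """Monte-Carlo estimate of the mean jump length from a random walk."""

    mean: float
    stderr: float
    n_jumps: int

    def __float__(self) -> float:
        return self.mean


def mean_jump_length_walk(
    W, n_jumps: int = 1_000_000, seed: int | None = None
) -> WalkEstimate:
    """Mean |i - j| over an ``n_jumps``-step random walk following W.

    The walk starts at a state drawn uniformly over supported rows; when it
    reaches a state with no outgoing transitions it restarts uniformly over
    supported rows, and the restart is not counted as a jump.
    """
    w = _weights(W)
    Q = w.shape[0]
    rowsum = w.sum(axis=1)
    supported = np.flatnonzero(rowsum > 0)
    if supported.size == 0:
        raise InvalidInputError("all rows unsupported: no walk is possible")
    if n_jumps < 1:
        raise InvalidInputError("n_jumps must be >= 1")
    cum = np.cumsum(w, axis=1)
    cum = cum / np.where(rowsum[:, None] > 0, rowsum[:, None], 1.0)
    rng = np.random.default_rng(seed)
    sup_set = set(supported.tolist())

    state = int(supported[rng.integers(supported.size)])
    u = rng.random(n_jumps)
    total = 0.0
    total_sq = 0.0
    for s in range(n_jumps):
        if state not in sup_set:
            state = int(supported[rng.integers(supported.size)])
        nxt = int(np.searchsorted(cum[state], u[s], side="right"))
        nxt = min(nxt, Q - 1)
        jump = abs(state - nxt)
        total += jump
        total_sq += jump * jump
        state = nxt
    mean = total / n_jumps
    var = max(total_sq / n_jumps - mean * mean, 0.0)
    stderr = (var / n_jumps) ** 0.5
    return WalkEstimate(mean=mean, stderr=stderr, n_jumps=n_jumps)


# ---------------------------------------------------------------------------
# betweenness centrality


def betweenness_centrality(W) -> float:
    """Average normalised betweenness centrality on the directed arc graph.

    Shortest paths are counted unweighted (hop count) on the digraph of
    arcs with positive weight, self-loops ignored.  Each node's raw count
    of pair-shortest-paths through it is divided by (Q-1)(Q-2); the node
    average is returned.  On a complete digraph no pair routes through a
    third node, so BC = 0.
    """
    w = _offdiag(_weights(W))
    Q = w.shape[0]
    if Q < 3:
        raise InvalidInputError("betweenness needs Q >= 3")
    g = nx.DiGraph()
    g.add_nodes_from(range(Q))
    src, dst = np.nonzero(w)
    g.add_edges_from(zip(src.tolist(), dst.tolist()))
    bc = nx.betweenness_centrality(g, normalized=True)  # /((Q-1)(Q-2)) directed
    return float(np.mean([bc[i] for i in range(Q)]))


# ---------------------------------------------------------------------------
# modularity


@dataclass(frozen=True)
class ModulePartition:
    """A node-to-module assignment together with its modularity score."""

    labels: np.ndarray  # labels[i] = module id of node i
    modularity: float

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.labels).size)


def modularity_score(W, labels) -> float:
    """Modularity of a partition on the symmetrised weighted graph::

        M(P) = sum_m [ e_m / E - (d_m / (2 E))^2 ]

    with E the total edge weight, e_m the intra-module weight and d_m the
    module strength sum.  Putting the whole graph in one module gives 0.
    """
    ws = _symmetrized(_weights(W))
    labels = np.asarray(labels)
    Q = ws.shape[0]
    if labels.size != Q:
        raise InvalidInputError("partition must assign every node")
    E = ws.sum() / 2.0
    if E <= 0:
        raise UndefinedMetricError("modularity undefined on an edgeless graph")
    strength = ws.sum(axis=1)
    score = 0.0
    for m in np.unique(labels):
        nodes = np.flatnonzero(labels == m)
        e_m = ws[np.ix_(nodes, nodes)].sum() / 2.0
        d_m = strength[nodes].sum()
        score += e_m / E - (d_m / (2.0 * E)) ** 2
    return float(score)


def detect_modules(W) -> ModulePartition:
    """Best partition by greedy modularity maximisation (deterministic).

    Runs on the symmetrised weighted graph with self-loops dropped.  An
    edgeless graph returns the single-module partition with M = 0 by
    convention.
    """
    ws = _symmetrized(_weights(W))
    Q = ws.shape[0]
    if ws.sum() == 0:
        return ModulePartition(labels=np.zeros(Q, dtype=int), modularity=0.0)
    g = nx.Graph()
    g.add_nodes_from(range(Q))
    src, dst = np.nonzero(ws)
    for i, j in zip(src.tolist(), dst.tolist()):
        if i < j:
            g.add_edge(i, j, weight=float(ws[i, j]))
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    labels = np.zeros(Q, dtype=int)
    for m, nodes in enumerate(communities):
        for i in nodes:
            labels[i] = m
    return ModulePartition(labels=labels, modularity=modularity_score(ws, labels))


def modularity(W) -> float:
    """Modularity of the detected best partition (scalar shortcut)."""
    return detect_modules(W).modularity


# ---------------------------------------------------------------------------
# Laplacian Estrada index


def laplacian_estrada_index(W) -> float:
    """Sum of exp(mu) over the Laplacian eigenvalues of the symmetrised graph.

    L = D - A with A the symmetrised weights (self-loops dropped) and D the
    diagonal of strengths; L is real symmetric so the spectrum is real.  An
    edgeless graph on n nodes gives LEE = n.  On row-stochastic weights all
    strengths are <= 1, so every eigenvalue is <= 2 and LEE stays O(Q e^2).
    """
    ws = _symmetrized(_weights(W))
    lap = np.diag(ws.sum(axis=1)) - ws
    mu = scipy.linalg.eigvalsh(lap)
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError("non-finite Laplacian eigenvalue")
    return float(np.exp(mu).sum())


#: Metric registry: scalar summaries of a TransitionMatrix, keyed by the
#: short names used throughout the discrimination pipeline.
METRICS = {
    "CC": clustering_coefficient,
    "MJL": mean_jump_length,
    "BC": betweenness_centrality,
    "MO": modularity,
    "LEE": laplacian_estrada_index,
}

METRIC_NAMES = tuple(METRICS)
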