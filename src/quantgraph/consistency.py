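"""Cross-lag consistency of quantile-graph count matrices.

The lag-1 count matrix of a length-T index sequence is the arc multiset of
an Eulerian path on Q nodes: the sequence traverses every lag-1 arc exactly
as many times as its weight.  Count matrices at higher lags are induced by
the *same* sequence, so a family of matrices ``{A_k}`` is mutually
consistent only if a single sequence generates all of them.  The search
below decides that by enumerating Eulerian paths of the lag-1 multigraph
with pruning against the higher-lag count budgets.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .segments import InvalidInputError

__all__ = ["arcs_to_counts", "find_consistent_sequence"]


def arcs_to_counts(arcs: Iterable[tuple[int, int, int]], Q: int) -> np.ndarray:
    """Turn a weighted arc list ``(src, dst, weight)`` (1-based) into counts."""
    counts = np.zeros((Q, Q), dtype=np.int64)
    for i, j, w in arcs:
        if not (1 <= i <= Q and 1 <= j <= Q):
            raise InvalidInputError(f"arc ({i}, {j}) outside 1..{Q}")
        counts[i - 1, j - 1] += int(w)
    return counts


def find_consistent_sequence(
    counts_by_lag: Mapping[int, np.ndarray], T: int
) -> list[int] | None:
    """Find one index sequence generating all given lag count matrices.

    Parameters
    ----------
    counts_by_lag
        Mapping lag ``k`` -> ``Q x Q`` count matrix.  Lag 1 must be present;
        each matrix must total ``T - k``.
    T
        Length of the sought sequence.

    Returns
    -------
    A list of ``T`` quantile indices (1-based) whose lag-k transition counts
    equal every supplied matrix, or ``None`` if no such sequence exists.
    """
    if 1 not in counts_by_lag:
        raise InvalidInputError("the lag-1 count matrix is required")
    lags = sorted(counts_by_lag)
    rem = {k: np.array(counts_by_lag[k], dtype=np.int64, copy=True) for k in lags}
    Q = rem[1].shape[0]
    for k in lags:
        if rem[k].shape != (Q, Q):
            raise InvalidInputError("all count matrices must share the same Q")
        if rem[k].sum() != T - k:
            return None  # totals already rule out a common sequence

    out_deg = rem[1].sum(axis=1)
    in_deg = rem[1].sum(axis=0)
    # Eulerian-path start: the unique node with out-degree excess, else any
    # node with outgoing arcs (Eulerian circuit case).
    starts = [i for i in range(Q) if out_deg[i] - in_deg[i] == 1]
    if not starts:
        starts = [i for i in range(Q) if out_deg[i] > 0]
    higher = [k for k in lags if k > 1]

    seq: list[int] = []

    def extend(node: int) -> bool:
        # `node` is 0-based here; seq holds 0-based indices during the search
        seq.append(node)
        pos = len(seq) - 1
        used: list[tuple[int, int]] = []
        ok = True
        for k in higher:
            if pos >= k:
                i = seq[pos - k]
                if rem[k][i, node] == 0:
                    ok = False
                    break
                rem[k][i, node] -= 1
                used.append((k, i))
        if ok:
            if len(seq) == T:
                return True
            row = rem[1][node]
            for j in range(Q):
                if row[j] > 0:
                    row[j] -= 1
                    if extend(j):
                        return True
                    row[j] += 1
        for k, i in reversed(used):
            rem[k][i, node] += 1
        seq.pop()
        return False

    for s in starts:
        if extend(s):
            return [i + 1 for i in seq]
    return None


def counts_are_consistent(
    counts_by_lag: Mapping[int, np.ndarray], T: int
) -> bool:
    """True iff one sequence of length T generates all the count matrices."""
    return find_consistent_sequence(counts_by_lag, T) is not None
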