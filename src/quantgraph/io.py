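"""Reading and writing cohorts, graphs and matrices.

The canonical interchange format is a long-format TSV with columns
``subject, group, channel, t, value`` (one row per sample).  Single
segments can also be read from one-column text/CSV files, with metadata
taken from a ``{group}_{subject}_{channel}`` filename stem or supplied
explicitly.  Graphs export as 1-based weighted edge lists (TSV) or
GraphML; matrices as dense CSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import QuantileGraph, TransitionMatrix
from .segments import Cohort, InvalidInputError, TimeSeriesSegment

__all__ = [
    "load_cohort",
    "write_cohort_tsv",
    "load_segment",
    "export_edges_tsv",
    "export_graphml",
    "export_matrix_csv",
]

_LONG_COLUMNS = ("subject", "group", "channel", "t", "value")


def write_cohort_tsv(cohort: Cohort, path: str | os.PathLike) -> None:
    """Write a cohort as long-format TSV (full float precision)."""
    rows = []
    for seg in cohort.segments:
        rows.append(
            pd.DataFrame(
                {
                    "subject": seg.subject_id,
                    "group": seg.group,
                    "channel": seg.channel,
                    "t": np.arange(seg.T),
                    "value": seg.values,
                    "sampling_rate": seg.sampling_rate,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _cohort_from_long(df: pd.DataFrame, path) -> Cohort:
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    bad = df["value"].isna() | ~np.isfinite(df["value"].to_numpy(dtype=float))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise InvalidInputError(f"{path}: malformed value rows at lines {lines}")
    if "sampling_rate" in df.columns:
        rates = df["sampling_rate"].unique()
        if len(rates) > 1:
            raise InvalidInputError(f"{path}: mixed sampling rates {sorted(rates)}")
        rate = float(rates[0])
    else:
        rate = 128.0
    cohort = Cohort()
    for (subject, group, channel), grp in df.groupby(
        ["subject", "group", "channel"], sort=True
    ):
        grp = grp.sort_values("t")
        cohort.add(
            TimeSeriesSegment(
                values=grp["value"].to_numpy(dtype=float),
                sampling_rate=rate,
                channel=str(channel),
                group=str(group),
                subject_id=str(subject),
            )
        )
    cohort.common_length()  # raises listing offenders if lengths differ
    return cohort


def load_segment(
    path: str | os.PathLike,
    group: str | None = None,
    channel: str | None = None,
    subject_id: str | None = None,
    sampling_rate: float = 128.0,
) -> TimeSeriesSegment:
    """Read a one-column text/CSV file as a single segment.

    Missing metadata is parsed from a ``{group}_{subject}_{channel}``
    filename stem when possible.
    """
    path = Path(path)
    try:
        values = np.loadtxt(path, dtype=float, delimiter=None, ndmin=1)
    except ValueError as exc:
        raise InvalidInputError(f"{path}: could not parse as one-column data: {exc}")
    if values.ndim != 1:
        raise InvalidInputError(f"{path}: expected exactly one column")
    parts = path.stem.split("_")
    if len(parts) == 3:
        g, s, c = parts
    else:
        g, s, c = "A", path.stem, "F7"
    return TimeSeriesSegment(
        values=values,
        sampling_rate=sampling_rate,
        channel=channel or c,
        group=group or g,
        subject_id=subject_id or s,
    )


def load_cohort(path: str | os.PathLike) -> Cohort:
    """Load a cohort from a long-format TSV file or a directory of segments.

    A directory is read as one segment per ``*.txt``/``*.csv``/``*.dat``
    file, metadata from filename stems.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".txt", ".csv", ".dat")
        )
        if not files:
            raise InvalidInputError(f"{path}: empty cohort directory")
        cohort = Cohort([load_segment(p) for p in files])
        cohort.common_length()
        return cohort
    if not path.exists():
        raise InvalidInputError(f"{path}: no such file or directory")
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise InvalidInputError(f"{path}: parse error: {exc}")
    return _cohort_from_long(df, path)


# ---------------------------------------------------------------------------
# graph / matrix export


def _as_graph_matrix(graph) -> tuple[np.ndarray, int]:
    if isinstance(graph, QuantileGraph):
        return np.asarray(graph.counts), graph.Q
    if isinstance(graph, TransitionMatrix):
        return np.asarray(graph.weights), graph.Q
    m = np.asarray(graph)
    return m, m.shape[0]


def export_edges_tsv(graph, path: str | os.PathLike) -> None:
    """Weighted arc list, columns src/dst/weight with 1-based node ids."""
    m, _ = _as_graph_matrix(graph)
    src, dst = np.nonzero(m)
    pd.DataFrame(
        {"src": src + 1, "dst": dst + 1, "weight": m[src, dst]}
    ).to_csv(path, sep="\t", index=False)


def export_graphml(graph, path: str | os.PathLike) -> None:
    m, Q = _as_graph_matrix(graph)
    g = nx.DiGraph()
    g.add_nodes_from(range(1, Q + 1))
    src, dst = np.nonzero(m)
    for i, j in zip(src.tolist(), dst.tolist()):
        g.add_edge(i + 1, j + 1, weight=float(m[i, j]))
    nx.write_graphml(g, path)


def export_matrix_csv(graph, path: str | os.PathLike) -> None:
    m, Q = _as_graph_matrix(graph)
    labels = [str(i) for i in range(1, Q + 1)]
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path)
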