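"""Group discrimination from quantile-graph metrics.

For every group the per-segment lag-k count matrices are aggregated by an
element-wise median and turned into one Markov matrix per lag; evaluating a
metric on each of these gives one metric-vs-lag curve per group.  The lag
``k_max`` at which the healthy and patient curve clusters are farthest
apart (worst-case inter-cluster gap) is selected, the metric is then
evaluated per segment at that lag, and group differences are quantified by
a two-level ANOVA and by Mann-Whitney ROC areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .core import (
    build_quantile_graph,
    default_num_quantiles,
    fit_partition,
    median_transition_matrix,
    quantile_index_sequence,
    to_markov,
)
from .metrics import METRICS
from .segments import Cohort, InvalidInputError

__all__ = [
    "DEFAULT_K_CAP",
    "DEFAULT_PAIRS",
    "SeparationResult",
    "AnovaResult",
    "group_median_matrices",
    "metric_curves",
    "select_kmax",
    "per_segment_metrics",
    "roc_auc",
    "group_anova",
    "channel_auc_map",
]

#: Default lag sweep, k = 1..25.
DEFAULT_K_CAP = 25

#: The four cross-condition (healthy vs patient) group pairs whose ROC
#: areas are averaged into the per-channel score; within-condition pairs
#: (A, B) and (C, D) are excluded.
DEFAULT_PAIRS = (("A", "C"), ("B", "D"), ("A", "D"), ("B", "C"))


def _metric_fn(metric):
    if callable(metric):
        return metric
    try:
        return METRICS[metric]
    except KeyError:
        raise InvalidInputError(
            f"unknown metric {metric!r}; expected one of {tuple(METRICS)}"
        ) from None


def _indices_for_segments(segments, Q):
    out = []
    for seg in segments:
        part = fit_partition(seg, Q)
        out.append(quantile_index_sequence(seg, part))
    return out


def group_median_matrices(
    cohort: Cohort,
    channel: str,
    k_cap: int = DEFAULT_K_CAP,
    Q: int | None = None,
    groups: Sequence[str] | None = None,
):
    """Median-aggregated Markov matrix per (group, lag).

    Returns ``dict[group] -> list of TransitionMatrix`` indexed by lag
    ``k = 1..k_cap``.  Each group's matrix at lag k is the element-wise
    median of its segments' count matrices, row-normalised.
    """
    groups = tuple(groups) if groups is not None else cohort.groups
    T = cohort.common_length()
    if Q is None:
        Q = default_num_quantiles(T)
    if k_cap < 1 or k_cap >= T:
        raise InvalidInputError("k_cap must satisfy 1 <= k_cap < T")
    result: dict[str, list] = {}
    for g in groups:
        segments = cohort.select(group=g, channel=channel)
        if not segments:
            raise InvalidInputError(f"no segments for group {g!r} channel {channel!r}")
        idx = _indices_for_segments(segments, Q)
        mats = []
        for k in range(1, k_cap + 1):
            graphs = [build_quantile_graph(ix, k, Q) for ix in idx]
            mats.append(median_transition_matrix(graphs))
        result[g] = mats
    return result


def metric_curves(
    cohort: Cohort,
    channel: str,
    metric,
    k_cap: int = DEFAULT_K_CAP,
    Q: int | None = None,
    groups: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """One metric-vs-lag curve per group (metric on the median matrix)."""
    fn = _metric_fn(metric)
    mats = group_median_matrices(cohort, channel, k_cap=k_cap, Q=Q, groups=groups)
    return {g: np.array([fn(m) for m in ms]) for g, ms in mats.items()}


@dataclass(frozen=True)
class SeparationResult:
    """Selected lag of maximum curve-cluster separation."""

    k_max: int
    separation: float
    separations: np.ndarray = field(repr=False)


def select_kmax(
    healthy_curves: Sequence[np.ndarray], patient_curves: Sequence[np.ndarray]
) -> SeparationResult:
    """Lag with the largest worst-case gap between the two curve clusters.

    ``separation(k) = min over (h, u) pairs |curve_h(k) - curve_u(k)|``;
    ``k_max`` is the argmax, ties broken toward the smallest k.
    """
    healthy = [np.asarray(c, dtype=float) for c in healthy_curves]
    patient = [np.asarray(c, dtype=float) for c in patient_curves]
    if not healthy or not patient:
        raise InvalidInputError("need at least one curve per side")
    lengths = {c.size for c in healthy + patient}
    if len(lengths) != 1:
        raise InvalidInputError("curves must share the same k grid")
    if any(np.any(~np.isfinite(c)) for c in healthy + patient):
        raise InvalidInputError("curves contain non-finite values")
    sep = np.min(
        [np.abs(h - u) for h in healthy for u in patient], axis=0
    )
    k_max = int(np.argmax(sep)) + 1  # ties: np.argmax returns the first
    return SeparationResult(k_max=k_max, separation=float(sep[k_max - 1]), separations=sep)


def per_segment_metrics(
    cohort: Cohort,
    channel: str,
    metric,
    k: int,
    Q: int | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """The metric on each segment's own W_k (no median aggregation).

    Returns a tidy frame with columns group, subject, value.
    """
    fn = _metric_fn(metric)
    groups = tuple(groups) if groups is not None else cohort.groups
    T = cohort.common_length()
    if Q is None:
        Q = default_num_quantiles(T)
    rows = []
    for g in groups:
        for seg in cohort.select(group=g, channel=channel):
            part = fit_partition(seg, Q)
            idx = quantile_index_sequence(seg, part)
            w = to_markov(build_quantile_graph(idx, k, Q))
            rows.append({"group": g, "subject": seg.subject_id, "value": fn(w)})
    return pd.DataFrame(rows)


def roc_auc(values_group1, values_group2) -> float:
    """Mann-Whitney area under the ROC curve, oriented into [0.5, 1].

    The orientation ``max(AUC, 1 - AUC)`` makes the score direction-free:
    it measures separability whether the pathology raises or lowers the
    metric.  Ties are handled by midranks.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InvalidInputError("both groups must be non-empty")
    u = scipy.stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    auc = u / (x.size * y.size)
    return float(max(auc, 1.0 - auc))


@dataclass(frozen=True)
class AnovaResult:
    """One-way two-level ANOVA with the 95% CI of the mean difference."""

    F: float
    p: float
    ci_low: float
    ci_high: float
    mean_diff: float


def group_anova(healthy_values, patient_values, ci_level: float = 0.95) -> AnovaResult:
    """Compare healthy vs patient means (two-level one-way ANOVA).

    Equivalent to a pooled two-sample t-test: F = t^2.  Returns F, p and
    the CI of ``mean(healthy) - mean(patient)``.  If both samples have zero
    variance and equal means, p = 1 by convention.
    """
    h = np.asarray(healthy_values, dtype=float)
    u = np.asarray(patient_values, dtype=float)
    if h.size < 2 or u.size < 2:
        raise InvalidInputError("need at least 2 values per group")
    diff = float(h.mean() - u.mean())
    if h.var() == 0 and u.var() == 0:
        if diff == 0:
            return AnovaResult(F=0.0, p=1.0, ci_low=0.0, ci_high=0.0, mean_diff=0.0)
        return AnovaResult(F=np.inf, p=0.0, ci_low=diff, ci_high=diff, mean_diff=diff)
    F, p = scipy.stats.f_oneway(h, u)
    tt = scipy.stats.ttest_ind(h, u)
    ci = tt.confidence_interval(ci_level)
    return AnovaResult(
        F=float(F), p=float(p), ci_low=float(ci.low), ci_high=float(ci.high),
        mean_diff=diff,
    )


def channel_auc_map(
    cohort: Cohort,
    metric,
    k_cap: int = DEFAULT_K_CAP,
    Q: int | None = None,
    healthy_groups: Sequence[str] = ("A", "B"),
    patient_groups: Sequence[str] = ("C", "D"),
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-channel mean ROC area over the cross-condition group pairs.

    For each channel: pick that channel's ``k_max`` for the metric from the
    group median curves, evaluate the metric per segment at ``k_max``, then
    compute the ROC area for every healthy-vs-patient pair and average them.
    Pairs with a missing group are skipped with a warning.

    Returns a frame with one row per (channel, pair) plus the per-channel
    mean in the ``mean_auc`` column (repeated within a channel).
    """
    channels = tuple(channels) if channels is not None else cohort.channels
    if len(channels) < 1:
        raise InvalidInputError("cohort has no channels")
    present = set(cohort.groups)
    rows = []
    for ch in channels:
        curves = metric_curves(cohort, ch, metric, k_cap=k_cap, Q=Q)
        healthy = [curves[g] for g in healthy_groups if g in curves]
        patient = [curves[g] for g in patient_groups if g in curves]
        sel = select_kmax(healthy, patient)
        values = per_segment_metrics(cohort, ch, metric, sel.k_max, Q=Q)
        by_group = {g: grp["value"].to_numpy() for g, grp in values.groupby("group")}
        aucs = {}
        for g1, g2 in pairs:
            if g1 not in present or g2 not in present:
                warnings.warn(
                    f"pair ({g1}, {g2}) skipped: group missing from cohort",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            aucs[(g1, g2)] = roc_auc(by_group[g1], by_group[g2])
        if not aucs:
            raise InvalidInputError("no group pair could be evaluated")
        mean_auc = float(np.mean(list(aucs.values())))
        for (g1, g2), a in aucs.items():
            rows.append(
                {
                    "channel": ch,
                    "metric": metric if isinstance(metric, str) else getattr(metric, "__name__", "metric"),
                    "k_max": sel.k_max,
                    "pair": f"{g1}{g2}",
                    "auc": a,
                    "mean_auc": mean_auc,
                }
            )
    return pd.DataFrame(rows)
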