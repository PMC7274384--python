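"""Two-class subject classification from quantile-graph metric features.

Each subject is described by the five network metrics (CC, MJL, BC, MO,
LEE), each evaluated on the subject's own transition matrix at that
metric's discriminating lag ``k_max``.  A linear max-margin classifier
(SVM) with per-fold standardisation is assessed by stratified 10-fold
cross-validation, reporting accuracy, sensitivity, specificity and AUC
pooled over the held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .discriminate import per_segment_metrics
from .metrics import METRIC_NAMES
from .segments import Cohort, InvalidInputError

__all__ = ["build_feature_table", "crossval_classify", "ClassificationReport"]

HEALTHY_LABEL = "healthy"
PATIENT_LABEL = "AD"


def build_feature_table(
    cohort: Cohort,
    channel: str,
    kmax_per_metric: Mapping[str, int],
    healthy_groups: Sequence[str] = ("A", "B"),
    metrics: Sequence[str] = METRIC_NAMES,
    Q: int | None = None,
) -> pd.DataFrame:
    """Assemble the subjects x metrics feature table.

    Each metric is evaluated per segment at its own ``k_max``; a subject
    recorded under several conditions (e.g. eyes open and closed) has its
    per-condition values averaged into one row, and the conditions used are
    recorded in the ``conditions`` column.  The ``label`` column marks each
    row healthy or patient according to ``healthy_groups``.
    """
    missing = [m for m in metrics if m not in kmax_per_metric]
    if missing:
        raise InvalidInputError(f"k_max missing for metrics: {missing}")
    healthy = set(healthy_groups)

    per_metric = {
        m: per_segment_metrics(cohort, channel, m, int(kmax_per_metric[m]), Q=Q)
        for m in metrics
    }
    # long -> wide on (label, subject); group identity kept as condition info
    frames = []
    for m, df in per_metric.items():
        df = df.copy()
        df["label"] = np.where(df["group"].isin(healthy), HEALTHY_LABEL, PATIENT_LABEL)
        frames.append(df.rename(columns={"value": m}))
    base = frames[0][["label", "subject", "group"]]
    merged = base.copy()
    for m, df in zip(metrics, frames):
        merged[m] = df[m].to_numpy()
    table = (
        merged.groupby(["label", "subject"], sort=True)
        .agg({**{m: "mean" for m in metrics}, "group": lambda g: "+".join(sorted(set(g)))})
        .rename(columns={"group": "conditions"})
        .reset_index()
    )
    return table


@dataclass(frozen=True)
class ClassificationReport:
    """Pooled cross-validated performance of the two-class classifier."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_subjects: int
    folds: int
    per_fold: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "ACC": self.accuracy,
            "SEN": self.sensitivity,
            "SPE": self.specificity,
            "AUC": self.auc,
            "n_subjects": self.n_subjects,
            "folds": self.folds,
        }


def crossval_classify(
    table: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    kernel: str = "linear",
    feature_columns: Sequence[str] | None = None,
    positive_label: str = PATIENT_LABEL,
) -> ClassificationReport:
    """Stratified k-fold cross-validation of an SVM on the feature table.

    Features are z-scored with statistics fitted on each training fold only.
    Predictions and decision scores from the held-out folds are pooled into
    a single confusion matrix and ROC area.  The positive class (for
    sensitivity) is the patient label.
    """
    if feature_columns is None:
        feature_columns = [c for c in METRIC_NAMES if c in table.columns]
    if not feature_columns:
        raise InvalidInputError("no feature columns found in the table")
    if "label" not in table.columns:
        raise InvalidInputError("table must have a 'label' column")
    X = table[list(feature_columns)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise InvalidInputError("feature table contains missing or non-finite cells")
    y = (table["label"].to_numpy() == positive_label).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidInputError("need two classes to classify")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise InvalidInputError("need at least 2 subjects per class")
    n_splits = int(min(folds, counts.min()))

    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    score = np.empty(y.size, dtype=float)
    fold_rows = []
    for f, (tr, te) in enumerate(cv.split(X, y)):
        model = make_pipeline(StandardScaler(), SVC(kernel=kernel, C=1.0))
        model.fit(X[tr], y[tr])
        y_pred[te] = model.predict(X[te])
        score[te] = model.decision_function(X[te])
        fold_rows.append(
            {
                "fold": f,
                "n_test": te.size,
                "accuracy": float((y_pred[te] == y[te]).mean()),
            }
        )
    tp = int(np.sum((y == 1) & (y_pred == 1)))
    tn = int(np.sum((y == 0) & (y_pred == 0)))
    fp = int(np.sum((y == 0) & (y_pred == 1)))
    fn = int(np.sum((y == 1) & (y_pred == 0)))
    acc = (tp + tn) / y.size
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    auc = float(roc_auc_score(y, score))
    return ClassificationReport(
        accuracy=float(acc),
        sensitivity=float(sen),
        specificity=float(spe),
        auc=auc,
        n_subjects=int(y.size),
        folds=n_splits,
        per_fold=pd.DataFrame(fold_rows),
    )
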