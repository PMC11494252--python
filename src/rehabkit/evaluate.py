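"""Holdout evaluation: confusion matrices, precision/recall/F1 and model
comparison tables.

Per-class precision is TP over the predicted-class column sum, recall TP
over the true-class row sum, and F1 their harmonic mean; macro averages
treat classes equally while weighted averages use class support.  Both are
always reported.  All metrics are percentages in [0, 100]; zero
denominators yield 0 and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .dataset import CODE_CLASSES
from .models import CVResult, FittedModel, predict

#: canonical class order for reports
CLASS_ORDER = (0, 1, 2)  # no, low, high

#: Holdout precision/recall/F1 (percent) per class, as reported by the
#: motivating clinical study of 33 stroke patients on its own (undeposited)
#: device data.  Kept as arithmetic-consistency inputs: the per-class F1
#: values satisfy F1 = 2PR/(P+R) for the printed precision and recall.
REFERENCE_HOLDOUT_METRICS = {
    "extra_trees": {
        "low": {"precision": 95.44, "recall": 92.83, "f1": 94.12},
        "high": {"precision": 94.46, "recall": 91.10, "f1": 92.75},
        "no": {"precision": 94.55, "recall": 97.04, "f1": 95.78},
        "weighted": {"precision": 94.82, "recall": 94.84, "f1": 94.81},
    },
    "gradient_boosted_trees": {
        "low": {"precision": 96.80, "recall": 95.61, "f1": 96.20},
        "high": {"precision": 96.49, "recall": 94.97, "f1": 95.73},
        "no": {"precision": 96.70, "recall": 97.83, "f1": 97.26},
        "weighted": {"precision": 96.70, "recall": 96.70, "f1": 96.70},
    },
    "feedforward_network": {
        "low": {"precision": 74.34, "recall": 64.94, "f1": 69.32},
        "high": {"precision": 61.93, "recall": 28.27, "f1": 38.82},
        "no": {"precision": 71.64, "recall": 87.71, "f1": 78.86},
        "weighted": {"precision": 71.14, "recall": 71.94, "f1": 70.11},
    },
    "logistic_regression": {
        "low": {"precision": 59.61, "recall": 37.61, "f1": 46.12},
        "high": {"precision": 48.77, "recall": 8.27, "f1": 14.15},
        "no": {"precision": 61.71, "recall": 89.42, "f1": 73.02},
        "weighted": {"precision": 59.15, "recall": 60.96, "f1": 55.82},
    },
}

#: 10-fold cross-validated training accuracy, percent mean (SD), from the
#: same study; used only for ranking-layout examples and consistency checks.
REFERENCE_CV_ACCURACY = {
    "extra_trees": (96.40, 0.4),
    "gradient_boosted_trees": (94.0, 0.4),
    "feedforward_network": (71.70, 0.7),
    "logistic_regression": (61.20, 0.5),
}


@dataclass
class ConfusionMatrix:
    """Counts[i][j] = rows of true class i predicted as class j."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def percentages(self) -> np.ndarray:
        """Row-normalized view in percent (zero rows stay zero)."""
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        row[row == 0.0] = np.inf
        return 100.0 * self.counts / row

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        names = [CODE_CLASSES.get(c, c) for c in self.labels]
        data = self.percentages() if percent else self.counts
        return pd.DataFrame(data, index=names, columns=names)


def confusion_matrix(y_true, y_pred, labels=CLASS_ORDER) -> ConfusionMatrix:
    """Build the confusion matrix over a fixed class order."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size == 0:
        return ConfusionMatrix(labels=tuple(labels), counts=np.zeros((len(labels), len(labels)), dtype=int))
    known = set(labels)
    unknown = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not unknown <= known:
        raise ValueError(f"unknown class label(s) {sorted(unknown - known)}")
    counts = _sk_confusion_matrix(y_true, y_pred, labels=list(labels))
    return ConfusionMatrix(labels=tuple(labels), counts=counts)


@dataclass
class ClassMetrics:
    precision: float  # percent
    recall: float  # percent
    f1: float  # percent
    support: int


@dataclass
class MetricsReport:
    per_class: dict
    macro: ClassMetrics
    weighted: ClassMetrics
    zero_division_labels: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for label, m in self.per_class.items():
            rows[CODE_CLASSES.get(label, label)] = {
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "support": m.support,
            }
        for name, m in (("macro average", self.macro), ("weighted average", self.weighted)):
            rows[name] = {
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "support": m.support,
            }
        return pd.DataFrame(rows).T


def f1_score_from(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units in, same out)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class, macro and support-weighted metrics from a confusion matrix."""
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    zero_flags: list = []
    per_class: dict = {}
    precisions, recalls, f1s, supports = [], [], [], []
    for i, label in enumerate(cm.labels):
        if col[i] == 0 or row[i] == 0:
            zero_flags.append(label)
        p = 100.0 * tp[i] / col[i] if col[i] else 0.0
        r = 100.0 * tp[i] / row[i] if row[i] else 0.0
        f1 = f1_score_from(p, r)
        per_class[label] = ClassMetrics(precision=p, recall=r, f1=f1, support=int(row[i]))
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1)
        supports.append(row[i])
    supports_arr = np.asarray(supports, dtype=float)
    total = supports_arr.sum()
    weights = supports_arr / total if total else np.zeros_like(supports_arr)
    macro = ClassMetrics(
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        support=int(total),
    )
    weighted = ClassMetrics(
        precision=float(np.dot(weights, precisions)),
        recall=float(np.dot(weights, recalls)),
        f1=float(np.dot(weights, f1s)),
        support=int(total),
    )
    return MetricsReport(
        per_class=per_class, macro=macro, weighted=weighted, zero_division_labels=zero_flags
    )


def evaluate_holdout(
    model: FittedModel, test_rows: pd.DataFrame, label_col: str = "Class"
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Score a fitted model on the (train-normalized) holdout rows."""
    if len(test_rows) == 0:
        raise ValueError("holdout set is empty")
    y_true = test_rows[label_col].to_numpy()
    y_pred = predict(model, test_rows)
    cm = confusion_matrix(y_true, y_pred)
    return precision_recall_f1(cm), cm


@dataclass
class ComparisonTables:
    cv_table: pd.DataFrame  # per-model CV accuracy, mean (SD) in percent
    holdout_table: pd.DataFrame  # per-model per-class metrics plus averages
    ranking: list  # model names ordered by weighted holdout F1, best first


def compare_models(
    reports: dict[str, MetricsReport],
    cv_results: dict[str, CVResult] | None = None,
) -> ComparisonTables:
    """Assemble the cross-validation and holdout comparison tables.

    Models are ranked by weighted holdout F1 (descending); the ranking is a
    permutation of the input model names.
    """
    if not reports:
        raise ValueError("need at least one model report")
    cv_rows = []
    if cv_results:
        for name, res in cv_results.items():
            cv_rows.append(
                {
                    "model": name,
                    "cv_accuracy_mean_pct": 100.0 * res.mean,
                    "cv_accuracy_sd_pct": 100.0 * res.sd,
                    "display": f"{100.0 * res.mean:.2f} ({100.0 * res.sd:.1f})",
                }
            )
    cv_table = pd.DataFrame(
        cv_rows, columns=["model", "cv_accuracy_mean_pct", "cv_accuracy_sd_pct", "display"]
    )
    if len(cv_table):
        cv_table = cv_table.sort_values(
            "cv_accuracy_mean_pct", ascending=False, ignore_index=True
        )

    hold_rows = []
    for name, rep in reports.items():
        frame = rep.to_frame().reset_index(names="label")
        frame.insert(0, "model", name)
        hold_rows.append(frame)
    holdout_table = pd.concat(hold_rows, ignore_index=True)

    ranking = sorted(reports, key=lambda name: reports[name].weighted.f1, reverse=True)
    return ComparisonTables(cv_table=cv_table, holdout_table=holdout_table, ranking=ranking)


def rank_by_weighted_f1(weighted_f1: dict[str, float]) -> list[str]:
    """Order model names by a weighted-F1 mapping, best first."""
    return sorted(weighted_f1, key=weighted_f1.__getitem__, reverse=True)
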