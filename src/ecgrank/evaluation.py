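"""Per-model evaluation: confusion counts, accuracy, F1, AUC (all on the
percent scale), and the decision-matrix assembly feeding the ranking stage.

The positive class is the abnormal beat (label 1).  AUC is the rank
statistic — the probability that a random positive outscores a random
negative, ties counting one half — which is exactly the area under the ROC
curve.  ``printed_precision`` reproduces the table dialect of the reference
experiments (F1 to integers, AUC/accuracy to 2 decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifiers import PredictionSet

__all__ = [
    "ConfusionCounts", "MetricRow", "MetricTable",
    "confusion", "accuracy", "f1", "auc",
    "build_metric_table", "printed_precision",
    "read_metric_csv", "write_metric_csv",
]

METRIC_COLUMNS = ("Auc", "f1-score", "Accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positive class = abnormal (label 1)."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricRow:
    model_id: str
    auc: float
    f1: float
    accuracy: float


@dataclass
class MetricTable:
    """m models x 3 criteria (percent scale) — the TOPSIS decision matrix."""

    rows: list[MetricRow]
    dataset_tag: str = ""
    feature_tag: str = ""

    def __post_init__(self) -> None:
        ids = [r.model_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated model_id in metric table")
        if not self.rows:
            raise ValueError("metric table must have at least one row")

    @property
    def model_ids(self) -> list[str]:
        return [r.model_id for r in self.rows]

    @property
    def matrix(self) -> np.ndarray:
        """m x 3 array in column order (AUC, F1, Accuracy)."""
        return np.array([[r.auc, r.f1, r.accuracy] for r in self.rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Method": self.model_ids,
            "Auc": [r.auc for r in self.rows],
            "f1-score": [r.f1 for r in self.rows],
            "Accuracy": [r.accuracy for r in self.rows],
        })


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", t), ("predicted", p)):
        if v.size and not np.all(np.isin(v, (0, 1))):
            raise ValueError(f"{name} labels outside {{0, 1}}")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        FP=int(np.sum((t == 0) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FN=int(np.sum((t == 1) & (p == 0))))


def accuracy(c: ConfusionCounts) -> float:
    """100 * (TP + TN) / n."""
    if c.n == 0:
        raise ValueError("empty confusion counts")
    return 100.0 * (c.TP + c.TN) / c.n


def f1(c: ConfusionCounts) -> float:
    """100 * 2TP / (2TP + FP + FN) for the positive (abnormal) class."""
    denom = 2 * c.TP + c.FP + c.FN
    if c.n == 0:
        raise ValueError("empty confusion counts")
    if denom == 0:  # no positives anywhere: define F1 as 0
        return 0.0
    return 100.0 * 2 * c.TP / denom


def auc(true_labels, scores) -> float:
    """Rank-statistic AUC on the percent scale (ties count one half)."""
    t = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return 100.0 * u / (n_pos * n_neg)


def build_metric_table(prediction_sets: list[PredictionSet],
                       true_labels, dataset_tag: str = "",
                       feature_tag: str = "") -> MetricTable:
    """One (AUC, F1, accuracy) row per model; full precision retained."""
    t = np.asarray(true_labels, dtype=int)
    rows = []
    for ps in prediction_sets:
        if ps.labels.shape[0] != t.shape[0]:
            raise ValueError(f"{ps.model_id}: prediction length mismatch")
        c = confusion(t, ps.labels)
        rows.append(MetricRow(model_id=ps.model_id,
                              auc=auc(t, ps.scores),
                              f1=f1(c), accuracy=accuracy(c)))
    return MetricTable(rows=rows, dataset_tag=dataset_tag,
                       feature_tag=feature_tag)


def printed_precision(table: MetricTable) -> MetricTable:
    """Display-rounding mode: F1 to the nearest integer, AUC and accuracy
    to 2 decimals — the precision of the reference metric tables."""
    rows = [MetricRow(r.model_id, round(r.auc, 2), float(round(r.f1)),
                      round(r.accuracy, 2)) for r in table.rows]
    return MetricTable(rows=rows, dataset_tag=table.dataset_tag,
                       feature_tag=table.feature_tag)


def write_metric_csv(table: MetricTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_metric_csv(path, dataset_tag: str = "",
                    feature_tag: str = "") -> MetricTable:
    """Read a metric-table CSV (columns Method, Auc, f1-score, Accuracy)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed metric CSV: {exc}") from exc
    missing = [c for c in ("Method",) + METRIC_COLUMNS
               if c not in df.columns]
    if missing:
        raise ValueError(f"metric CSV missing columns {missing}")
    for col in METRIC_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2  # 1-based + header
            raise ValueError(f"non-numeric value in column {col!r} "
                             f"at line {line}")
        df[col] = vals
    rows = [MetricRow(str(m), float(a), float(f), float(acc))
            for m, a, f, acc in zip(df["Method"], df["Auc"],
                                    df["f1-score"], df["Accuracy"])]
    return MetricTable(rows=rows, dataset_tag=dataset_tag,
                       feature_tag=feature_tag)
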