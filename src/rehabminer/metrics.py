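"""Per-class and aggregate P / R / F1 / AUPR / AUC for relation classification.

Conventions:

* P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); any 0/0 is defined as 0
  and logged.
* The aggregate "Total" row is the support-weighted mean of the per-class
  values (the only common scheme whose total precision, recall and F1 can
  all differ, as observed in practice); the micro average is reported
  alongside it.
* AUC is the one-vs-rest ROC area (rank statistic); AUPR is the step-wise
  average-precision area, which avoids the optimistic trapezoidal
  interpolation of PR points.  Classes absent from the true labels have
  undefined areas and are reported as missing (NaN).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .corpus_io import RELATION_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "prf",
    "aggregate",
    "auc_ovr",
    "aupr_ovr",
    "classification_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def support(self) -> int:
        return self.tp + self.fn


def confusion_counts(
    y_true, y_pred, labels: tuple[str, ...] = RELATION_LABELS
) -> dict[str, ConfusionCounts]:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    out = {}
    for lab in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
        out[lab] = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=len(y_true) - tp - fp - fn)
    return out


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("0/0 in %s defined as 0", what)
        return 0.0
    return num / den


def prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from one-vs-rest counts."""
    p = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    r = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_div(2.0 * p * r, p + r, "F1")
    return p, r, f1


def aggregate(
    per_class: dict[str, tuple[float, float, float]], supports: dict[str, int]
) -> dict[str, dict[str, float]]:
    """Support-weighted ("Total") and micro aggregates of per-class P/R/F1."""
    total_support = sum(supports.values())
    weighted = {}
    for i, name in enumerate(("P", "R", "F1")):
        weighted[name] = (
            sum(per_class[lab][i] * supports[lab] for lab in per_class) / total_support
            if total_support
            else 0.0
        )
    # single-label multi-class: micro P = micro R = micro F1 = accuracy,
    # and accuracy = support-weighted recall (sum TP / n)
    acc = weighted["R"]
    return {"weighted": weighted, "micro": {"P": acc, "R": acc, "F1": acc}}


def classification_report(
    y_true, y_pred, labels: tuple[str, ...] = RELATION_LABELS, probs=None
) -> "MetricReport":
    """Full per-class + Total report; adds AUPR/AUC when probs are given.

    ``probs`` must be an (n, len(labels)) row-stochastic matrix aligned with
    ``labels``.
    """
    counts = confusion_counts(y_true, y_pred, labels)
    per_class = {lab: prf(counts[lab]) for lab in labels}
    supports = {lab: counts[lab].support for lab in labels}
    n = len(list(y_true))
    micro_tp = sum(counts[lab].tp for lab in labels)
    micro_fp = sum(counts[lab].fp for lab in labels)
    micro_fn = sum(counts[lab].fn for lab in labels)
    micro_p = _safe_div(micro_tp, micro_tp + micro_fp, "micro precision")
    micro_r = _safe_div(micro_tp, micro_tp + micro_fn, "micro recall")
    micro_f1 = _safe_div(2 * micro_p * micro_r, micro_p + micro_r, "micro F1")
    agg = aggregate(per_class, supports)["weighted"]

    auc = aupr = None
    if probs is not None:
        auc = auc_ovr(y_true, probs, labels)
        aupr = aupr_ovr(y_true, probs, labels)
    rows = {}
    for lab in labels:
        p, r, f1 = per_class[lab]
        rows[lab] = {
            "P": p, "R": r, "F1": f1,
            "AUPR": aupr[lab] if aupr else float("nan"),
            "AUC": auc[lab] if auc else float("nan"),
            "support": supports[lab],
        }
    total = {
        "P": agg["P"], "R": agg["R"], "F1": agg["F1"],
        "AUPR": aupr["Total"] if aupr else float("nan"),
        "AUC": auc["Total"] if auc else float("nan"),
        "support": n,
    }
    micro = {"P": micro_p, "R": micro_r, "F1": micro_f1}
    return MetricReport(rows=rows, total=total, micro=micro, labels=labels)


def _ovr_area(y_true, probs, labels, score_fn) -> dict[str, float]:
    y_true = list(y_true)
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(y_true), len(labels)):
        raise ValueError("probs shape does not match labels")
    areas: dict[str, float] = {}
    weights: dict[str, int] = {}
    for j, lab in enumerate(labels):
        ind = np.array([1 if t == lab else 0 for t in y_true])
        if ind.sum() in (0, len(ind)):
            logger.warning("class %s absent (or universal); area undefined", lab)
            areas[lab] = float("nan")
            continue
        areas[lab] = float(score_fn(ind, probs[:, j]))
        weights[lab] = int(ind.sum())
    defined = [lab for lab in labels if not np.isnan(areas[lab])]
    wsum = sum(weights[lab] for lab in defined)
    areas["Total"] = (
        sum(areas[lab] * weights[lab] for lab in defined) / wsum
        if wsum
        else float("nan")
    )
    return areas


def auc_ovr(y_true, probs, labels: tuple[str, ...] = RELATION_LABELS):
    """One-vs-rest ROC areas per class plus the support-weighted Total."""
    return _ovr_area(y_true, probs, labels, roc_auc_score)


def aupr_ovr(y_true, probs, labels: tuple[str, ...] = RELATION_LABELS):
    """One-vs-rest average-precision areas plus the support-weighted Total."""
    return _ovr_area(y_true, probs, labels, average_precision_score)


@dataclass
class MetricReport:
    rows: dict[str, dict[str, float]]
    total: dict[str, float]
    micro: dict[str, float]
    labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Rows DS..UKN then Total, columns P/R/F1/AUPR/AUC/support."""
        data = {lab: self.rows[lab] for lab in self.labels}
        data["Total"] = self.total
        return pd.DataFrame(data).T[["P", "R", "F1", "AUPR", "AUC", "support"]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="Relationship category")

    def to_json(self, path) -> None:
        payload = {
            "per_class": self.rows,
            "total": self.total,
            "micro": self.micro,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)
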