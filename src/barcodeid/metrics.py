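"""Multiclass performance metrics with one-vs-rest ROC analysis.

For a multiclass classifier the per-class view reduces the problem to binary
one-vs-rest (OvR): one class is "positive", all others pooled as "negative".
From the resulting 2x2 confusion counts the standard scalar metrics follow:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = recall = TPR = TP / (TP + FN)
    specificity = TNR = TN / (TN + FP)
    FPR         = 1 - specificity = FP / (FP + TN)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

ROC curves are computed per class over the thresholds induced by the
predicted class probabilities and integrated by the trapezoidal rule; the
macro AUROC is the unweighted mean over classes present in the truth.  The
overall multiclass accuracy is always computed on the raw labels, never
through an OvR reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "ScalarMetrics",
    "RocCurve",
    "MetricsReport",
    "confusion",
    "scalar_metrics",
    "binary_roc",
    "ovr_roc",
    "macro_average",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally of a one-vs-rest reduction."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ScalarMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    precision: float
    f1: float
    #: names of metrics whose denominator was zero (reported as 0.0)
    degenerate: tuple[str, ...] = ()


def confusion(
    y_true: Sequence[int], y_pred: Sequence[int], positive_class: int
) -> ConfusionCounts:
    """OvR binarization against ``positive_class`` followed by a 2x2 tally."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError(
            f"label vectors differ in length: {t.shape[0]} vs {p.shape[0]}"
        )
    pos_t = t == positive_class
    pos_p = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def scalar_metrics(counts: ConfusionCounts) -> ScalarMetrics:
    """Scalar metrics from one OvR confusion tally.

    Zero-denominator cases (no positives, no predicted positives, ...) are
    reported as 0.0 and flagged in ``degenerate`` rather than raising, so
    per-class loops over imbalanced data never abort.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    degenerate: list[str] = []
    accuracy = (counts.tp + counts.tn) / counts.total
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", degenerate)
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity", degenerate)
    fpr = 1.0 - specificity if "specificity" not in degenerate else 0.0
    if "specificity" in degenerate:
        degenerate.append("fpr")
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", degenerate)
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        degenerate.append("f1")
        f1 = 0.0
    if degenerate:
        warnings.warn(
            f"zero-denominator metrics reported as 0.0: {degenerate}", stacklevel=2
        )
    return ScalarMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        fpr=fpr,
        precision=precision,
        f1=f1,
        degenerate=tuple(degenerate),
    )


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def binary_roc(y_positive: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC of a binary problem from scores for the positive class.

    Thresholds are the distinct score values (descending) with a sentinel
    above the maximum, giving the standard step curve from (0,0) to (1,1);
    the area is the trapezoidal integral, which equals the Mann-Whitney
    concordance probability with ties counted 1/2.
    """
    y = np.asarray(y_positive, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return RocCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]), float("nan"))
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # last index of each distinct-score run
    boundary = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[boundary]
    fp = (boundary + 1) - tp
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def ovr_roc(
    y_true: Sequence[int],
    class_probabilities: np.ndarray,
    classes: Sequence[int] | None = None,
    atol: float = 1e-6,
) -> tuple[dict[int, RocCurve], float]:
    """Per-class OvR ROC curves and the macro-average AUROC.

    ``class_probabilities`` has one column per class (rows summing to 1
    within ``atol``); ``classes`` gives the class code of each column and
    defaults to 0..S-1.  A class absent from ``y_true`` gets AUROC NaN and is
    excluded from the macro average with a warning.
    """
    proba = np.asarray(class_probabilities, dtype=float)
    y = np.asarray(y_true)
    if proba.ndim != 2 or proba.shape[1] < 2:
        raise ValueError("class_probabilities must be (n_samples, >=2 classes)")
    if proba.shape[0] != y.shape[0]:
        raise ValueError("y_true and probability matrix disagree on n_samples")
    row_sums = proba.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=atol):
        raise ValueError("probability rows must sum to 1")
    if classes is None:
        classes = list(range(proba.shape[1]))
    curves: dict[int, RocCurve] = {}
    aucs: list[float] = []
    for j, cls in enumerate(classes):
        curve = binary_roc(y == cls, proba[:, j])
        curves[cls] = curve
        if np.isnan(curve.auc):
            warnings.warn(
                f"class {cls} absent from y_true; excluded from macro AUROC",
                stacklevel=2,
            )
        else:
            aucs.append(curve.auc)
    if not aucs:
        raise ValueError("no class present in y_true; macro AUROC undefined")
    return curves, macro_average(aucs)


def macro_average(per_class_scores: Sequence[float]) -> float:
    """Unweighted arithmetic mean over classes."""
    scores = np.asarray(per_class_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("macro_average of an empty score list")
    return float(scores.mean())


@dataclass
class MetricsReport:
    """Full evaluation of one prediction set.

    ``per_class`` carries one row per class (code, species, support, auroc,
    precision, recall, specificity, fpr, f1); ``macro`` and ``weighted`` are
    the unweighted and support-weighted aggregates of the per-class scores.
    """

    accuracy: float
    per_class: pd.DataFrame
    macro: dict[str, float]
    weighted: dict[str, float]
    macro_auroc: float
    roc_curves: dict[int, RocCurve] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Per-class rows plus macro / weighted summary rows."""
        rows = self.per_class.copy()
        extra = []
        for name, agg in (("macro", self.macro), ("weighted", self.weighted)):
            extra.append(
                {
                    "code": "",
                    "species": name,
                    "support": int(rows["support"].sum()),
                    "auroc": self.macro_auroc if name == "macro" else np.nan,
                    "accuracy": self.accuracy,
                    **{m: agg[m] for m in ("precision", "recall", "f1")},
                }
            )
        return pd.concat([rows, pd.DataFrame(extra)], ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def write_roc_tsv(self, path: str | Path) -> None:
        """ROC curve points, one (class, fpr, tpr) row per threshold."""
        frames = [
            pd.DataFrame({"class": cls, "fpr": c.fpr, "tpr": c.tpr})
            for cls, c in self.roc_curves.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )

    def plot_roc(self, path: str | Path) -> None:
        """One-vs-rest ROC curves for every class, saved to ``path``."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for cls, curve in self.roc_curves.items():
            ax.plot(curve.fpr, curve.tpr, lw=1, label=f"class {cls} (AUC={curve.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"One-vs-rest ROC (macro AUROC = {self.macro_auroc:.3f})")
        ax.legend(fontsize=6, loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def evaluate_predictions(
    y_true: Sequence[int],
    class_probabilities: np.ndarray,
    label_map: Mapping[str, int] | None = None,
) -> MetricsReport:
    """Score hard predictions (argmax) and probabilistic output together."""
    proba = np.asarray(class_probabilities, dtype=float)
    y = np.asarray(y_true)
    y_pred = proba.argmax(axis=1)
    inverse = (
        {code: name for name, code in label_map.items()} if label_map else {}
    )
    n_classes = proba.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes handled below
        curves, macro_auroc = ovr_roc(y, proba)
    rows = []
    for cls in range(n_classes):
        counts = confusion(y, y_pred, positive_class=cls)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scal = scalar_metrics(counts)
        rows.append(
            {
                "code": cls,
                "species": inverse.get(cls, str(cls)),
                "support": int(np.sum(y == cls)),
                "auroc": curves[cls].auc,
                "precision": scal.precision,
                "recall": scal.sensitivity,
                "specificity": scal.specificity,
                "fpr": scal.fpr,
                "f1": scal.f1,
            }
        )
    per_class = pd.DataFrame(rows)
    support = per_class["support"].to_numpy(dtype=float)
    macro = {
        m: macro_average(per_class[m]) for m in ("precision", "recall", "f1")
    }
    if support.sum() > 0:
        weighted = {
            m: float(np.average(per_class[m], weights=support))
            for m in ("precision", "recall", "f1")
        }
    else:  # pragma: no cover - guarded upstream
        weighted = dict(macro)
    return MetricsReport(
        accuracy=float(np.mean(y == y_pred)),
        per_class=per_class,
        macro=macro,
        weighted=weighted,
        macro_auroc=macro_auroc,
        roc_curves=curves,
    )
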