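"""Evaluation statistics: confusion matrices, the benign/malignant
grouping, ROC/AUC by threshold sweep, and the McNemar paired test.

Convention throughout: confusion-matrix rows are true classes, columns
are predicted classes. ROC points are fractions in [0, 1]; the TPR/FPR
fields of :class:`BinaryMetrics` are percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from dermokit.labels import BENIGN_CLASSES, CLASS_NAMES, MALIGNANT_CLASSES

__all__ = [
    "ConfusionMatrix",
    "BinaryMetrics",
    "RocCurve",
    "McNemarCounts",
    "confusion_matrix",
    "group_benign_malignant",
    "binary_rates",
    "roc_curve",
    "mcnemar",
    "paired_table",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = len(self.class_names)
        if c.shape != (n, n):
            raise ValueError(f"counts shape {c.shape} != ({n}, {n})")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)


@dataclass(frozen=True)
class BinaryMetrics:
    """Counts plus rates in percent: TPR = TP/(TP+FN)*100,
    FPR = FP/(TN+FP)*100."""

    TP: int
    TN: int
    FP: int
    FN: int
    TPR: float
    FPR: float


@dataclass
class RocCurve:
    """Threshold-sweep ROC: ordered (FPR, TPR) fraction pairs, from (0,0)
    to (1,1), with trapezoidal AUC."""

    points: List[Tuple[float, float]]
    auc: float


@dataclass(frozen=True)
class McNemarCounts:
    """Discordant counts of a paired comparison: b = system A wrong while
    B right; c = B wrong while A right."""

    b: int
    c: int
    chi2: float


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_names: Sequence[str] = CLASS_NAMES,
) -> ConfusionMatrix:
    """Tally counts[i][j] = #{samples of true class i predicted as j}."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    names = tuple(class_names)
    index = {name: i for i, name in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=names)


def group_benign_malignant(matrix: ConfusionMatrix) -> ConfusionMatrix:
    """Collapse the 10-class matrix to 2x2 over {benign, malignant}.

    Benign: vascular lesions, nevus, solar lentigo, dermatofibroma,
    seborrheic keratosis, benign keratosis. Malignant: actinic keratosis,
    basal cell carcinoma, squamous cell carcinoma, melanoma. Cell sums
    are preserved.
    """
    known = set(BENIGN_CLASSES) | set(MALIGNANT_CLASSES)
    unknown = [n for n in matrix.class_names if n not in known]
    if unknown:
        raise ValueError(f"cannot group unknown categories: {unknown}")
    group_of = {n: 0 for n in BENIGN_CLASSES}
    group_of.update({n: 1 for n in MALIGNANT_CLASSES})
    out = np.zeros((2, 2), dtype=np.int64)
    for i, ti in enumerate(matrix.class_names):
        for j, pj in enumerate(matrix.class_names):
            out[group_of[ti], group_of[pj]] += matrix.counts[i, j]
    return ConfusionMatrix(counts=out, class_names=("benign", "malignant"))


def binary_rates(matrix: ConfusionMatrix, positive_class: str = "malignant") -> BinaryMetrics:
    """TPR/FPR in percent from a 2x2 matrix (rows true, columns predicted)."""
    if matrix.counts.shape != (2, 2):
        raise ValueError("binary_rates requires a 2x2 matrix")
    if positive_class not in matrix.class_names:
        raise ValueError(f"positive class {positive_class!r} not in {matrix.class_names}")
    pos = matrix.class_names.index(positive_class)
    neg = 1 - pos
    TP = int(matrix.counts[pos, pos])
    FN = int(matrix.counts[pos, neg])
    FP = int(matrix.counts[neg, pos])
    TN = int(matrix.counts[neg, neg])
    if TP + FN == 0:
        raise ZeroDivisionError("no positive samples: TPR undefined")
    if TN + FP == 0:
        raise ZeroDivisionError("no negative samples: FPR undefined")
    return BinaryMetrics(
        TP=TP,
        TN=TN,
        FP=FP,
        FN=FN,
        TPR=TP / (TP + FN) * 100.0,
        FPR=FP / (TN + FP) * 100.0,
    )


def roc_curve(scores: Sequence[float], truths: Sequence[int]) -> RocCurve:
    """ROC by sweeping a threshold over the unique scores, plus the
    trapezoidal AUC. Tied scores collapse into a single staircase step,
    which counts ties as half-concordant in the area."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(truths)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truths must be equal-length 1-D sequences")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run (one threshold step)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = [(float(f), float(t)) for f, t in zip(fpr, tpr)]
    return RocCurve(points=points, auc=auc)


def mcnemar(b: int, c: int) -> float:
    """McNemar statistic (b - c)^2 / (b + c); undefined when b + c = 0."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        raise ZeroDivisionError("b + c = 0: McNemar statistic undefined")
    return (b - c) ** 2 / (b + c)


def paired_table(
    preds_a: Sequence[str], preds_b: Sequence[str], truths: Sequence[str]
) -> McNemarCounts:
    """Discordant counts of two classifiers on the same samples.

    b counts samples where A is wrong and B right, c the reverse; the
    chi-squared statistic is attached via :func:`mcnemar` (0 when both
    counts are 0, by the b = c symmetry).
    """
    if not (len(preds_a) == len(preds_b) == len(truths)):
        raise ValueError("prediction and truth sequences differ in length")
    b = sum(1 for pa, pb, t in zip(preds_a, preds_b, truths) if pa != t and pb == t)
    c = sum(1 for pa, pb, t in zip(preds_a, preds_b, truths) if pb != t and pa == t)
    chi2 = 0.0 if b + c == 0 else mcnemar(b, c)
    return McNemarCounts(b=b, c=c, chi2=chi2)


def report(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    malignant_scores: Sequence[float] = None,
    class_names: Sequence[str] = CLASS_NAMES,
) -> Dict:
    """Bundle the full evaluation into a JSON-serializable dict."""
    cm = confusion_matrix(true_labels, predicted_labels, class_names)
    out: Dict = {
        "n_samples": cm.total,
        "accuracy": cm.accuracy,
        "confusion_matrix": cm.counts.tolist(),
        "class_names": list(cm.class_names),
    }
    if set(class_names) <= set(CLASS_NAMES):
        cm2 = group_benign_malignant(cm)
        out["confusion_matrix_2class"] = cm2.counts.tolist()
        try:
            rates = binary_rates(cm2, positive_class="malignant")
            out["binary"] = {
                "TP": rates.TP,
                "TN": rates.TN,
                "FP": rates.FP,
                "FN": rates.FN,
                "TPR_percent": rates.TPR,
                "FPR_percent": rates.FPR,
            }
        except ZeroDivisionError:
            pass
        if malignant_scores is not None:
            y = [1 if t in MALIGNANT_CLASSES else 0 for t in true_labels]
            try:
                roc = roc_curve(malignant_scores, y)
                out["roc"] = {"points": roc.points, "auc": roc.auc}
            except ValueError:
                pass
    return out
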