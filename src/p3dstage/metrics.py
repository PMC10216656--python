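"""Multiclass staging metrics: confusion-matrix rates and one-vs-rest ROC/AUC.

Conventions
-----------
* Class order is fixed: ``("mild", "moderate", "severe")``.
* Confusion matrices are oriented rows = predicted, columns = actual, so each
  column sums to the true number of samples in that class.
* AUC is the rank statistic ``(Σ ranks of positives − M(M+1)/2) / (M·N)`` with
  samples ranked ascending by the positive-class score and ties assigned mean
  ranks (the Mann–Whitney convention); it equals the trapezoidal area under
  the ROC curve.
* Metrics with a zero denominator (e.g. precision of a never-predicted class)
  are reported as ``nan`` and flagged, never silently coerced to 0 — silent
  zeros would corrupt macro averages.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

from .errors import InvalidArgumentError, UndefinedMetricError

__all__ = [
    "CLASS_NAMES",
    "ConfusionMatrix",
    "ScoreTable",
    "PerClassMetrics",
    "MetricReport",
    "confusion_from_predictions",
    "accuracy",
    "per_class_metrics",
    "auc_rank",
    "roc_curve",
    "averaged_roc",
    "build_report",
    "scores_to_predictions",
    "write_report_csv",
    "write_report_json",
    "write_roc_csv",
    "plot_roc",
    "plot_confusion",
]

CLASS_NAMES = ("mild", "moderate", "severe")
_CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


def _label_index(label) -> int:
    if isinstance(label, (int, np.integer)):
        if 0 <= int(label) < len(CLASS_NAMES):
            return int(label)
        raise InvalidArgumentError(f"label index {label} out of range")
    try:
        return _CLASS_INDEX[str(label)]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown stage label {label!r}; expected one of {CLASS_NAMES}"
        ) from None


@dataclass(frozen=True)
class ConfusionMatrix:
    """3×3 counts with rows = predicted class, columns = actual class."""

    counts: tuple

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise InvalidArgumentError(
                f"confusion matrix must be 3x3 non-negative, got shape {arr.shape}")
        object.__setattr__(self, "counts", tuple(map(tuple, arr.tolist())))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def num(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class ScoreTable:
    """Per-sample class-score vectors plus true labels.

    Scores are normalised to the simplex on construction (non-negative,
    summing to one per sample).
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        y = np.asarray([_label_index(v) for v in np.asarray(self.labels).ravel()])
        if s.ndim != 2 or s.shape[1] != len(CLASS_NAMES):
            raise InvalidArgumentError(
                f"scores must be (n, {len(CLASS_NAMES)}), got {s.shape}")
        if s.shape[0] != y.shape[0]:
            raise InvalidArgumentError(
                f"{s.shape[0]} score rows vs {y.shape[0]} labels")
        if not np.isfinite(s).all() or (s < 0).any():
            raise InvalidArgumentError("scores must be finite and non-negative")
        totals = s.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise InvalidArgumentError("each sample needs a nonzero score vector")
        object.__setattr__(self, "scores", s / totals)
        object.__setattr__(self, "labels", y)

    def __len__(self):
        return self.scores.shape[0]


def confusion_from_predictions(predicted, actual) -> ConfusionMatrix:
    """Tally ``counts[p][a]`` = number of samples predicted ``p`` with actual ``a``."""
    p = [_label_index(v) for v in predicted]
    a = [_label_index(v) for v in actual]
    if len(p) != len(a):
        raise InvalidArgumentError(
            f"{len(p)} predictions vs {len(a)} actual labels")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (p, a), 1)
    return ConfusionMatrix(tuple(map(tuple, counts.tolist())))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples: trace / total."""
    if cm.num == 0:
        raise UndefinedMetricError("accuracy undefined for an empty matrix")
    return float(np.trace(cm.array)) / cm.num


@dataclass(frozen=True)
class PerClassMetrics:
    precision: float
    recall: float
    specificity: float
    f1: float
    undefined: tuple = ()


def per_class_metrics(cm: ConfusionMatrix, class_i) -> PerClassMetrics:
    """One-vs-rest precision, recall, specificity and F1 for one class.

    With class ``i`` as positive: TP is the diagonal cell, FP the rest of row
    ``i`` (predicted ``i``, actually other), FN the rest of column ``i``, and
    TN everything else.  F1 is the harmonic mean of precision and recall.
    """
    if cm.num == 0:
        raise UndefinedMetricError("metrics undefined for an empty matrix")
    i = _label_index(class_i)
    arr = cm.array
    tp = arr[i, i]
    fp = arr[i].sum() - tp
    fn = arr[:, i].sum() - tp
    tn = cm.num - tp - fp - fn

    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return float(num) / float(den)

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, fp + tn, "specificity")
    if "precision" in undefined or "recall" in undefined or precision + recall == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return PerClassMetrics(precision, recall, specificity, f1, tuple(undefined))


def _binary(table: ScoreTable, positive_class):
    i = _label_index(positive_class)
    y = (table.labels == i).astype(int)
    s = table.scores[:, i]
    return y, s


def auc_rank(table: ScoreTable, positive_class) -> float:
    """Rank-statistic AUC for one class against the rest.

    Ranks all samples ascending by the positive-class score (mean ranks on
    ties) and returns ``(Σ positive ranks − M(M+1)/2) / (M·N)`` with ``M``
    positives and ``N`` negatives.
    """
    y, s = _binary(table, positive_class)
    m, n = int(y.sum()), int((1 - y).sum())
    if m == 0 or n == 0:
        raise UndefinedMetricError(
            f"AUC for {positive_class!r} needs both positives and negatives "
            f"(M={m}, N={n})")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def roc_curve(table: ScoreTable, positive_class):
    """One-vs-rest ROC points ``(fpr, tpr)`` swept over distinct scores.

    Endpoints (0,0) and (1,1) are always included; the trapezoidal area under
    the returned polyline equals :func:`auc_rank` to floating-point accuracy.
    """
    y, s = _binary(table, positive_class)
    m, n = int(y.sum()), int((1 - y).sum())
    if m == 0 or n == 0:
        raise UndefinedMetricError(
            f"ROC for {positive_class!r} needs both positives and negatives")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep the last index of each run of equal scores (one point per threshold)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / m]
    fpr = np.r_[0.0, fp[distinct] / n]
    return np.column_stack([fpr, tpr])


def _trapezoid_area(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def scores_to_predictions(table: ScoreTable) -> np.ndarray:
    """Argmax labels; ties resolved to the lowest class index (deterministic)."""
    return table.scores.argmax(axis=1)


def averaged_roc(table: ScoreTable):
    """Micro- and macro-averaged one-vs-rest ROC curves and AUCs.

    Micro: every entry of the one-hot label indicator matrix is treated as its
    own binary decision, i.e. one ROC over the flattened indicator matrix
    against the flattened score matrix.  Macro: per-class TPR curves are
    interpolated onto the union of all per-class FPR breakpoints and averaged
    with equal weight; the macro AUC is the trapezoidal area of that mean
    curve.  Classes absent from the truth are excluded from the macro average
    with a warning.

    Returns ``{"micro": (points, auc), "macro": (points, auc)}``.
    """
    present = sorted(set(table.labels.tolist()))
    if len(present) < 2:
        raise UndefinedMetricError("averaged ROC needs at least two classes present")

    # micro: flatten indicator matrix vs flatten scores
    onehot = np.zeros_like(table.scores)
    onehot[np.arange(len(table)), table.labels] = 1.0
    flat_y = onehot.ravel().astype(int)
    flat_s = table.scores.ravel()
    order = np.argsort(-flat_s, kind="stable")
    ys, ss = flat_y[order], flat_s[order]
    m, n = int(ys.sum()), int((1 - ys).sum())
    tp, fp = np.cumsum(ys), np.cumsum(1 - ys)
    distinct = np.r_[np.diff(ss) != 0, True]
    micro_pts = np.column_stack([np.r_[0.0, fp[distinct] / n],
                                 np.r_[0.0, tp[distinct] / m]])
    micro_auc = _trapezoid_area(micro_pts)

    # macro: mean per-class TPR on the union FPR grid
    curves = []
    for i in range(len(CLASS_NAMES)):
        if i not in present:
            warnings.warn(
                f"class {CLASS_NAMES[i]!r} absent from the truth; "
                f"excluded from the macro average", stacklevel=2)
            continue
        curves.append(roc_curve(table, i))
    grid = np.unique(np.concatenate([c[:, 0] for c in curves]))
    mean_tpr = np.zeros_like(grid)
    for c in curves:
        mean_tpr += np.interp(grid, c[:, 0], c[:, 1])
    mean_tpr /= len(curves)
    macro_pts = np.column_stack([grid, mean_tpr])
    macro_auc = _trapezoid_area(macro_pts)
    return {"micro": (micro_pts, micro_auc), "macro": (macro_pts, macro_auc)}


@dataclass
class MetricReport:
    """Accuracy plus per-class rates, AUCs and ROC curves."""

    accuracy: float
    per_class: dict = field(default_factory=dict)   # name -> PerClassMetrics
    auc: dict = field(default_factory=dict)         # name -> float
    roc: dict = field(default_factory=dict)         # name -> (k,2) points
    micro_auc: float = float("nan")
    macro_auc: float = float("nan")
    confusion: ConfusionMatrix | None = None


def build_report(table: ScoreTable) -> MetricReport:
    """Assemble the full report from per-sample scores and true labels."""
    preds = scores_to_predictions(table)
    cm = confusion_from_predictions(preds, table.labels)
    report = MetricReport(accuracy=accuracy(cm), confusion=cm)
    for i, name in enumerate(CLASS_NAMES):
        report.per_class[name] = per_class_metrics(cm, i)
        try:
            report.auc[name] = auc_rank(table, i)
            report.roc[name] = roc_curve(table, i)
        except UndefinedMetricError:
            report.auc[name] = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        avg = averaged_roc(table)
    report.micro_auc = avg["micro"][1]
    report.macro_auc = avg["macro"][1]
    report.roc["micro"] = avg["micro"][0]
    report.roc["macro"] = avg["macro"][0]
    return report


# ---------------------------------------------------------------------------
# Writers (full precision internally; CSV formatted at 3 decimals)
# ---------------------------------------------------------------------------

def write_report_csv(report: MetricReport, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "precision", "recall", "specificity", "f1", "auc"])
        for name in CLASS_NAMES:
            pc = report.per_class[name]
            w.writerow([name] + [f"{v:.3f}" for v in
                                 (pc.precision, pc.recall, pc.specificity, pc.f1,
                                  report.auc[name])])
        w.writerow(["accuracy", f"{report.accuracy:.3f}", "", "", "", ""])
        w.writerow(["micro_auc", f"{report.micro_auc:.3f}", "", "", "", ""])
        w.writerow(["macro_auc", f"{report.macro_auc:.3f}", "", "", "", ""])


def write_report_json(report: MetricReport, path) -> None:
    payload = {
        "accuracy": report.accuracy,
        "micro_auc": report.micro_auc,
        "macro_auc": report.macro_auc,
        "per_class": {name: asdict(pc) for name, pc in report.per_class.items()},
        "auc": report.auc,
        "confusion": report.confusion.counts if report.confusion else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_roc_csv(report: MetricReport, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "fpr", "tpr"])
        for name, pts in report.roc.items():
            for fpr, tpr in pts:
                w.writerow([name, f"{fpr:.6f}", f"{tpr:.6f}"])


def plot_roc(report: MetricReport, path) -> None:
    """ROC overlay (per class plus micro/macro averages)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, pts in report.roc.items():
        auc = {"micro": report.micro_auc, "macro": report.macro_auc}.get(
            name, report.auc.get(name))
        style = "--" if name in ("micro", "macro") else "-"
        ax.plot(pts[:, 0], pts[:, 1], style, label=f"{name} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(report: MetricReport, path) -> None:
    """Confusion-matrix heat map (rows predicted, columns actual)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = report.confusion.array
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(arr, cmap="Blues")
    for i in range(3):
        for j in range(3):
            ax.text(j, i, str(arr[i, j]), ha="center", va="center")
    ax.set_xticks(range(3), CLASS_NAMES)
    ax.set_yticks(range(3), CLASS_NAMES)
    ax.set_xlabel("actual")
    ax.set_ylabel("predicted")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
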