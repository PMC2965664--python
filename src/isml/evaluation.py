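"""Classification metrics and validation machinery.

Conventions, fixed once and used everywhere:

* Confusion matrices have true classes in rows, predicted (or matched)
  classes in columns.
* Accuracy (recall) of a class = correctly classified / samples *in* the
  class; precision = correctly classified / samples *assigned to* the class.
* Weighted averages weight per-class values by TRUE class sizes, for
  precision as well as accuracy; applied to accuracies this equals the
  overall fraction correct (100 * trace / total).
* ROC areas are one-vs-rest, computed by the Mann-Whitney rank statistic
  with midrank tie handling; the weighted area is the class-size-weighted
  mean.
* Percentages are reported to 1 decimal, rounded half-up.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix
from .errors import IsmlError, ValidationError

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_matrix",
    "per_class_accuracy",
    "per_class_precision",
    "weighted_average",
    "roc_area_weighted",
    "metric_report",
    "round_half_up",
    "format_confusion_table",
    "stratified_fold_assignment",
    "nested_cv",
    "correlate_model_metrics",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as printed report tables do."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted/matched class."""

    class_names: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.class_names)
        if self.counts.shape != (K, K):
            raise ValidationError("confusion matrix must be K x K")
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    class_names: list[str]
    per_class_accuracy: np.ndarray  # %
    per_class_precision: np.ndarray  # %
    weighted_accuracy: float  # %
    weighted_precision: float  # %
    per_class_roc: np.ndarray | None = None
    weighted_roc: float | None = None


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_names: Sequence[str],
) -> ConfusionMatrix:
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label vectors must have equal length")
    index = {c: i for i, c in enumerate(class_names)}
    K = len(class_names)
    counts = np.zeros((K, K), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValidationError(f"label outside class set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(list(class_names), counts)


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """100 * diagonal / row sum; NaN (with a warning) for an empty class."""
    out = np.full(len(cm.class_names), np.nan)
    for i, n in enumerate(cm.row_sums):
        if n == 0:
            warnings.warn(f"class {cm.class_names[i]!r} has no samples; accuracy undefined")
        else:
            out[i] = 100.0 * cm.counts[i, i] / n
    return out


def per_class_precision(cm: ConfusionMatrix) -> np.ndarray:
    """100 * diagonal / column sum; NaN (with a warning) for an empty prediction."""
    out = np.full(len(cm.class_names), np.nan)
    for j, n in enumerate(cm.col_sums):
        if n == 0:
            warnings.warn(
                f"no samples assigned to class {cm.class_names[j]!r}; precision undefined"
            )
        else:
            out[j] = 100.0 * cm.counts[j, j] / n
    return out


def weighted_average(
    per_class_values: Sequence[float], class_sizes: Sequence[float]
) -> float:
    """Class-size-weighted mean; NaN entries are excluded with their weight."""
    v = np.asarray(per_class_values, dtype=float)
    w = np.asarray(class_sizes, dtype=float)
    if v.shape != w.shape:
        raise ValidationError("values and sizes must align")
    if (w < 0).any() or not (w > 0).any():
        raise IsmlError("class sizes must be nonnegative and not all zero")
    ok = np.isfinite(v)
    if not ok.all():
        warnings.warn("undefined per-class values excluded from the weighted average")
    if not (w[ok] > 0).any():
        raise IsmlError("no defined values with positive weight")
    return float(np.sum(v[ok] * w[ok]) / np.sum(w[ok]))


def _auc_rank(scores: np.ndarray, positive: np.ndarray) -> float:
    """One-vs-rest AUROC by the midrank Mann-Whitney statistic."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)  # average (mid) ranks
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_area_weighted(
    class_scores: Mapping[str, Sequence[float]] | np.ndarray,
    true_labels: Sequence[str],
    class_names: Sequence[str] | None = None,
) -> tuple[dict[str, float], float]:
    """Per-class one-vs-rest ROC areas and their class-size-weighted mean.

    ``class_scores`` maps each class to one score per sample (larger =
    more class-like), or is an (n_samples, K) array in ``class_names``
    order.  A class absent from the true labels gets a NaN area and is
    excluded from the weighted mean.
    """
    labels = np.asarray(list(true_labels))
    if isinstance(class_scores, np.ndarray):
        if class_names is None:
            raise ValidationError("class_names required with an array of scores")
        score_map = {c: class_scores[:, i] for i, c in enumerate(class_names)}
    else:
        score_map = {c: np.asarray(s, dtype=float) for c, s in class_scores.items()}
    per_class: dict[str, float] = {}
    sizes: list[float] = []
    areas: list[float] = []
    for cls, scores in score_map.items():
        if len(scores) != len(labels):
            raise ValidationError("scores must align with labels")
        positive = labels == cls
        auc = _auc_rank(np.asarray(scores, dtype=float), positive)
        per_class[cls] = auc
        if np.isfinite(auc):
            sizes.append(positive.sum())
            areas.append(auc)
    weighted = float(np.sum(np.array(areas) * np.array(sizes)) / np.sum(sizes)) if sizes else float("nan")
    return per_class, weighted


def metric_report(
    cm: ConfusionMatrix,
    class_scores: Mapping[str, Sequence[float]] | None = None,
    true_labels: Sequence[str] | None = None,
) -> MetricReport:
    acc = per_class_accuracy(cm)
    prec = per_class_precision(cm)
    sizes = cm.row_sums.astype(float)
    report = MetricReport(
        class_names=list(cm.class_names),
        per_class_accuracy=acc,
        per_class_precision=prec,
        weighted_accuracy=weighted_average(acc, sizes),
        weighted_precision=weighted_average(prec, sizes),
    )
    if class_scores is not None and true_labels is not None:
        per_class, weighted = roc_area_weighted(class_scores, true_labels)
        report.per_class_roc = np.array([per_class.get(c, np.nan) for c in cm.class_names])
        report.weighted_roc = weighted
    return report


def format_confusion_table(cm: ConfusionMatrix, roc: Mapping[str, float] | None = None) -> str:
    """Render the report-table layout: true-class rows with sizes, then a
    precision row and a weighted-average row, percentages to 1 decimal."""
    acc = per_class_accuracy(cm)
    prec = per_class_precision(cm)
    sizes = cm.row_sums
    lines = ["\t".join(["true_class"] + list(cm.class_names) + ["accuracy_pct", "roc_area"])]
    for i, cls in enumerate(cm.class_names):
        roc_cell = "" if roc is None else f"{roc.get(cls, float('nan')):.3f}"
        lines.append(
            "\t".join(
                [f"{cls} ({sizes[i]})"]
                + [str(int(c)) for c in cm.counts[i]]
                + [f"{round_half_up(acc[i]):.1f}", roc_cell]
            )
        )
    lines.append(
        "\t".join(
            ["precision_pct"]
            + [f"{round_half_up(p):.1f}" if np.isfinite(p) else "NA" for p in prec]
            + ["", ""]
        )
    )
    lines.append(
        "\t".join(
            [f"weighted_average ({cm.total})",
             f"{round_half_up(weighted_average(prec, sizes)):.1f} (precision)",
             f"{round_half_up(weighted_average(acc, sizes)):.1f}", "", "", ""]
        )
    )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_fold_assignment(
    labels: Sequence[str],
    sample_ids: Sequence[str],
    n_folds: int,
    seed: int,
) -> np.ndarray:
    """Deterministic stratified folds: within each class, samples are sorted
    by a seed-keyed stable hash of their identifier and dealt round-robin.

    Every fold's class proportions are within one sample of the global
    proportions; identical (labels, ids, seed) always give identical folds.
    """
    labels = np.asarray(list(labels))
    ids = list(sample_ids)
    if len(labels) != len(ids):
        raise ValidationError("labels and sample_ids must align")
    if n_folds < 2:
        raise IsmlError("need at least 2 folds")
    fold = np.empty(len(ids), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        keyed = sorted(
            idx,
            key=lambda i: hashlib.sha256(f"{seed}|{ids[i]}".encode()).hexdigest(),
        )
        for pos, i in enumerate(keyed):
            fold[i] = pos % n_folds
    return fold


def nested_cv(
    m: ExpressionMatrix,
    labels: Sequence[str],
    model_builder: Callable,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> tuple[MetricReport, ConfusionMatrix, list[dict]]:
    """Nested stratified cross-validation with all selection inside the outer loop.

    ``model_builder(train_matrix, train_labels, inner_folds, seed)`` must
    re-run every data-dependent choice (filtering, ranking, refinement,
    fitting) on the outer-training data only, tuning in the inner loop if it
    tunes at all, and return an object with ``predict(test_matrix) ->
    labels``.  Outer-fold test predictions are pooled into one confusion
    matrix, giving a selection-bias-free accuracy estimate.
    """
    labels = np.asarray(list(labels))
    classes = sorted(np.unique(labels).tolist())
    smallest = min(int((labels == c).sum()) for c in classes)
    if smallest < 2:
        raise IsmlError("every class needs at least 2 samples")
    folds = outer_folds
    if smallest < outer_folds:
        warnings.warn(
            f"smallest class has {smallest} samples; reducing outer folds to {smallest}"
        )
        folds = smallest
    if len(labels) < folds:
        raise IsmlError("fewer samples than folds")
    assignment = stratified_fold_assignment(labels, m.sample_ids, folds, seed)
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    details: list[dict] = []
    for f in range(folds):
        test_idx = np.flatnonzero(assignment == f)
        train_idx = np.flatnonzero(assignment != f)
        train_m = m.subset_samples(train_idx)
        test_m = m.subset_samples(test_idx)
        model = model_builder(train_m, labels[train_idx], inner_folds, seed + f)
        pred = list(model.predict(test_m))
        pooled_true.extend(labels[test_idx])
        pooled_pred.extend(pred)
        fold_correct = sum(t == p for t, p in zip(labels[test_idx], pred))
        details.append(
            {"fold": f, "n_test": len(test_idx), "n_correct": int(fold_correct)}
        )
    cm = confusion_matrix(pooled_true, pooled_pred, classes)
    return metric_report(cm), cm, details


def correlate_model_metrics(model_summaries: Sequence) -> float:
    """Pearson correlation of accuracy vs ROC area across trained models.

    Accepts (accuracy, roc_area) pairs or objects with ``accuracy`` and
    ``roc_area`` attributes.  Requires at least 3 models; zero variance in
    either metric yields NaN with a warning.
    """
    pairs = []
    for s in model_summaries:
        if hasattr(s, "accuracy"):
            pairs.append((float(s.accuracy), float(s.roc_area)))
        else:
            a, r = s
            pairs.append((float(a), float(r)))
    if len(pairs) < 3:
        raise IsmlError("need at least 3 models to correlate metrics")
    acc = np.array([p[0] for p in pairs])
    roc = np.array([p[1] for p in pairs])
    if np.ptp(acc) == 0 or np.ptp(roc) == 0:
        warnings.warn("zero variance in a metric; correlation undefined")
        return float("nan")
    return float(np.corrcoef(acc, roc)[0, 1])
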