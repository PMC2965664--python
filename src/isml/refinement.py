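"""Iterative refinement of the ranked classifier-gene set.

Two pluggable evaluators score a gene set's three-class performance:

* ``svm`` — a multi-class SVM assembled from one soft-margin linear SVM per
  unordered class pair (trained by SMO), predicting by pairwise vote with
  ties resolved toward the more prevalent training class; accuracies come
  from pooled stratified cross-validation test folds.
* ``clustering`` — K-means with k = number of classes on the full data,
  clusters matched one-to-one to classes by the assignment that maximizes
  the matched sample count; accuracies come from the matched confusion
  matrix (no train/test split is meaningful for unsupervised matching).

The backward elimination then alternates two steps until a fixed point:
build the accuracy curve over ranking prefixes (per-class accuracies plus
the weighted average as one gene at a time is added in rank order), and
remove — scanning from the bottom of the ranking — every gene whose
addition strictly decreased ALL of those accuracies.  Genes that trade one
class's accuracy against another's survive by design; the top-ranked gene
is never removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .datatypes import ExpressionMatrix
from .errors import IsmlError, ValidationError
from .evaluation import (
    ConfusionMatrix,
    confusion_matrix,
    per_class_accuracy,
    stratified_fold_assignment,
    weighted_average,
)

__all__ = [
    "MCSVM",
    "AccuracyCurve",
    "RefinementIteration",
    "RefinementTrace",
    "ClassifierGeneSet",
    "train_mc_svm",
    "kmeans_match",
    "accuracy_curve",
    "prune_pass",
    "iterate_refinement",
    "combine_gene_sets",
]


# ---------------------------------------------------------------------------
# multi-class SVM (pairwise soft-margin SVMs trained by SMO)
# ---------------------------------------------------------------------------

class MCSVM:
    """One-vs-one linear SVMs with pairwise voting.

    Each binary sub-problem is solved by sequential minimal optimization
    (libsvm's SMO solver) with soft-margin parameter ``C``.  Features are
    standardized with statistics of the *training* data only.  Pairwise
    votes decide the class; vote ties go to the class with larger training
    prevalence, then lexicographically.
    """

    def __init__(self, C: float = 1.0, kernel: str = "linear"):
        self.C = C
        self.kernel = kernel

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "MCSVM":
        y = np.asarray([str(l) for l in y])
        self.classes_ = sorted(np.unique(y).tolist())
        if len(self.classes_) < 2:
            raise IsmlError("MC-SVM needs at least 2 classes")
        for cls in self.classes_:
            if (y == cls).sum() < 2:
                raise IsmlError(f"class {cls!r} has fewer than 2 training samples")
        X = np.asarray(X, dtype=float)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Z = (X - self._mu) / self._sd
        self._prevalence = {c: int((y == c).sum()) for c in self.classes_}
        self._machines: dict[tuple[str, str], SVC] = {}
        for i, a in enumerate(self.classes_):
            for b in self.classes_[i + 1 :]:
                rows = (y == a) | (y == b)
                svc = SVC(C=self.C, kernel=self.kernel)
                svc.fit(Z[rows], y[rows])
                self._machines[(a, b)] = svc
        return self

    def _votes(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self._mu) / self._sd
        votes = np.zeros((len(Z), len(self.classes_)))
        idx = {c: i for i, c in enumerate(self.classes_)}
        for (a, b), svc in self._machines.items():
            pred = svc.predict(Z)
            for c in (a, b):
                votes[pred == c, idx[c]] += 1
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = self._votes(X)
        out = []
        for row in votes:
            top = row.max()
            tied = [c for c, v in zip(self.classes_, row) if v == top]
            if len(tied) > 1:
                tied.sort(key=lambda c: (-self._prevalence[c], c))
            out.append(tied[0])
        return np.asarray(out)

    def vote_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class pairwise vote counts, usable as ROC scores."""
        return self._votes(X)


def train_mc_svm(
    m: ExpressionMatrix, genes: Sequence[str], labels: Sequence[str], C: float = 1.0
) -> MCSVM:
    """Fit the pairwise MC-SVM on the matrix restricted to ``genes``."""
    sub = m.subset_genes(np.asarray(list(genes)))
    return MCSVM(C=C).fit(sub.imputed().T, labels)


# ---------------------------------------------------------------------------
# K-means with cluster-to-class matching
# ---------------------------------------------------------------------------

def best_cluster_assignment(table: np.ndarray) -> dict[int, int]:
    """One-to-one cluster -> class assignment maximizing the matched count.

    ``table[c, k]`` counts samples of cluster c with true class k; solved as
    a linear assignment problem (Hungarian algorithm).
    """
    table = np.asarray(table)
    rows, cols = linear_sum_assignment(-table)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def kmeans_match(
    m: ExpressionMatrix,
    genes: Sequence[str],
    labels: Sequence[str],
    k: int | None = None,
    seed: int = 0,
    restarts: int = 50,
) -> ConfusionMatrix:
    """Cluster samples on the gene subset and match clusters to classes.

    K-means (Euclidean, k-means++ initialization, best of ``restarts`` runs
    by within-cluster sum of squares) on per-gene standardized expression;
    the k x K contingency table of cluster vs true class is matched
    one-to-one by the assignment maximizing the total matched samples
    (Hungarian algorithm), which makes the result invariant to arbitrary
    cluster numbering.  Rows of the returned confusion matrix are true
    classes, columns the matched class of each sample's cluster.
    """
    labels = np.asarray([str(l) for l in labels])
    classes = sorted(np.unique(labels).tolist())
    if k is None:
        k = len(classes)
    if k != len(classes):
        raise IsmlError("k must equal the number of classes for matching")
    if k > m.n_samples:
        raise IsmlError("more clusters than samples")
    sub = m.subset_genes(np.asarray(list(genes)))
    X = sub.imputed()
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = ((X - mu) / np.where(sd > 0, sd, 1.0)).T  # samples x genes
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed)
    cluster = km.fit_predict(Z)
    # contingency: clusters x classes
    table = np.zeros((k, len(classes)), dtype=int)
    cls_idx = {c: i for i, c in enumerate(classes)}
    for cl, lab in zip(cluster, labels):
        table[cl, cls_idx[lab]] += 1
    assignment = best_cluster_assignment(table)
    cluster_to_class = {r: classes[c] for r, c in assignment.items()}
    matched = [cluster_to_class[int(c)] for c in cluster]
    return confusion_matrix(labels, matched, classes)


# ---------------------------------------------------------------------------
# accuracy curves over ranking prefixes
# ---------------------------------------------------------------------------

@dataclass
class AccuracyCurve:
    """Per-class and weighted-average accuracy (%) at each prefix size k."""

    class_names: list[str]
    ks: np.ndarray  # prefix sizes 1..n
    per_class: np.ndarray  # len(ks) x K, percent
    weighted: np.ndarray  # len(ks), percent

    def deltas(self) -> np.ndarray:
        """Rows 2..n: change in (per-class..., weighted) vs the previous prefix."""
        series = np.column_stack([self.per_class, self.weighted])
        return np.diff(series, axis=0)


def _svm_cv_confusion(
    m: ExpressionMatrix,
    genes: Sequence[str],
    labels: np.ndarray,
    classes: list[str],
    fold_assignment: np.ndarray,
    C: float,
) -> ConfusionMatrix:
    sub = m.subset_genes(np.asarray(list(genes)))
    X = sub.imputed().T
    pred = np.empty(len(labels), dtype=object)
    for f in np.unique(fold_assignment):
        train = fold_assignment != f
        model = MCSVM(C=C).fit(X[train], labels[train])
        pred[~train] = model.predict(X[~train])
    return confusion_matrix(labels, pred.tolist(), classes)


def accuracy_curve(
    ranked_genes: Sequence[str],
    m: ExpressionMatrix,
    labels: Sequence[str],
    evaluator: str = "svm",
    cv_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    kmeans_restarts: int = 50,
) -> AccuracyCurve:
    """Accuracy as one gene at a time is added in rank order.

    For each prefix of the ranking (size 1..n), the evaluator's per-class
    accuracies and their class-size-weighted average are computed: pooled
    CV test-fold predictions for ``svm`` (folds fixed once per curve, so
    prefix rows differ only in the gene set), full-data cluster matching
    for ``clustering``.
    """
    if not ranked_genes:
        raise IsmlError("ranked gene list is empty")
    if evaluator not in ("svm", "clustering"):
        raise IsmlError(f"unknown evaluator {evaluator!r}")
    labels = np.asarray([str(l) for l in labels])
    classes = sorted(np.unique(labels).tolist())
    if evaluator == "svm":
        smallest = min(int((labels == c).sum()) for c in classes)
        folds = max(2, min(cv_folds, smallest))
        assignment = stratified_fold_assignment(labels, m.sample_ids, folds, seed)
    rows = []
    weighted = []
    sizes = None
    for k in range(1, len(ranked_genes) + 1):
        prefix = list(ranked_genes[:k])
        if evaluator == "svm":
            cm = _svm_cv_confusion(m, prefix, labels, classes, assignment, C)
        else:
            cm = kmeans_match(
                m, prefix, labels, seed=seed, restarts=kmeans_restarts
            )
        acc = per_class_accuracy(cm)
        sizes = cm.row_sums
        rows.append(acc)
        weighted.append(weighted_average(acc, sizes))
    return AccuracyCurve(
        class_names=classes,
        ks=np.arange(1, len(ranked_genes) + 1),
        per_class=np.vstack(rows),
        weighted=np.asarray(weighted),
    )


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

@dataclass
class RefinementIteration:
    genes_before: list[str]
    removed: list[str]
    curve: AccuracyCurve


@dataclass
class RefinementTrace:
    evaluator_name: str
    iterations: list[RefinementIteration] = field(default_factory=list)
    final_set: list[str] = field(default_factory=list)


@dataclass
class ClassifierGeneSet:
    genes: list[str]
    provenance: str  # svm_optimized | clustering_optimized | combined_union | common_intersection

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("classifier gene set must be unique")


def prune_pass(
    ranked_genes: Sequence[str], curve: AccuracyCurve
) -> tuple[list[str], list[str]]:
    """Remove, bottom-up, every gene whose addition declined ALL accuracies.

    For the gene at rank position k >= 2, the four deltas are the changes in
    each per-class accuracy and the weighted average between prefix k and
    prefix k-1 of ``curve``.  "Decline" is strict (< 0): a gene with any
    zero or positive delta is kept, and the top-ranked gene is never
    removed.  Relative order of the kept genes is preserved.
    """
    ranked_genes = list(ranked_genes)
    if len(curve.ks) != len(ranked_genes):
        raise IsmlError("curve length must match the ranked gene list")
    removed: list[str] = []
    if len(ranked_genes) > 1:
        deltas = curve.deltas()  # row i -> gene at position i+1 (0-based)
        for pos in range(len(ranked_genes) - 1, 0, -1):
            if (deltas[pos - 1] < 0).all():
                removed.append(ranked_genes[pos])
    kept = [g for g in ranked_genes if g not in set(removed)]
    return kept, removed


def iterate_refinement(
    ranked_genes: Sequence[str],
    m: ExpressionMatrix,
    labels: Sequence[str],
    evaluator: str = "svm",
    cv_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    kmeans_restarts: int = 50,
) -> tuple[ClassifierGeneSet, RefinementTrace]:
    """Alternate accuracy curves and prune passes until nothing is removed.

    The curve (and hence every delta) is recomputed each iteration because
    positions shift after removals.  Terminates: each pass either strictly
    shrinks the set or ends the loop.  The whole run is reproducible from
    (data, ranking, seed).
    """
    current = list(ranked_genes)
    trace = RefinementTrace(evaluator_name=evaluator)
    while True:
        curve = accuracy_curve(
            current, m, labels, evaluator=evaluator, cv_folds=cv_folds,
            seed=seed, C=C, kmeans_restarts=kmeans_restarts,
        )
        kept, removed = prune_pass(current, curve)
        trace.iterations.append(
            RefinementIteration(genes_before=list(current), removed=removed, curve=curve)
        )
        if not removed:
            break
        current = kept
    trace.final_set = current
    provenance = "svm_optimized" if evaluator == "svm" else "clustering_optimized"
    return ClassifierGeneSet(genes=current, provenance=provenance), trace


def combine_gene_sets(
    svm_set: ClassifierGeneSet, clust_set: ClassifierGeneSet
) -> tuple[ClassifierGeneSet, ClassifierGeneSet]:
    """Union and intersection of the two independently optimized sets.

    Union order: the SVM-optimized genes first, then clustering-only genes,
    each in their refined order, so |union| = |A| + |B| - |A ∩ B|.
    """
    a, b = list(svm_set.genes), list(clust_set.genes)
    in_a = set(a)
    union = a + [g for g in b if g not in in_a]
    inter = [g for g in a if g in set(b)]
    return (
        ClassifierGeneSet(genes=union, provenance="combined_union"),
        ClassifierGeneSet(genes=inter, provenance="common_intersection"),
    )
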