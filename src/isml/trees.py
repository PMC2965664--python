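"""Tree-based classifier-gene selection and weight-of-significance ranking.

A suite of decision-tree learners (plain, bagged, boosted) is trained on the
statistically filtered genes.  Any gene that appears at a decision node of
any model is a *classifier gene*.  Each model assigns the gene a positional
weight: with L the number of decision-node levels on the longest
root-to-leaf path and d the depth (in decision-node levels, root = 0) of
the shallowest node that tests the gene,

    w(g, m) = (L - d) / L,

so the root gene scores 1, the deepest decision gene scores 1/L, and the
scale is normalized to the longest path.  Ensemble models average member
weights (a gene absent from a member contributes 0).  The overall weight
sums model weights scaled by each model's cross-validated accuracy,

    W(g) = sum_m A_m * w(g, m),

and genes are ranked by W descending (ties broken by gene identifier), so a
gene sitting high in many accurate trees outranks one that appears deep in
a few weak ones.  The depth-decay function is pluggable for sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .datatypes import ExpressionMatrix
from .errors import IsmlError, ValidationError
from .evaluation import roc_area_weighted, stratified_fold_assignment

__all__ = [
    "LearnerConfig",
    "TreeNode",
    "TreeModel",
    "GeneWeightTable",
    "default_learner_suite",
    "train_tree",
    "train_ensemble",
    "train_model_suite",
    "extract_path_weights",
    "overall_weights",
    "select_classifier_genes",
    "linear_depth_decay",
]


@dataclass(frozen=True)
class LearnerConfig:
    """One CART-family learner configuration.

    The axes cover what distinguishes the classical tree algorithms: split
    criterion (Gini impurity vs information gain), pruning strength
    (cost-complexity alpha), growth order (depth-first, or best-first via a
    node budget) and minimum leaf size.
    """

    name: str
    criterion: str = "gini"  # "gini" | "entropy" | "log_loss"
    max_depth: int | None = None
    min_samples_leaf: int = 2
    ccp_alpha: float = 0.0
    max_leaf_nodes: int | None = None  # not None -> best-first growth
    max_features: float | str | None = None  # per-split feature subsampling

    def build(self, seed: int) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion=self.criterion,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            ccp_alpha=self.ccp_alpha,
            max_leaf_nodes=self.max_leaf_nodes,
            max_features=self.max_features,
            random_state=seed,
        )


@dataclass
class TreeNode:
    """One node of a parsed tree: a gene test or a class leaf."""

    node_id: int
    depth: int
    gene_id: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    class_label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.gene_id is None


@dataclass
class TreeModel:
    """A trained tree or tree ensemble with its cross-validated performance."""

    model_id: str
    learner_name: str
    ensemble_mode: str  # "none" | "bagging" | "adaboost_m1"
    trees: list[TreeNode]  # member roots (singleton unless ensemble)
    accuracy: float  # A_m on the [0, 1] scale
    roc_area: float
    external_weights: dict[str, float] | None = None  # hook for model-supplied weights

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1 or not (
            0 <= self.roc_area <= 1 or np.isnan(self.roc_area)
        ):
            raise ValidationError("accuracy and roc_area must lie in [0, 1]")
        if not self.trees:
            raise ValidationError("a tree model needs at least one member tree")


@dataclass
class GeneWeightTable:
    """Per-model weights w(g, m), overall weights W(g) and ranks."""

    gene_ids: list[str]
    model_ids: list[str]
    per_model: np.ndarray  # genes x models
    model_accuracies: np.ndarray
    overall: np.ndarray
    rank: np.ndarray  # 1 = highest overall weight

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_model, index=self.gene_ids, columns=self.model_ids)
        df["overall_weight"] = self.overall
        df["rank"] = self.rank
        return df

    def ranked_gene_ids(self) -> list[str]:
        order = np.argsort(self.rank)
        return [self.gene_ids[i] for i in order]


def default_learner_suite(n_models: int = 6) -> list[tuple[LearnerConfig, str]]:
    """(learner, ensemble-mode) grid; 6 = 3 configs x {bagging, boosting},
    12 doubles the learner configs to mirror a full algorithm-grid run."""
    configs = [
        LearnerConfig("cart_gini", criterion="gini"),
        LearnerConfig("cart_entropy", criterion="entropy"),
        LearnerConfig("cart_pruned", criterion="gini", ccp_alpha=0.01),
        LearnerConfig("cart_bestfirst", criterion="entropy", max_leaf_nodes=16),
        # random-subspace splits diversify which correlated genes get picked
        LearnerConfig("cart_subspace", criterion="gini", max_features="sqrt"),
        LearnerConfig("cart_subspace_entropy", criterion="entropy", max_features=0.3),
    ]
    modes = ["bagging", "adaboost_m1"]
    grid = [(cfg, mode) for cfg in configs for mode in modes]
    if not 1 <= n_models <= len(grid):
        raise IsmlError(f"n_models must lie in [1, {len(grid)}]")
    return grid[:n_models]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _parse_sklearn_tree(clf: DecisionTreeClassifier, gene_ids: Sequence[str]) -> TreeNode:
    t = clf.tree_
    classes = [str(c) for c in clf.classes_]

    def build(node: int, depth: int) -> TreeNode:
        if t.children_left[node] == -1:
            label = classes[int(np.argmax(t.value[node]))]
            return TreeNode(node_id=node, depth=depth, class_label=label)
        return TreeNode(
            node_id=node,
            depth=depth,
            gene_id=str(gene_ids[t.feature[node]]),
            threshold=float(t.threshold[node]),
            left=build(t.children_left[node], depth + 1),
            right=build(t.children_right[node], depth + 1),
        )

    return build(0, 0)


def _cv_performance(
    estimator_factory: Callable[[int], object],
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: Sequence[str],
    cv_folds: int,
    seed: int,
) -> tuple[float, float]:
    """Stratified K-fold pooled accuracy and weighted one-vs-rest ROC area."""
    classes = np.array(sorted(np.unique(y).tolist()))
    smallest = min(int((y == c).sum()) for c in classes)
    folds = max(2, min(cv_folds, smallest))
    assignment = stratified_fold_assignment(y, sample_ids, folds, seed)
    pred = np.empty(len(y), dtype=object)
    proba = np.zeros((len(y), len(classes)))
    for f in range(folds):
        train = assignment != f
        test = ~train
        est = estimator_factory(seed + 1000 * f)
        est.fit(X[train], y[train])
        pred[test] = est.predict(X[test])
        p = est.predict_proba(X[test])
        cols = {str(c): i for i, c in enumerate(est.classes_)}
        for i, c in enumerate(classes):
            if str(c) in cols:
                proba[test, i] = p[:, cols[str(c)]]
    accuracy = float(np.mean(pred == y))
    _, weighted_roc = roc_area_weighted(proba, y, class_names=[str(c) for c in classes])
    return accuracy, weighted_roc


def _check_inputs(m: ExpressionMatrix, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != m.n_samples:
        raise ValidationError("labels must align with samples")
    if len(np.unique(labels)) < 2:
        raise IsmlError("tree training needs at least 2 classes")
    X = m.imputed().T  # samples x genes
    return X, labels


def train_tree(
    m: ExpressionMatrix,
    labels: Sequence[str],
    config: LearnerConfig,
    seed: int = 0,
    cv_folds: int = 10,
) -> TreeModel:
    """Train one plain decision tree; A_m from stratified 10-fold CV."""
    X, y = _check_inputs(m, labels)
    accuracy, roc = _cv_performance(config.build, X, y, m.sample_ids, cv_folds, seed)
    clf = config.build(seed)
    clf.fit(X, y)
    root = _parse_sklearn_tree(clf, m.gene_ids)
    return TreeModel(
        model_id=f"{config.name}",
        learner_name=config.name,
        ensemble_mode="none",
        trees=[root],
        accuracy=accuracy,
        roc_area=roc,
    )


def train_ensemble(
    m: ExpressionMatrix,
    labels: Sequence[str],
    config: LearnerConfig,
    mode: str,
    n_members: int = 10,
    seed: int = 0,
    cv_folds: int = 10,
    bootstrap: bool = True,
) -> TreeModel:
    """Bagged (bootstrap + majority vote) or AdaBoost.M1 (reweighted, weighted
    vote, early stop on member error 0 or >= 1/2) tree ensemble."""
    if n_members < 1:
        raise IsmlError("n_members must be >= 1")
    if mode not in ("bagging", "adaboost_m1"):
        raise IsmlError(f"unknown ensemble mode {mode!r}")
    X, y = _check_inputs(m, labels)

    def factory(s: int):
        base = config.build(s)
        if mode == "bagging":
            return BaggingClassifier(
                estimator=base,
                n_estimators=n_members,
                bootstrap=bootstrap,
                random_state=s,
            )
        return AdaBoostClassifier(estimator=base, n_estimators=n_members, random_state=s)

    accuracy, roc = _cv_performance(factory, X, y, m.sample_ids, cv_folds, seed)
    ens = factory(seed)
    ens.fit(X, y)
    if mode == "bagging":
        # bagging label-encodes y for its members; decode leaves afterwards
        members = [
            _parse_sklearn_tree(est, [m.gene_ids[i] for i in feats])
            for est, feats in zip(ens.estimators_, ens.estimators_features_)
        ]
        decode = {str(i): str(c) for i, c in enumerate(ens.classes_)}
        for root in members:
            stack = [root]
            while stack:
                node = stack.pop()
                if node.is_leaf:
                    node.class_label = decode.get(node.class_label, node.class_label)
                else:
                    stack.extend((node.left, node.right))
    else:
        members = [_parse_sklearn_tree(est, m.gene_ids) for est in ens.estimators_]
    return TreeModel(
        model_id=f"{mode}_{config.name}",
        learner_name=config.name,
        ensemble_mode=mode,
        trees=members,
        accuracy=accuracy,
        roc_area=roc,
    )


def train_model_suite(
    m: ExpressionMatrix,
    labels: Sequence[str],
    suite: Sequence[tuple[LearnerConfig, str]] | None = None,
    n_members: int = 10,
    seed: int = 0,
    cv_folds: int = 10,
) -> list[TreeModel]:
    """Train the whole learner x ensemble grid on the same data."""
    if suite is None:
        suite = default_learner_suite()
    models = []
    for k, (config, mode) in enumerate(suite):
        if mode == "none":
            models.append(train_tree(m, labels, config, seed=seed + k, cv_folds=cv_folds))
        else:
            models.append(
                train_ensemble(
                    m, labels, config, mode, n_members=n_members, seed=seed + k,
                    cv_folds=cv_folds,
                )
            )
    return models


# ---------------------------------------------------------------------------
# weight extraction and ranking
# ---------------------------------------------------------------------------

def linear_depth_decay(depth: int, longest: int) -> float:
    """Default positional weight: (L - d) / L."""
    return (longest - depth) / longest


def _tree_weights(
    root: TreeNode, decay: Callable[[int, int], float]
) -> dict[str, float]:
    """Per-gene weight within one member tree: decay at the gene's shallowest
    decision node, normalized to the longest root-to-leaf decision path."""
    best_depth: dict[str, int] = {}
    longest = 0

    def walk(node: TreeNode, n_decisions: int) -> None:
        nonlocal longest
        if node.is_leaf:
            longest = max(longest, n_decisions)
            return
        d = best_depth.get(node.gene_id)
        if d is None or node.depth < d:
            best_depth[node.gene_id] = node.depth
        walk(node.left, n_decisions + 1)
        walk(node.right, n_decisions + 1)

    walk(root, 0)
    if longest == 0:
        return {}
    return {g: decay(d, longest) for g, d in best_depth.items()}


def extract_path_weights(
    model: TreeModel, decay: Callable[[int, int], float] = linear_depth_decay
) -> dict[str, float]:
    """Per-gene positional weights w(g, m) in (0, 1] for one model.

    Single tree: the decay of the gene's shallowest decision node.  Ensemble:
    mean over member trees, counting 0 for members that never test the gene.
    A model whose trees are all single leaves yields an empty map.  When the
    model carries externally supplied weights (e.g. from a logistic-model
    learner) those are returned unchanged.
    """
    if model.external_weights is not None:
        return dict(model.external_weights)
    member_maps = [_tree_weights(root, decay) for root in model.trees]
    genes = set().union(*member_maps) if member_maps else set()
    n = len(model.trees)
    return {g: sum(mm.get(g, 0.0) for mm in member_maps) / n for g in genes}


def overall_weights(
    models: Sequence[TreeModel],
    decay: Callable[[int, int], float] = linear_depth_decay,
) -> GeneWeightTable:
    """Accuracy-scaled sum of per-model weights, ranked descending.

    W(g) = sum_m A_m * w(g, m); ties in W broken by gene identifier so the
    ranking is a deterministic permutation, invariant to model order.
    """
    if not models:
        raise IsmlError("need at least one trained model")
    per_model_maps = [extract_path_weights(mdl, decay) for mdl in models]
    genes = sorted(set().union(*per_model_maps))
    W = np.zeros((len(genes), len(models)))
    for j, mm in enumerate(per_model_maps):
        for i, g in enumerate(genes):
            W[i, j] = mm.get(g, 0.0)
    acc = np.array([mdl.accuracy for mdl in models])
    overall = W @ acc
    order = sorted(range(len(genes)), key=lambda i: (-overall[i], genes[i]))
    rank = np.empty(len(genes), dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    return GeneWeightTable(
        gene_ids=genes,
        model_ids=[mdl.model_id for mdl in models],
        per_model=W,
        model_accuracies=acc,
        overall=overall,
        rank=rank,
    )


def select_classifier_genes(models: Sequence[TreeModel]) -> set[str]:
    """Union of genes appearing at any decision node of any model."""
    out: set[str] = set()
    for mdl in models:
        if mdl.external_weights is not None:
            out |= set(mdl.external_weights)
            continue
        for root in mdl.trees:
            stack = [root]
            while stack:
                node = stack.pop()
                if not node.is_leaf:
                    out.add(node.gene_id)
                    stack.append(node.left)
                    stack.append(node.right)
    return out
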