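"""Tree training, path-weight extraction and the overall-weight ranking."""

from __future__ import annotations

import numpy as np
import pytest

from isml.datatypes import ExpressionMatrix
from isml.errors import IsmlError
from isml.reference import LEARNER_SUMMARY
from isml.trees import (
    LearnerConfig,
    TreeModel,
    TreeNode,
    default_learner_suite,
    extract_path_weights,
    overall_weights,
    select_classifier_genes,
    train_ensemble,
    train_model_suite,
    train_tree,
)


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        np.ones(values.shape, bool),
    )


def _leaf(nid, label="A", depth=0):
    return TreeNode(node_id=nid, depth=depth, class_label=label)


def _node(nid, gene, depth, left, right):
    return TreeNode(nid, depth, gene_id=gene, threshold=0.0, left=left, right=right)


def _model(roots, accuracy=1.0, model_id="m"):
    return TreeModel(model_id, "toy", "none" if len(roots) == 1 else "bagging",
                     roots, accuracy, 1.0)


# -- independent oracle: per-path enumeration ------------------------------

def brute_force_weights(root: TreeNode) -> dict[str, float]:
    """Enumerate every root-to-leaf path; weight of a gene = max over paths of
    (decision nodes below-or-at it on that path) / (longest path's decision count)."""
    paths: list[list[str]] = []

    def walk(node, prefix):
        if node.is_leaf:
            paths.append(list(prefix))
            return
        walk(node.left, prefix + [node.gene_id])
        walk(node.right, prefix + [node.gene_id])

    walk(root, [])
    longest = max(len(p) for p in paths)
    if longest == 0:
        return {}
    best: dict[str, float] = {}
    for path in paths:
        for pos, gene in enumerate(path):  # pos = depth in decision levels
            w = (longest - pos) / longest
            best[gene] = max(best.get(gene, 0.0), w)
    return best


def _random_tree(rng, max_depth=6) -> TreeNode:
    counter = [0]

    def grow(depth):
        counter[0] += 1
        nid = counter[0]
        if depth >= max_depth or rng.random() < 0.3:
            return TreeNode(nid, depth, class_label=str(rng.integers(3)))
        gene = f"g{rng.integers(8)}"
        return TreeNode(nid, depth, gene_id=gene, threshold=float(rng.normal()),
                        left=grow(depth + 1), right=grow(depth + 1))

    root = grow(0)
    if root.is_leaf:  # ensure at least one decision node
        root = TreeNode(0, 0, gene_id="g0", threshold=0.0,
                        left=_leaf(1, depth=1), right=_leaf(2, "B", depth=1))
    return root


# -- extraction -------------------------------------------------------------

def test_single_decision_node_gets_weight_one():
    root = _node(0, "gX", 0, _leaf(1, "A", 1), _leaf(2, "B", 1))
    assert extract_path_weights(_model([root])) == {"gX": 1.0}


def test_three_level_chain_weights():
    chain = _node(
        0, "gA", 0,
        _node(1, "gB", 1, _node(2, "gC", 2, _leaf(3, "A", 3), _leaf(4, "B", 3)),
              _leaf(5, "C", 2)),
        _leaf(6, "A", 1),
    )
    w = extract_path_weights(_model([chain]))
    assert w == pytest.approx({"gA": 1.0, "gB": 2 / 3, "gC": 1 / 3})
    assert w == pytest.approx(brute_force_weights(chain))


def test_repeated_gene_takes_max_depth_rule():
    # gX at depth 0 and again at depth 2 -> weight stays 1.0
    tree = _node(
        0, "gX", 0,
        _node(1, "gY", 1, _node(2, "gX", 2, _leaf(3, "A", 3), _leaf(4, "B", 3)),
              _leaf(5, "A", 2)),
        _leaf(6, "B", 1),
    )
    assert extract_path_weights(_model([tree]))["gX"] == 1.0


def test_all_leaf_model_yields_empty_map():
    assert extract_path_weights(_model([_leaf(0)])) == {}


def test_extraction_matches_brute_force_on_100_random_trees():
    rng = np.random.default_rng(555)
    for _ in range(100):
        root = _random_tree(rng)
        got = extract_path_weights(_model([root]))
        expected = brute_force_weights(root)
        assert got == pytest.approx(expected)
        if expected:
            assert max(got.values()) == 1.0
            assert all(0 < v <= 1 for v in got.values())


def test_ensemble_weights_average_members():
    t1 = _node(0, "gA", 0, _leaf(1, "A", 1), _leaf(2, "B", 1))
    t2 = _node(0, "gB", 0, _leaf(1, "A", 1), _leaf(2, "B", 1))
    w = extract_path_weights(_model([t1, t2]))
    assert w == pytest.approx({"gA": 0.5, "gB": 0.5})


def test_external_weights_hook_bypasses_extraction():
    mdl = _model([_leaf(0)])
    mdl.external_weights = {"gZ": 0.7}
    assert extract_path_weights(mdl) == {"gZ": 0.7}


# -- overall weights --------------------------------------------------------

def test_single_model_overall_weight():
    root = _node(0, "g1", 0, _leaf(1, "A", 1), _leaf(2, "B", 1))
    table = overall_weights([_model([root], accuracy=0.8)])
    assert table.overall[table.gene_ids.index("g1")] == pytest.approx(0.8)


def test_reference_accuracy_grid_bounds_observed_weights():
    """A gene at the root of all 12 models scores the sum of the model
    accuracies; the largest observed overall weight (8.70) respects it."""
    accuracies = [row[2] / 100 for row in LEARNER_SUMMARY]
    models = [
        _model([_node(0, "gRoot", 0, _leaf(1, "A", 1), _leaf(2, "B", 1))],
               accuracy=a, model_id=f"m{i}")
        for i, a in enumerate(accuracies)
    ]
    table = overall_weights(models)
    bound = table.overall[table.gene_ids.index("gRoot")]
    assert bound == pytest.approx(sum(accuracies))
    assert 8.70 <= bound


def test_equal_weights_tie_broken_by_gene_id():
    roots = _node(0, "gB", 0, _node(1, "gA", 1, _leaf(2, "A", 2), _leaf(3, "B", 2)),
                  _leaf(4, "B", 1))
    sym = _node(0, "gA", 0, _node(1, "gB", 1, _leaf(2, "A", 2), _leaf(3, "B", 2)),
                _leaf(4, "B", 1))
    table = overall_weights([_model([roots], model_id="m1"), _model([sym], model_id="m2")])
    # both genes end with identical W; gA must rank first
    assert table.rank[table.gene_ids.index("gA")] == 1
    assert table.rank[table.gene_ids.index("gB")] == 2


def test_ranking_invariant_under_model_order():
    rng = np.random.default_rng(8)
    models = [_model([_random_tree(rng)], accuracy=0.6 + 0.1 * i, model_id=f"m{i}")
              for i in range(4)]
    t1 = overall_weights(models)
    t2 = overall_weights(models[::-1])
    assert t1.gene_ids == t2.gene_ids
    np.testing.assert_allclose(t1.overall, t2.overall)
    np.testing.assert_array_equal(t1.rank, t2.rank)


def test_weight_bound_holds_for_random_models():
    rng = np.random.default_rng(99)
    models = [_model([_random_tree(rng)], accuracy=float(rng.uniform(0.5, 1)),
                     model_id=f"m{i}") for i in range(6)]
    table = overall_weights(models)
    assert (table.overall <= sum(m.accuracy for m in models) + 1e-12).all()


def test_empty_model_list_rejected():
    with pytest.raises(IsmlError):
        overall_weights([])


# -- training ---------------------------------------------------------------

def test_separable_single_gene_tree():
    values = np.array([[1.0, 1.1, 0.9, 5.0, 5.1, 4.9, 5.2, 0.8]])
    labels = ["A", "A", "A", "B", "B", "B", "B", "A"]
    mdl = train_tree(_matrix(values), labels, LearnerConfig("toy"), seed=0, cv_folds=4)
    assert mdl.accuracy == 1.0
    root = mdl.trees[0]
    assert root.gene_id == "g0" and root.left.is_leaf and root.right.is_leaf


def test_null_labels_give_chance_level_accuracy():
    rng = np.random.default_rng(12)
    values = rng.normal(size=(30, 200))
    labels = list(np.repeat(["A", "B", "C"], 200 // 3)) + ["A", "B"]
    mdl = train_tree(_matrix(values), labels, LearnerConfig("toy"), seed=12)
    assert 0.23 <= mdl.accuracy <= 0.45


def test_planted_additive_signal_recovered_near_root():
    rng = np.random.default_rng(5)
    n = 120
    labels = np.repeat(["A", "B", "C"], n // 3)
    values = rng.normal(size=(20, n)) * 0.3
    shift = {"A": 0, "B": 2.5, "C": 5.0}
    for gi in (3, 7, 11):
        values[gi] += np.array([shift[l] for l in labels]) + rng.normal(size=n) * 0.2
    mdl = train_tree(_matrix(values), list(labels), LearnerConfig("toy"), seed=5)
    weights = extract_path_weights(mdl)
    top3 = sorted(weights, key=weights.get, reverse=True)[:3]
    assert set(top3) <= {"g3", "g7", "g11"}


def test_bagging_without_bootstrap_single_member_equals_plain_tree():
    rng = np.random.default_rng(9)
    n = 40
    labels = ["A"] * 20 + ["B"] * 20
    values = rng.normal(size=(10, n)) * 0.1
    values[2] += np.array([0.0] * 20 + [10.0] * 20)  # perfectly separable
    m = _matrix(values)
    plain = train_tree(m, labels, LearnerConfig("toy"), seed=1, cv_folds=5)
    ens = train_ensemble(m, labels, LearnerConfig("toy"), "bagging", n_members=1,
                         seed=1, cv_folds=5, bootstrap=False)
    assert ens.accuracy == plain.accuracy
    assert extract_path_weights(ens) == pytest.approx(extract_path_weights(plain))


def test_adaboost_stops_early_on_separable_toy():
    values = np.array([[0.0, 0.1, 0.2, 1.0, 1.1, 1.2]])
    labels = ["A", "A", "A", "B", "B", "B"]
    ens = train_ensemble(_matrix(values), labels, LearnerConfig("toy"), "adaboost_m1",
                         n_members=10, seed=0, cv_folds=3)
    assert len(ens.trees) == 1


def test_bagging_no_worse_than_plain_tree_on_noise():
    """Averaged over 5 seeds, 25-member bagging CV accuracy is within 2 pp
    of (usually above) the plain tree on a noisy planted signal."""
    diffs = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n = 60
        labels = list(np.repeat(["A", "B", "C"], n // 3))
        values = rng.normal(size=(30, n))
        values[0] += np.array([{"A": 0, "B": 1.2, "C": 2.4}[l] for l in labels])
        values[1] += np.array([{"A": 2.4, "B": 0, "C": 1.2}[l] for l in labels])
        m = _matrix(values)
        plain = train_tree(m, labels, LearnerConfig("toy"), seed=seed, cv_folds=5)
        bag = train_ensemble(m, labels, LearnerConfig("toy"), "bagging",
                             n_members=25, seed=seed, cv_folds=5)
        diffs.append(bag.accuracy - plain.accuracy)
    assert np.mean(diffs) >= -0.02


def test_single_class_input_rejected():
    with pytest.raises(IsmlError):
        train_tree(_matrix(np.ones((3, 6))), ["A"] * 6, LearnerConfig("toy"))


# -- selection --------------------------------------------------------------

def test_select_classifier_genes_union():
    t1 = _node(0, "g1", 0, _node(1, "g2", 1, _leaf(2, "A", 2), _leaf(3, "B", 2)),
               _leaf(4, "B", 1))
    t2 = _node(0, "g2", 0, _node(1, "g3", 1, _leaf(2, "A", 2), _leaf(3, "B", 2)),
               _leaf(4, "B", 1))
    allleaf = _model([_leaf(0)], model_id="leafy")
    genes = select_classifier_genes([_model([t1], model_id="a"),
                                     _model([t2], model_id="b"), allleaf])
    assert genes == {"g1", "g2", "g3"}


def test_suite_selection_enriched_for_planted():
    from isml.synthetic import default_design, generate_dataset

    design = default_design(seed=77)  # 2,000 genes, 60 planted
    m, annotations, _, truth = generate_dataset(design)
    labels = [a.class_label for a in annotations]
    regular = m.subset_genes(~m.spikein)
    models = train_model_suite(regular, labels, suite=default_learner_suite(4),
                               n_members=10, seed=77, cv_folds=5)
    selected = select_classifier_genes(models)
    assert 0 < len(selected) < regular.n_genes / 2
    planted = truth.all_discriminative
    frac_selected = len(selected & planted) / len(selected)
    background = len(planted) / regular.n_genes
    assert frac_selected >= 5 * background
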