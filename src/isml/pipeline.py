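"""End-to-end pipeline driver: preprocess -> statistics -> trees -> refinement.

The flow mirrors the four-component design: (1) univariate statistical
filtering with permutation false-positive control, (2) tree-based selection
with weight-of-significance ranking, (3) independent SVM- and
clustering-driven backward elimination, (4) combination of the two
optimized sets and final evaluation.  A :class:`RunManifest` records the
configuration snapshot, the seed fan-out, per-stage gene counts (the
"genes remaining" bracket numbers), timings and digests of the stage
outputs, so a run is auditable and reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import class_comparison as cc
from . import refinement as rf
from . import trees as ts
from .datatypes import ExpressionMatrix, PipelineConfig, SampleAnnotation, SpikeInTable
from .errors import IsmlError
from .evaluation import ConfusionMatrix, MetricReport, metric_report
from .preprocess import LinearRange, preprocess_pipeline
from .synthetic import PlantedTruth, SimulationDesign, generate_dataset

__all__ = [
    "RunManifest",
    "PipelineResult",
    "stage_seed",
    "run_pipeline",
    "FilterThenSvmModel",
    "filter_then_svm_builder",
]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed from the run seed (documented fan-out:
    low 31 bits of SHA-256 over ``"<seed>/<stage>"``)."""
    digest = hashlib.sha256(f"{seed}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _digest(items: Sequence[str]) -> str:
    h = hashlib.sha256()
    for item in items:
        h.update(str(item).encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    stage_digests: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineResult:
    manifest: RunManifest
    preprocessed: ExpressionMatrix
    significant: cc.SignificantGeneList
    models: list[ts.TreeModel]
    weight_table: ts.GeneWeightTable
    svm_set: rf.ClassifierGeneSet
    clustering_set: rf.ClassifierGeneSet
    combined_union: rf.ClassifierGeneSet
    common_intersection: rf.ClassifierGeneSet
    svm_trace: rf.RefinementTrace
    clustering_trace: rf.RefinementTrace
    final_confusion: ConfusionMatrix
    final_report: MetricReport
    truth: PlantedTruth | None = None


def run_pipeline(
    config: PipelineConfig,
    m: ExpressionMatrix | None = None,
    annotations: Sequence[SampleAnnotation] | None = None,
    spikes: SpikeInTable | None = None,
    design: SimulationDesign | None = None,
) -> PipelineResult:
    """Run every stage on the given data (or a dataset simulated from ``design``).

    Gene counts are nonincreasing along the stages: all genes -> presence-
    filtered -> statistically significant -> tree-selected classifier genes
    -> refined sets.  Each stage draws its randomness from a documented
    derivation of ``config.seed`` so stages can be re-run in isolation.
    """
    truth = None
    if m is None:
        if design is None:
            raise IsmlError("provide either a dataset or a simulation design")
        m, annotations, spikes, truth = generate_dataset(design)
    if annotations is None:
        raise IsmlError("sample annotations are required")
    manifest = RunManifest(config=dict(config.__dict__), seed=config.seed)
    manifest.stage_counts["input_genes"] = int((~m.spikein).sum())

    # 1. preprocessing ------------------------------------------------------
    t0 = time.perf_counter()
    pre = preprocess_pipeline(
        m,
        LinearRange(config.linear_range_low, config.linear_range_high),
        spikes=spikes,
        presence_fraction=config.presence_fraction,
    )
    manifest.stage_seconds["preprocess"] = time.perf_counter() - t0
    manifest.stage_counts["after_presence_filter"] = int((~pre.spikein).sum())
    manifest.stage_digests["preprocess"] = _digest(pre.gene_ids)

    ann_by_id = {a.sample_id: a for a in annotations}
    labels = [ann_by_id[s].class_label for s in pre.sample_ids]

    # 2. class comparison ---------------------------------------------------
    t0 = time.perf_counter()
    suite = cc.standard_suite(annotations)
    union, per_comparison = cc.run_comparison_suite(
        pre,
        annotations,
        suite,
        n_permutations=config.n_permutations,
        confidence=config.confidence,
        max_false_positives=config.max_false_positives,
        seed=stage_seed(config.seed, "class_comparison"),
    )
    manifest.stage_seconds["class_comparison"] = time.perf_counter() - t0
    manifest.stage_counts["significant_genes"] = len(union.gene_ids)
    manifest.stage_digests["class_comparison"] = _digest(union.gene_ids)
    if not union.gene_ids:
        raise IsmlError("class comparison selected no genes; nothing to refine")

    # 3. tree selection and ranking ----------------------------------------
    t0 = time.perf_counter()
    sig_matrix = pre.subset_genes(np.asarray(union.gene_ids))
    models = ts.train_model_suite(
        sig_matrix,
        labels,
        suite=ts.default_learner_suite(config.n_tree_models),
        n_members=config.ensemble_members,
        seed=stage_seed(config.seed, "tree_selection"),
        cv_folds=config.cv_folds,
    )
    weight_table = ts.overall_weights(models)
    ranked = weight_table.ranked_gene_ids()
    manifest.stage_seconds["tree_selection"] = time.perf_counter() - t0
    manifest.stage_counts["classifier_genes"] = len(ranked)
    manifest.stage_digests["tree_selection"] = _digest(ranked)

    # 4. refinement (SVM and clustering, independently) ---------------------
    t0 = time.perf_counter()
    svm_set, svm_trace = rf.iterate_refinement(
        ranked, pre, labels, evaluator="svm", cv_folds=config.cv_folds,
        seed=stage_seed(config.seed, "refine_svm"), C=config.svm_C,
    )
    manifest.stage_seconds["refine_svm"] = time.perf_counter() - t0
    manifest.stage_counts["svm_optimized"] = len(svm_set.genes)
    t0 = time.perf_counter()
    clust_set, clust_trace = rf.iterate_refinement(
        ranked, pre, labels, evaluator="clustering", cv_folds=config.cv_folds,
        seed=stage_seed(config.seed, "refine_clustering"),
        kmeans_restarts=config.kmeans_restarts,
    )
    manifest.stage_seconds["refine_clustering"] = time.perf_counter() - t0
    manifest.stage_counts["clustering_optimized"] = len(clust_set.genes)

    # 5. combination --------------------------------------------------------
    union_set, inter_set = rf.combine_gene_sets(svm_set, clust_set)
    manifest.stage_counts["combined_union"] = len(union_set.genes)
    manifest.stage_counts["common_intersection"] = len(inter_set.genes)
    manifest.stage_digests["combined"] = _digest(union_set.genes)

    # 6. final evaluation of the combined set (SVM, pooled CV test folds) ---
    t0 = time.perf_counter()
    classes = sorted(set(labels))
    curve_cm = rf._svm_cv_confusion(
        pre,
        union_set.genes,
        np.asarray(labels),
        classes,
        rf.stratified_fold_assignment(
            labels, pre.sample_ids,
            max(2, min(config.cv_folds, min(labels.count(c) for c in classes))),
            stage_seed(config.seed, "final_eval"),
        ),
        config.svm_C,
    )
    report = metric_report(curve_cm)
    manifest.stage_seconds["evaluation"] = time.perf_counter() - t0

    return PipelineResult(
        manifest=manifest,
        preprocessed=pre,
        significant=union,
        models=models,
        weight_table=weight_table,
        svm_set=svm_set,
        clustering_set=clust_set,
        combined_union=union_set,
        common_intersection=inter_set,
        svm_trace=svm_trace,
        clustering_trace=clust_trace,
        final_confusion=curve_cm,
        final_report=report,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# model builder for nested cross-validation
# ---------------------------------------------------------------------------

class FilterThenSvmModel:
    """Univariate gene filtering + MC-SVM, fitted on training data only."""

    def __init__(self, genes: list[str], svm: rf.MCSVM):
        self.genes = genes
        self.svm = svm

    def predict(self, test_m: ExpressionMatrix) -> np.ndarray:
        sub = test_m.subset_genes(np.asarray(self.genes))
        return self.svm.predict(sub.imputed().T)


def filter_then_svm_builder(n_top: int = 20, C: float = 1.0):
    """Builder for :func:`isml.evaluation.nested_cv`: select the ``n_top``
    genes by moderated F on the training fold, then fit the MC-SVM on them.

    All selection happens inside the training data handed in by the outer
    loop, which is exactly what makes the resulting estimate unbiased.
    """

    def build(train_m: ExpressionMatrix, train_labels, inner_folds: int, seed: int):
        train_m = train_m.subset_genes(~train_m.spikein)
        prior = cc.fit_variance_prior(*cc.residual_variances(train_m, train_labels))
        results = cc.random_variance_test(train_m, train_labels, prior)
        testable = [r for r in results if r.testable]
        testable.sort(key=lambda r: (r.p_value, r.gene_id))
        genes = [r.gene_id for r in testable[:n_top]]
        svm = rf.train_mc_svm(train_m, genes, train_labels, C=C)
        return FilterThenSvmModel(genes, svm)

    return build
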