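"""Published benchmark results for the three-class earthworm exposure study.

The motivating application is a 248-array *Eisenia fetida* microarray
experiment (32 control, 120 RDX-exposed, 96 TNT-exposed samples).  The
study's published classification tables fully determine a set of metric
values; they are embedded here as reference inputs so the metric layer can
be validated against an externally reported analysis, and so report
formatting can be exercised on realistic numbers.  Nothing in the pipeline
depends on these tables.
"""

from __future__ import annotations

from .evaluation import ConfusionMatrix

__all__ = [
    "CLASS_ORDER",
    "LEARNER_SUMMARY",
    "SVM39_CONFUSION",
    "CLUST30_CONFUSION",
    "COMBINED58_SVM_CONFUSION",
    "COMBINED58_CLUST_CONFUSION",
    "SET_SIZES",
]

#: class order used by the published tables
CLASS_ORDER = ["Control", "RDX", "TNT"]

#: 12 tree-model runs: (ensemble, learner, accuracy %, ROC area)
LEARNER_SUMMARY = [
    ("boosting", "BFTree", 75.8, 0.878),
    ("boosting", "J48", 79.8, 0.882),
    ("boosting", "LADTree", 77.4, 0.881),
    ("boosting", "SimpleCart", 75.0, 0.868),
    ("boosting", "FT", 83.5, 0.930),
    ("boosting", "LMT", 81.8, 0.936),
    ("bagging", "J48", 75.4, 0.868),
    ("bagging", "LADTree", 75.0, 0.876),
    ("bagging", "REPTree", 75.0, 0.870),
    ("bagging", "SimpleCart", 76.2, 0.855),
    ("bagging", "FT", 82.7, 0.937),
    ("bagging", "LMT", 84.7, 0.944),
]

#: MC-SVM test-fold results with the 39-gene SVM-optimized set
SVM39_CONFUSION = ConfusionMatrix(
    CLASS_ORDER,
    [[29, 2, 1],
     [7, 106, 7],
     [2, 14, 80]],
)

#: cluster-matching results with the 30-gene clustering-optimized set
CLUST30_CONFUSION = ConfusionMatrix(
    CLASS_ORDER,
    [[22, 1, 9],
     [46, 56, 18],
     [21, 8, 67]],
)

#: results with the combined 58-gene set, SVM evaluator
COMBINED58_SVM_CONFUSION = ConfusionMatrix(
    CLASS_ORDER,
    [[26, 6, 0],
     [9, 100, 11],
     [2, 13, 81]],
)

#: results with the combined 58-gene set, clustering evaluator
COMBINED58_CLUST_CONFUSION = ConfusionMatrix(
    CLASS_ORDER,
    [[22, 1, 9],
     [48, 55, 17],
     [22, 10, 64]],
)

#: reported sizes of the optimized gene sets
SET_SIZES = {
    "svm_optimized": 39,
    "clustering_optimized": 30,
    "common_intersection": 11,
    "combined_union": 58,
}
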