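"""Core in-memory containers for the pipeline.

The central object is :class:`ExpressionMatrix`: a genes-by-samples matrix of
signal intensities (or relative RNA concentrations after spike-in conversion)
together with a boolean usability mask.  The mask is the single mechanism by
which flagged spots, out-of-range intensities and missing cells propagate
through every downstream stage; no operation ever un-masks a cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "SpikeInTable",
    "PipelineConfig",
    "check_unique",
]


def check_unique(ids: Sequence[str], kind: str) -> None:
    """Raise :class:`ValidationError` naming the first duplicated identifier."""
    seen: set[str] = set()
    for token in ids:
        if token in seen:
            raise ValidationError(f"duplicate {kind} identifier: {token!r}")
        seen.add(token)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a usability mask.

    Parameters
    ----------
    gene_ids
        Unique row identifiers (probe or gene names).
    sample_ids
        Unique column identifiers (array / RNA-sample names).
    values
        Float matrix of shape ``(n_genes, n_samples)``.  Cells whose mask is
        false may hold NaN (missing on input) or a real number (flagged but
        measured); either way they are ignored by every computation.
    mask
        Boolean matrix, ``True`` where the measurement is usable.
    spikein
        Per-gene flag marking spike-in control probes.  Spike-in rows ride
        along through preprocessing but are excluded from gene filtering,
        statistics and classification.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    spikein: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask and values must share shape")
        check_unique(self.gene_ids, "gene")
        check_unique(self.sample_ids, "sample")
        if self.spikein is None:
            self.spikein = np.zeros(len(self.gene_ids), dtype=bool)
        self.spikein = np.asarray(self.spikein, dtype=bool)
        if self.spikein.shape != (len(self.gene_ids),):
            raise ValidationError("spikein flag must have one entry per gene")

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise ValidationError(f"unknown gene identifier: {exc.args[0]!r}") from None

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise ValidationError(f"unknown sample identifier: {exc.args[0]!r}") from None

    # -- derived views -------------------------------------------------------
    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.sample_ids),
            self.values.copy(),
            self.mask.copy(),
            self.spikein.copy(),
        )

    def subset_genes(self, keep: np.ndarray | Sequence[str]) -> "ExpressionMatrix":
        """Row subset by boolean mask, integer index, or gene identifiers."""
        keep = np.asarray(keep)
        if keep.dtype.kind in "US":
            idx = self.gene_index(keep)
        elif keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep.astype(int)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx],
            self.mask[idx],
            self.spikein[idx],
        )

    def subset_samples(self, keep: np.ndarray | Sequence[str]) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype.kind in "US":
            idx = self.sample_index(keep)
        elif keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep.astype(int)
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.values[:, idx],
            self.mask[:, idx],
            self.spikein,
        )

    def imputed(self) -> np.ndarray:
        """Values with masked cells replaced by the gene's mean usable value.

        Classifiers and clustering need a dense matrix; mean imputation per
        gene is neutral for split thresholds and Euclidean distances.  Genes
        with no usable value at all impute to 0.
        """
        vals = np.where(self.mask, self.values, np.nan)
        with np.errstate(invalid="ignore"):
            gene_means = np.nanmean(np.where(self.mask, vals, np.nan), axis=1)
        gene_means = np.where(np.isfinite(gene_means), gene_means, 0.0)
        out = np.where(self.mask, self.values, gene_means[:, None])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Genes x samples DataFrame with NaN at masked cells."""
        vals = np.where(self.mask, self.values, np.nan)
        return pd.DataFrame(vals, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleAnnotation:
    """Treatment metadata for one array.

    ``class_label`` carries the K-class assignment used throughout (in the
    motivating design: control / TNT / RDX pooled over concentrations and
    exposure durations).  ``experiment_block`` names the exposure batch
    (e.g. D4orig / D4Rpt / D14) so comparison suites can slice on it.
    """

    sample_id: str
    class_label: str
    compound: str | None = None
    concentration: float | None = None
    duration_days: float | None = None
    experiment_block: str | None = None
    replicate: int | None = None


def annotation_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in annotations]).set_index("sample_id")


@dataclass
class SpikeInTable:
    """Known concentrations of spike-in control probes (per-array standard curve)."""

    probe_ids: list[str]
    known_concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.known_concentrations = np.asarray(self.known_concentrations, dtype=float)
        check_unique(self.probe_ids, "spike-in probe")
        if np.any(self.known_concentrations <= 0):
            raise ValidationError("spike-in concentrations must be positive")
        if len(set(self.known_concentrations.tolist())) < 2:
            raise ValidationError(
                "need at least 2 distinct spike-in concentrations to fit a line"
            )


@dataclass
class PipelineConfig:
    """Run-level settings for the end-to-end pipeline.

    Defaults mirror the published protocol where one exists (presence
    fraction 0.5; permutation filter at 99% confidence with at most 10
    false positives) and otherwise a desk-scale choice documented in the
    methods note.
    """

    class_names: list[str] = field(default_factory=lambda: ["control", "TNT", "RDX"])
    linear_range_low: float = 1.0
    linear_range_high: float = 1e5
    presence_fraction: float = 0.5
    n_permutations: int = 1000
    confidence: float = 0.99
    max_false_positives: int = 10
    n_tree_models: int = 12
    ensemble_members: int = 25
    svm_C: float = 1.0
    cv_folds: int = 10
    kmeans_restarts: int = 50
    seed: int = 0
    out_dir: str = "isml_out"

    def __post_init__(self) -> None:
        if not 0 < self.presence_fraction <= 1:
            raise ValidationError("presence fraction must lie in (0, 1]")
        if not 0 < self.confidence < 1:
            raise ValidationError("confidence must lie in (0, 1)")
        if self.max_false_positives < 0:
            raise ValidationError("max_false_positives must be >= 0")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
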