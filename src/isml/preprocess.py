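"""Array pre-treatment: flagging, spike-in conversion, normalization, filtering.

The four steps run in a fixed order:

1. ``flag_features`` — mask spots whose intensity falls outside the scanner's
   linear range, plus any externally supplied spot flags (non-uniform spots
   are a scanner-software call that cannot be recomputed from intensities).
2. ``spike_in_convert`` — per array, regress log known concentration on log
   observed intensity over the spike-in probes and map every usable
   intensity through the fitted standard curve, yielding relative RNA
   concentrations.
3. ``median_normalize`` — divide each array by its median usable value.
4. ``filter_genes_by_presence`` — drop genes usable on fewer than a fraction
   of arrays (at 50% of 248 arrays this is the classic "present on at least
   124 arrays" rule).

Steps never un-mask a cell; steps 3-4 are idempotent on their own output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, SpikeInTable
from .errors import IsmlError, ValidationError

__all__ = [
    "LinearRange",
    "flag_features",
    "spike_in_convert",
    "median_normalize",
    "filter_genes_by_presence",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class LinearRange:
    """Bounds of the scanner's linear response, in signal-intensity units."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError("linear range requires low < high")


def flag_features(
    m: ExpressionMatrix,
    linear_range: LinearRange,
    extra_flags: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Mask out-of-linear-range intensities and externally flagged spots.

    ``extra_flags`` (True = flagged) carries spot-quality calls made by the
    image-analysis software.  Values are left untouched; only the mask
    changes.
    """
    out = m.copy()
    with np.errstate(invalid="ignore"):
        out_of_range = (m.values < linear_range.low) | (m.values > linear_range.high)
    out.mask &= ~(out_of_range & np.isfinite(m.values))
    out.mask &= ~np.isnan(m.values)
    if extra_flags is not None:
        extra_flags = np.asarray(extra_flags, dtype=bool)
        if extra_flags.shape != m.values.shape:
            raise ValidationError("extra_flags shape must match the matrix")
        out.mask &= ~extra_flags
    return out


def spike_in_convert(m: ExpressionMatrix, spikes: SpikeInTable) -> ExpressionMatrix:
    """Convert intensities to relative concentrations via per-array spike-in curves.

    For each array, ordinary least squares of log(known concentration) on
    log(observed spike-in intensity) gives the standard curve
    ``log c = alpha + beta log x``; every usable value is mapped through it.
    Non-positive spike-in intensities are masked before fitting; an array
    with fewer than two usable spike-ins (or without two distinct
    intensities) is an error naming the array.  Spike-in rows stay in the
    matrix, still labelled by the ``spikein`` flag.
    """
    spike_idx = m.gene_index(spikes.probe_ids)
    out = m.copy()
    log_conc = np.log(spikes.known_concentrations)
    for j, sample in enumerate(m.sample_ids):
        sx = m.values[spike_idx, j]
        usable = m.mask[spike_idx, j] & np.isfinite(sx) & (sx > 0)
        if usable.sum() < 2 or len(set(sx[usable].tolist())) < 2:
            raise IsmlError(
                f"array {sample!r}: fewer than 2 usable spike-in intensities "
                "to fit a standard curve"
            )
        beta, alpha = np.polyfit(np.log(sx[usable]), log_conc[usable], 1)
        col = out.values[:, j]
        ok = out.mask[:, j] & np.isfinite(col) & (col > 0)
        out.mask[:, j] &= ok
        col[ok] = np.exp(alpha + beta * np.log(col[ok]))
        out.values[:, j] = col
    return out


def median_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each array by the median of its usable values.

    Median over usable cells only; even counts average the two central
    values.  Afterwards every array's usable median equals 1 up to floating
    error.  An all-masked array is an error naming the array.
    """
    out = m.copy()
    for j, sample in enumerate(m.sample_ids):
        usable = out.mask[:, j]
        if not usable.any():
            raise IsmlError(f"array {sample!r} has no usable values to normalize")
        med = float(np.median(out.values[usable, j]))
        if med == 0:
            raise IsmlError(f"array {sample!r} has zero median; cannot normalize")
        out.values[usable, j] = out.values[usable, j] / med
    return out


def filter_genes_by_presence(m: ExpressionMatrix, min_fraction: float) -> ExpressionMatrix:
    """Keep genes usable on at least ceil(min_fraction * n_samples) arrays.

    The ceiling makes "half of 248" the familiar at-least-124-arrays rule.
    Spike-in rows are always retained (they are controls, not genes).  Row
    order is preserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValidationError("min_fraction must lie in (0, 1]")
    threshold = math.ceil(min_fraction * m.n_samples)
    present = m.mask.sum(axis=1) >= threshold
    keep = present | m.spikein
    return m.subset_genes(keep)


def preprocess_pipeline(
    m: ExpressionMatrix,
    linear_range: LinearRange,
    spikes: SpikeInTable | None = None,
    extra_flags: np.ndarray | None = None,
    presence_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Run flag -> convert -> normalize -> filter in the fixed order."""
    out = flag_features(m, linear_range, extra_flags)
    if spikes is not None:
        out = spike_in_convert(out, spikes)
    out = median_normalize(out)
    return filter_genes_by_presence(out, presence_fraction)
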