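"""Synthetic multi-class expression datasets with planted classifier genes.

The generator emulates the statistical structure the pipeline assumes for a
soil-exposure microarray experiment: a treatment design of class x compound x
concentration x duration groups with replicate animals, log-normal signal
intensities whose per-gene variances follow an inverse-gamma prior (the
hierarchical assumption behind the random-variance test), class-discriminative
genes whose log-mean is shifted in their target class, spike-in control probes
lying on a log-log standard curve, and independently missing / flagged spots.

Every draw derives from a single integer seed through per-gene substreams
(``SeedSequence`` spawn keys), so enlarging ``n_genes`` never reshuffles the
values of earlier genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .datatypes import ExpressionMatrix, SampleAnnotation, SpikeInTable
from .errors import DesignError, IsmlError

__all__ = [
    "GroupSpec",
    "SimulationDesign",
    "PlantedTruth",
    "default_design",
    "study_scale_design",
    "generate_dataset",
    "recovery_score",
]


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: class x compound x concentration x duration."""

    class_label: str
    compound: str | None
    concentration: float
    duration_days: float
    n_replicates: int
    block: str = ""


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic dataset.

    ``variance_prior`` is (shape a, scale b) of the inverse-gamma prior on
    per-gene variances, parameterized so that the gene precision 1/sigma^2 is
    Gamma(a, scale=b) — the convention under which the moderated variance
    adds ``2/b`` to the residual sum of squares and ``2a`` degrees of
    freedom.  ``effect_size`` is the mean log-expression shift planted in a
    discriminative gene's target class.  ``n_discriminative`` counts planted
    genes per non-baseline class (the first class in ``class_names`` is the
    unshifted baseline).
    """

    groups: tuple[GroupSpec, ...]
    n_genes: int = 2000
    n_discriminative: int = 30
    effect_size: float = 1.5
    variance_prior: tuple[float, float] = (3.0, 1.0)
    baseline_log_expression: float = 7.0
    missing_rate: float = 0.05
    n_spikeins: int = 10
    spikein_slope: float = 1.0
    spikein_intercept: float = 0.0
    spikein_noise_sd: float = 0.05
    seed: int = 0

    @property
    def class_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g.class_label not in seen:
                seen.append(g.class_label)
        return seen

    @property
    def n_samples(self) -> int:
        return sum(g.n_replicates for g in self.groups)

    def validate(self) -> None:
        if len(self.class_names) < 2:
            raise DesignError("need at least 2 classes")
        n_target = len(self.class_names) - 1
        if self.n_discriminative * n_target > self.n_genes:
            raise DesignError(
                f"{self.n_discriminative} discriminative genes per class x "
                f"{n_target} classes exceed {self.n_genes} genes"
            )
        if not 0 <= self.missing_rate < 1:
            raise DesignError("missing_rate must lie in [0, 1)")
        a, b = self.variance_prior
        if a <= 0 or b <= 0:
            raise DesignError("variance prior parameters must be positive")

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=seed)


@dataclass
class PlantedTruth:
    """Which genes were planted as class-discriminative (ground truth)."""

    discriminative_genes: dict[str, set[str]]
    null_genes: set[str]

    @property
    def all_discriminative(self) -> set[str]:
        out: set[str] = set()
        for genes in self.discriminative_genes.values():
            out |= genes
        return out


def default_design(seed: int = 0, **overrides) -> SimulationDesign:
    """Desk-scale analogue of a 3-class soil-exposure study.

    12 treatment groups x 8 replicate animals = 96 arrays: 2 control groups
    and 5 concentration groups for each of two compounds, 2,000 genes of
    which 30 respond to each compound.  Small enough that the full pipeline
    runs in minutes, yet keeps the unbalanced class sizes and the
    concentration-series structure of the motivating experiment.
    """
    tnt_concs = [6, 12, 24, 48, 96]
    rdx_concs = [8, 16, 32, 64, 128]
    groups = [
        GroupSpec("control", None, 0.0, 4.0, 8, "D4orig"),
        GroupSpec("control", None, 0.0, 14.0, 8, "D14"),
    ]
    groups += [GroupSpec("TNT", "TNT", c, 4.0, 8, "D4orig") for c in tnt_concs]
    groups += [GroupSpec("RDX", "RDX", c, 4.0, 8, "D4orig") for c in rdx_concs]
    return SimulationDesign(groups=tuple(groups), seed=seed, **overrides)


def study_scale_design(seed: int = 0, **overrides) -> SimulationDesign:
    """Full-scale treatment layout: 31 groups x 8 replicates = 248 arrays.

    Class sizes 32 control / 96 TNT / 120 RDX, split over an original 4-day
    exposure, a repeated 4-day exposure and a 14-day exposure (plus a day-0
    control group), mirroring the shape of the motivating dataset.
    """
    groups = [
        GroupSpec("control", None, 0.0, 0.0, 8, "D0"),
        GroupSpec("control", None, 0.0, 4.0, 8, "D4orig"),
        GroupSpec("control", None, 0.0, 4.0, 8, "D4Rpt"),
        GroupSpec("control", None, 0.0, 14.0, 8, "D14"),
    ]
    groups += [GroupSpec("TNT", "TNT", c, 4.0, 8, "D4orig") for c in (6, 12, 24)]
    groups += [GroupSpec("TNT", "TNT", c, 4.0, 8, "D4Rpt") for c in (6, 12, 24, 48)]
    groups += [GroupSpec("TNT", "TNT", c, 14.0, 8, "D14") for c in (6, 12, 24, 48, 96)]
    groups += [GroupSpec("RDX", "RDX", c, 4.0, 8, "D4orig") for c in (8, 16, 32, 64, 128)]
    groups += [GroupSpec("RDX", "RDX", c, 4.0, 8, "D4Rpt") for c in (2, 4, 8, 16, 32)]
    groups += [GroupSpec("RDX", "RDX", c, 14.0, 8, "D14") for c in (8, 16, 32, 64, 128)]
    return SimulationDesign(groups=tuple(groups), seed=seed, **overrides)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_dataset(
    design: SimulationDesign,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SpikeInTable | None, PlantedTruth]:
    """Draw one dataset from the design; bit-reproducible from ``design.seed``.

    Model per regular gene g: sigma_g^2 ~ InvGamma(a, scale 1/b) (i.e. the
    precision is Gamma(a, scale b)); log-expression of sample j is
    Normal(mu0 + delta_gj, sigma_g^2) with delta_gj = effect_size when j's
    class is g's target class, else 0; the stored value is the exponential
    (intensity scale).  Spike-in probes follow the configured log-log
    standard curve log(conc) = intercept + slope * log(intensity), inverted
    with Gaussian noise on log-intensity.  Mask entries are false
    independently with probability ``missing_rate``.
    """
    design.validate()
    a, b = design.variance_prior
    classes = design.class_names
    n_samples = design.n_samples

    # sample annotations, group by group
    annotations: list[SampleAnnotation] = []
    labels: list[str] = []
    counter = 0
    for g in design.groups:
        for rep in range(1, g.n_replicates + 1):
            counter += 1
            annotations.append(
                SampleAnnotation(
                    sample_id=f"s{counter:04d}",
                    class_label=g.class_label,
                    compound=g.compound,
                    concentration=g.concentration,
                    duration_days=g.duration_days,
                    experiment_block=g.block or None,
                    replicate=rep,
                )
            )
            labels.append(g.class_label)
    label_arr = np.array(labels)
    sample_ids = [s.sample_id for s in annotations]

    # planted truth: n_discriminative genes per non-baseline class, chosen
    # by a dedicated substream so gene draws stay untouched
    target_classes = classes[1:]
    picker = _stream(design.seed, 1)
    n_planted = design.n_discriminative * len(target_classes)
    planted_idx = picker.choice(design.n_genes, size=n_planted, replace=False)
    gene_target: dict[int, str] = {}
    for ci, cls in enumerate(target_classes):
        for gi in planted_idx[ci * design.n_discriminative : (ci + 1) * design.n_discriminative]:
            gene_target[int(gi)] = cls

    gene_ids = [f"g{i + 1:05d}" for i in range(design.n_genes)]
    values = np.empty((design.n_genes, n_samples))
    mu0 = design.baseline_log_expression
    for gi in range(design.n_genes):
        rng = _stream(design.seed, 0, gi)
        sigma2 = 1.0 / rng.gamma(a, b)
        shift = np.zeros(n_samples)
        target = gene_target.get(gi)
        if target is not None:
            shift[label_arr == target] = design.effect_size
        values[gi] = np.exp(mu0 + shift + math.sqrt(sigma2) * rng.standard_normal(n_samples))

    truth = PlantedTruth(
        discriminative_genes={
            cls: {gene_ids[gi] for gi, t in gene_target.items() if t == cls}
            for cls in target_classes
        },
        null_genes={gene_ids[i] for i in range(design.n_genes) if i not in gene_target},
    )

    # spike-in probes on the standard curve
    spike_ids = [f"spike{i + 1:03d}" for i in range(design.n_spikeins)]
    concs = np.logspace(0, 4, design.n_spikeins) if design.n_spikeins else np.empty(0)
    spike_rows = np.empty((design.n_spikeins, n_samples))
    for si in range(design.n_spikeins):
        rng = _stream(design.seed, 2, si)
        log_x = (np.log(concs[si]) - design.spikein_intercept) / design.spikein_slope
        spike_rows[si] = np.exp(log_x + design.spikein_noise_sd * rng.standard_normal(n_samples))
    spikes = SpikeInTable(spike_ids, concs) if design.n_spikeins else None

    all_values = np.vstack([values, spike_rows]) if design.n_spikeins else values
    all_ids = gene_ids + spike_ids
    spikein_flag = np.zeros(len(all_ids), dtype=bool)
    spikein_flag[design.n_genes :] = True

    mask_rng = _stream(design.seed, 3)
    mask = mask_rng.random(all_values.shape) >= design.missing_rate
    # keep every spike-in usable so per-array standard curves always fit
    mask[design.n_genes :, :] = True

    matrix = ExpressionMatrix(all_ids, sample_ids, all_values, mask, spikein_flag)
    return matrix, annotations, spikes, truth


def recovery_score(
    ranked_genes: Sequence[str], truth: PlantedTruth, top_k: int
) -> float:
    """Fraction of the ``top_k`` ranked genes that were planted as discriminative."""
    if top_k <= 0:
        raise IsmlError("top_k must be positive")
    if top_k > len(ranked_genes):
        raise IsmlError("top_k exceeds the ranked list length")
    planted = truth.all_discriminative
    hits = sum(1 for g in ranked_genes[:top_k] if g in planted)
    return hits / top_k
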