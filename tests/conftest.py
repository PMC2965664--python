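"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from isml.datatypes import ExpressionMatrix
from isml.synthetic import (
    GroupSpec,
    SimulationDesign,
    default_design,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 3-class dataset: 300 genes (12 planted/class), 48 samples."""
    design = default_design(seed=123, n_genes=300, n_discriminative=12)
    design = design.with_seed(123)
    # halve the replicates for speed
    groups = tuple(
        GroupSpec(g.class_label, g.compound, g.concentration, g.duration_days, 4, g.block)
        for g in design.groups
    )
    design = SimulationDesign(
        groups=groups, n_genes=300, n_discriminative=12, seed=123
    )
    return generate_dataset(design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_matrix(rng):
    """20 x 10 matrix with ~15% missing cells (NaN, masked)."""
    values = rng.lognormal(mean=5.0, sigma=1.0, size=(20, 10))
    mask = rng.random((20, 10)) >= 0.15
    values = np.where(mask, values, np.nan)
    return ExpressionMatrix(
        [f"g{i}" for i in range(20)],
        [f"s{j}" for j in range(10)],
        values,
        mask,
    )
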