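"""Shared fixtures: small synthetic atlases generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from stressatlas import degs as degmod
from stressatlas import grn as grnmod
from stressatlas.design import make_design
from stressatlas.synthetic import (
    generate_bundle,
    plant_truth,
    simulate_log2fc,
    uniform_additivity,
)


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def small_bundle():
    """A small noisy atlas: 400 targets, 25 TFs, default additive mixing."""
    return generate_bundle(seed=11, n_genes=400, n_tfs=25, dispersion=0.2)


@pytest.fixture(scope="session")
def small_degsets(small_bundle):
    design, _truth, _lfc, _matrix, de_tables = small_bundle
    return degmod.consolidate_de_tables(de_tables, design.stress_conditions)


@pytest.fixture(scope="session")
def noiseless_truth(design):
    """Zero-noise planted truth: downstream inference should be exact.

    One TF per stress keeps the 25 condition profiles full rank in the TFs —
    with additive combinations the profile matrix has rank at most 7, so a
    larger TF panel would be collinear and the regression underdetermined.
    """
    return plant_truth(
        design,
        n_genes=150,
        n_tfs=7,
        edge_density=0.2,
        noise_sd=0.0,
        seed=5,
        additivity_params=uniform_additivity(design, 0.0, 0.6, 0.7),
    )


@pytest.fixture(scope="session")
def noiseless_log2fc(noiseless_truth, design):
    return simulate_log2fc(noiseless_truth, design)


@pytest.fixture(scope="session")
def grn_models(small_bundle, small_degsets):
    """All ElasticNet models for the small atlas (8 datasets x responses)."""
    design, truth, _lfc, matrix, _de = small_bundle
    slices = grnmod.prepare_slices(matrix, small_degsets, set(truth.tfs), design)
    models = []
    for name in sorted(slices):
        models.extend(grnmod.fit_slice(slices[name], seed=0))
    return slices, models


def random_sets(rng: np.random.Generator, n_items: int = 30, max_size: int = 20):
    pool = [f"g{i}" for i in range(n_items)]
    def one():
        k = int(rng.integers(0, max_size + 1))
        return set(rng.choice(pool, size=k, replace=False)) if k else set()
    return one
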