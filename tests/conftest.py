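"""Shared fixtures: geometries, seeded generators, and synthetic helpers."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from chondroscreen.io import migration_geometry, morphology_geometry
from chondroscreen.synthetic import (
    EffectModel,
    basal_effect,
    chondro_effect,
    generate_field_stack,
    sample_truth_cells,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def morph_geo():
    """Morphology acquisition: 8 planes, 2 µm step, 0.6 µm/px."""
    return morphology_geometry(0.6)


@pytest.fixture
def migr_geo():
    """Migration acquisition: 102 planes, 5 µm step, 0.6 µm/px."""
    return migration_geometry(0.6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_cells(
    effect: EffectModel,
    n: int,
    geometry,
    shape=(256, 256),
    seed: int = 0,
    min_separation_sigma: float | None = None,
    intensity: float | None = None,
):
    """Sample ground-truth cells, optionally pinning intensity_scale."""
    gen = np.random.default_rng(seed)
    cells = sample_truth_cells(
        effect, n, geometry, shape, gen, min_separation_sigma=min_separation_sigma
    )
    if intensity is not None:
        cells = [replace(c, intensity_scale=intensity) for c in cells]
    return cells


def render_isolated_cell(effect, geometry, shape=(288, 288), seed: int = 0, noise_sd: float = 0.0):
    """One cell alone in a field, rendered noise-free by default."""
    cells = make_cells(effect, 1, geometry, shape, seed=seed)
    stack, truth = generate_field_stack(cells, geometry, noise_sd=noise_sd, rng_seed=seed, shape=shape)
    return stack, truth[0]
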