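"""Shared fixtures: tiny grids, the toy space and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from cms_lesionmap import (BinaryMask, SyntheticCohortSpec, VolumeGrid,
                           WeightMap, generate_cohort, make_toy_space)


def make_mask(shape, voxels, affine=None) -> BinaryMask:
    """Binary mask with the given foreground voxel indices."""
    data = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        data[tuple(v)] = 1
    if affine is None:
        affine = np.eye(4)
    return BinaryMask(data=data, affine=np.asarray(affine, dtype=float))


@pytest.fixture(scope="session")
def toy_space():
    return make_toy_space((64, 64, 64))


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded synthetic cohort of 40 subjects with the planted effect."""
    return generate_cohort(SyntheticCohortSpec(n_subjects=40, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
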