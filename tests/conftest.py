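"""Shared fixtures: small noise volumes and a tiny planted-signal cohort."""

from __future__ import annotations

import numpy as np
import pytest

from shellrad import PhantomConfig, Volume, generate_cohort, make_sphere_mask


@pytest.fixture(scope="session")
def noise_volume() -> Volume:
    """A 40³ isotropic volume of soft-tissue-like noise (HU)."""
    rng = np.random.default_rng(7)
    data = rng.normal(40.0, 20.0, size=(40, 40, 40))
    return Volume(data, np.ones(3), np.zeros(3))


@pytest.fixture(scope="session")
def center_voxel() -> np.ndarray:
    """A centroid exactly on a voxel center of :func:`noise_volume`."""
    return np.array([19.0, 19.0, 19.0])


@pytest.fixture(scope="session")
def sphere_mask(noise_volume, center_voxel):
    return make_sphere_mask(noise_volume, center_voxel, 15.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 2×12-subject planted-signal phantom cohort (64³, signal in [9,12))."""
    return generate_cohort(PhantomConfig(n_per_class=12, seed=3))
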