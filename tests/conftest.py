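"""Shared fixtures: small random studies and a tiny synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from ftvsweep.enhancement import DCEStudy, compute_enhancement_maps
from ftvsweep.synthetic import SimConfig, simulate_cohort

VOXEL = (0.7, 0.94, 2.0)


def random_study(rng: np.random.Generator, shape=(8, 8, 4), s0_range=(1.0, 500.0)) -> DCEStudy:
    s0 = rng.uniform(*s0_range, size=shape)
    s_early = s0 * rng.uniform(0.5, 3.5, size=shape)
    s_late = s0 * rng.uniform(0.5, 3.0, size=shape)
    return DCEStudy(
        patient_id="R000", visit="MRI_1",
        s0=s0, s_early=s_early, s_late=s_late, voxel_size_mm=VOXEL,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_study(rng) -> DCEStudy:
    return random_study(rng)


@pytest.fixture
def small_maps(small_study):
    return compute_enhancement_maps(small_study, s0_floor=10.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 10-patient cohort with surfaces kept, reused across tests."""
    cfg = SimConfig(n_patients=10, seed=7)
    return simulate_cohort(cfg, keep_surfaces=True)
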