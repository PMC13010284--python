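"""Shared fixtures: small, fast phantom specs and precomputed subjects."""

from __future__ import annotations

import numpy as np
import pytest

from gliomap.phantom import (DensityParams, PhantomSpec, TumorGeometry,
                             generate_cohort, generate_subject)
from gliomap.dataset import preprocess_subject

# A reduced grid that keeps every anatomical ingredient but generates in ~0.1 s.
SMALL_SPEC = PhantomSpec(
    grid_shape=(64, 64, 40),
    voxel_size_mm=(2.5, 2.5, 2.5),
    brain_semiaxes_mm=(55.0, 60.0, 40.0),
    cerebellum_center_mm=(0.0, -38.0, -22.0),
    cerebellum_semiaxes_mm=(20.0, 16.0, 12.0),
    tumor_geometry=TumorGeometry(center_mm=(15.0, 18.0, 6.0), core_radius_mm=7.0,
                                 ncet_thickness_mm=5.0, edema_thickness_mm=7.0),
    geometry_jitter_mm=2.0,
    seed=0,
)

LOW_NOISE_SD = {"t1w": 1.0, "t2w": 1.0, "t1gd": 1.0, "pet": 0.004}


def low_noise(spec: PhantomSpec, **overrides) -> PhantomSpec:
    from dataclasses import replace
    overrides.setdefault("noise_sd", dict(LOW_NOISE_SD))
    return replace(spec, **overrides)


@pytest.fixture(scope="session")
def subject():
    return generate_subject(SMALL_SPEC, 0)


@pytest.fixture(scope="session")
def processed(subject):
    return preprocess_subject(subject)


@pytest.fixture(scope="session")
def cohort3():
    return generate_cohort(SMALL_SPEC, 3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
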