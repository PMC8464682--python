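"""Shared fixtures: small deterministic volumes, masks and records."""

import numpy as np
import pytest

from edemarad.model_pipeline import LesionRecord
from edemarad.roi_geometry import RoiMask, VoxelVolume
from edemarad.synthetic_data import generate_ellipsoid_mask, generate_texture_volume


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def textured_volume():
    return generate_texture_volume((16, 16, 16), 1.5, 3000, 600, seed=7)


@pytest.fixture
def ellipsoid_mask():
    return generate_ellipsoid_mask((16, 16, 16), (8, 8, 8), (5, 4, 5))


@pytest.fixture
def random_volume(rng):
    return VoxelVolume(rng.integers(0, 200, size=(8, 8, 8)).astype(np.uint16))


@pytest.fixture
def full_mask():
    return RoiMask(np.ones((8, 8, 8), dtype=bool))


@pytest.fixture
def record():
    return LesionRecord(
        lesion_id="fixture",
        age=55.0, menopause=1, family_history=0, hormone_therapy=0,
        location=2, stadiation=1, margins=1, dimensions=22.0,
        morphology=1, kinetic_curve=2, edema_type=1,
        histological_type="IDC", grade=3, er_percent=80.0,
        pgr_percent=40.0, her2_status=0, ki67_percent=30.0,
    )
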