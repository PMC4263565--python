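"""Shared test fixtures: small noiseless/noisy cameras and geometries."""

import numpy as np
import pytest

from lfaquant import OpticsConfig, SpotGeometry


@pytest.fixture
def noiseless_optics():
    return OpticsConfig(
        width_px=96, height_px=64, bit_depth=8, background_dn=20.0,
        read_noise_dn=0.0, shot_noise=False, reference_exposure_s=1.0 / 15.0,
    )


@pytest.fixture
def noisy_optics():
    return OpticsConfig(
        width_px=96, height_px=64, bit_depth=8, background_dn=20.0,
        read_noise_dn=2.0, shot_noise=False, reference_exposure_s=1.0 / 15.0,
    )


@pytest.fixture
def disk_geometry():
    return SpotGeometry(center=(32, 48), radius_px=8.0, crescent=False, flank_gap_px=5)


@pytest.fixture
def crescent_geometry():
    return SpotGeometry(
        center=(32, 48), radius_px=8.0, crescent=True, crescent_fraction=0.35,
        flank_gap_px=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
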