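import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cermap import CellGeometry, LocalizationProfile, NoiseModel


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Smaller frame for fast unit tests (same structure, less area)."""
    return CellGeometry(
        image_shape=(96, 96),
        cell_axes=(26.0, 34.0),
        plate_axes=(14.0, 5.0),
        spindle_axes=(12.0, 24.0),
        centrosome_offset=24.0,
    )


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel.noiseless()


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture
def uniform_profile():
    return LocalizationProfile(name="uniform")
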