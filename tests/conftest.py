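import numpy as np
import pytest

from nitramap.chemometrics import CalibrationTable
from nitramap.cube import HyperCube
from nitramap.synthetic import PhantomConfig, generate_calibration_set, generate_leaf_phantom


@pytest.fixture(scope="session")
def config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def phantom(config):
    """Default leaf phantom: blade 3,000 / vein 12,000 / petiole 14,000 mg/kg."""
    return generate_leaf_phantom(config, seed=2)


@pytest.fixture(scope="session")
def cal_small(config) -> CalibrationTable:
    """40-sample synthetic calibration set at default noise."""
    return generate_calibration_set(config, n_samples=40, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cube() -> HyperCube:
    """4 x 5 x 6 raw cube with a deterministic ramp payload."""
    data = np.arange(4 * 5 * 6, dtype=float).reshape(4, 5, 6) + 10.0
    wavelengths = 1000.0 + 10.0 * np.arange(6)
    return HyperCube(data, wavelengths)
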