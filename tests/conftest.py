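import numpy as np
import pytest

from metaii.buildup import (
    CALIBRATION_DISTANCES,
    DEFAULT_MIXING_GRID,
    BuildupParams,
    calibrate,
    normalize_to_control,
)
from metaii.synthetic import calibration_geometry, default_basis, generate_buildup_dataset
from metaii.titration import BasisSet


@pytest.fixture(scope="session")
def params():
    return BuildupParams()


@pytest.fixture(scope="session")
def grid():
    return np.asarray(DEFAULT_MIXING_GRID)


@pytest.fixture(scope="session")
def calibration_table(params):
    """Noiseless, normalized table of the five fixed-distance pairs."""
    table = generate_buildup_dataset(calibration_geometry(), params)
    return normalize_to_control(table, "C12-C20")


@pytest.fixture(scope="session")
def calibrated(calibration_table):
    return calibrate(calibration_table, CALIBRATION_DISTANCES)


@pytest.fixture(scope="session")
def basis():
    return BasisSet.from_frame(default_basis())
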