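import numpy as np
import pytest

from cellflim.flim_core import TimingCalibration


@pytest.fixture(scope="session")
def calib():
    """Default 80 MHz / 256-bin calibration (12.5 ns period)."""
    return TimingCalibration()


@pytest.fixture(scope="session")
def calib8():
    """Minimal 8-bin calibration for hand-computable examples."""
    return TimingCalibration(n_bins=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
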