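import numpy as np
import pytest

from bandbench import BandSpec, ExpBandpassParams, IIRDesignSpec, design_iir


@pytest.fixture(scope="session")
def fig_band():
    """The small illustrative configuration: fs=40 Hz, band 5-10 Hz."""
    return BandSpec(5.0, 10.0)


@pytest.fixture(scope="session")
def fig_butter(fig_band):
    return design_iir(IIRDesignSpec("butterworth", 4, fig_band, 40.0))


@pytest.fixture(scope="session")
def eeg_band():
    return BandSpec(0.5, 50.0)


@pytest.fixture(scope="session")
def eeg_cheby(eeg_band):
    return design_iir(IIRDesignSpec("chebyshev1", 4, eeg_band, 512.0, rp_db=0.5))


@pytest.fixture(scope="session")
def eeg_ellip(eeg_band):
    return design_iir(
        IIRDesignSpec("elliptic", 4, eeg_band, 512.0, rp_db=1.0, rs_db=40.0))


@pytest.fixture(scope="session")
def eeg_butter(eeg_band):
    return design_iir(IIRDesignSpec("butterworth", 4, eeg_band, 512.0))


@pytest.fixture
def default_params():
    return ExpBandpassParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sinusoid(freq, fs, n, phase=0.0):
    t = np.arange(n) / fs
    return np.sin(2.0 * np.pi * freq * t + phase)
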