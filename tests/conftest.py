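import numpy as np
import pytest

import adwt


@pytest.fixture(scope="session")
def ecg_default():
    """Default noisy ECG fixture: continuous-grid signal + beat times."""
    return adwt.synth_ecg(adwt.EcgSynthParams(seed=0))


@pytest.fixture(scope="session")
def eeg_records():
    """Four seeded two-state records at the default study size (100 epochs)."""
    return adwt.synth_eeg(adwt.EegSynthParams(seed=0))


@pytest.fixture(scope="session")
def white_noise_360():
    rng = np.random.default_rng(42)
    return adwt.Signal(rng.standard_normal(4096), 360.0)


def params_for(wavelet, fs=360.0):
    return adwt.ADWTDesignParams.for_wavelet(wavelet, fs)
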