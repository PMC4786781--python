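import numpy as np
import pytest

import pifeflow as pf
from pifeflow.twostate import TwoStateParams


@pytest.fixture
def r82a():
    return pf.get_preset("r82a")


@pytest.fixture
def spo0j_wt():
    return pf.get_preset("spo0j_wt")


@pytest.fixture
def hbsu_params():
    return TwoStateParams(K1=13.0, K2=390.0, I1=2.0, I2=4.0, L1=0.4, L2=0.95)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def clean_wt(spo0j_wt):
    """Wild-type preset with all stochasticity switched off."""
    return spo0j_wt.replace(noise_sd=0.0, length_noise_sd_um=0.0,
                            lag_sd_s=0.0, rate_sd_um_s=0.0)
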