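import warnings

import numpy as np
import pytest

import woundxrf as wx


@pytest.fixture(scope="session")
def sim_config() -> wx.SimConfig:
    return wx.SimConfig()


@pytest.fixture(scope="session")
def true_params(sim_config) -> wx.CalibrationParams:
    """Calibration constants implied exactly by the simulator configuration."""
    tp = sim_config.true_params()
    return wx.CalibrationParams(
        I0=tp["I0"],
        I0_Lb=tp["I0_Lb"],
        I1_La=tp["I1_La"],
        I1_Lb=tp["I1_Lb"],
        mu_La=tp["mu_La"],
        mu_Lb=tp["mu_Lb"],
        R0=tp["R0"],
        delta_mu=tp["delta_mu"],
    )


@pytest.fixture(scope="session")
def study_design(sim_config):
    """One full simulated phantom study: 6c x 5t x 4d, n=4 -> 480 spectra."""
    return wx.simulate_design(sim_config, seed=1)


@pytest.fixture(scope="session")
def fitted_params(study_design) -> wx.CalibrationParams:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return wx.build_calibration(study_design)


@pytest.fixture(scope="session")
def windows():
    return wx.default_windows()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
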