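"""Shared fixtures: reference parameter sets, protocols, small experiments."""

import numpy as np
import pytest

from per2osc import OscillatorParams
from per2osc.protocols import repeated_4h_sd, two_h_on_off
from per2osc.synth import SynthConfig, generate_experiment

#: Published point estimates for the lesioned-animal (SCNx) experiment and
#: the 2hOnOff experiment, used as ground truth throughout the tests.
SCNX_PARAMS = OscillatorParams(gamma=0.0155, omega0=0.288, beta=6.81e-5,
                               intercept=0.92, A=2.92e-3, phi=4.73)
ONOFF_PARAMS = OscillatorParams(gamma=0.0155, omega0=0.288, beta=6.81e-5,
                                intercept=0.91, A=3.87e-3, phi=2.78)
#: Published 95% CIs for the shared dynamical parameters.
GAMMA_CI = (0.0103, 0.0223)
OMEGA0_CI = (0.285, 0.291)


@pytest.fixture(scope="session")
def scnx_params():
    return SCNX_PARAMS


@pytest.fixture(scope="session")
def onoff_params():
    return ONOFF_PARAMS


@pytest.fixture(scope="session")
def sd_protocol():
    """7-day repeated-SD design: 2 baseline days, 4 daily 4-h SDs, recovery."""
    return repeated_4h_sd(baseline_h=48.0, n_days=4, recovery_h=24.0)


@pytest.fixture(scope="session")
def onoff_protocol():
    """2 baseline days, 2 days of alternating 2-h SD / 2-h SOW, 2 recovery."""
    return two_h_on_off(baseline_h=48.0, recovery_h=48.0)


@pytest.fixture(scope="session")
def scnx_experiment(sd_protocol):
    """One synthetic arrhythmic-animal recording at the reference truth."""
    cfg = SynthConfig(duration_h=168.0, circadian_modulation=0.0,
                      noise_sd=0.02, seed=11)
    return generate_experiment(cfg, SCNX_PARAMS, sd_protocol)


@pytest.fixture(scope="session")
def onoff_experiment(onoff_protocol):
    """One synthetic intact-animal recording under the 2hOnOff design."""
    cfg = SynthConfig(duration_h=144.0, circadian_modulation=0.8,
                      noise_sd=0.02, seed=13)
    return generate_experiment(cfg, ONOFF_PARAMS, onoff_protocol,
                               use_warmup=True)
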