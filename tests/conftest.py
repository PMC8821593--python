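import numpy as np
import pytest

import somitewave as sw


@pytest.fixture
def params():
    """Reference field: unit amplitude, lambda = 260 um, tau = 4.5 h."""
    return sw.MorphogenParams(amplitude_F0=1.0, decay_length_um=260.0, decay_time_h=4.5)


@pytest.fixture
def rule_x500(params):
    """Threshold chosen so the anchor sits at exactly 500 um."""
    eta = (
        params.amplitude_F0
        / params.decay_length_um
        * np.exp(-500.0 / params.decay_length_um)
    )
    return sw.ThresholdRule(eta_t=eta)


@pytest.fixture
def rule_x800(params):
    """Deeper threshold (anchor at 800 um), leaving room for perturbation shifts."""
    eta = (
        params.amplitude_F0
        / params.decay_length_um
        * np.exp(-800.0 / params.decay_length_um)
    )
    return sw.ThresholdRule(eta_t=eta)


@pytest.fixture
def clock27():
    """Clock at 27 degC from the period law, 20 somites."""
    return sw.ClockSchedule(period_h=sw.segmentation_period(27.0), n_somites=20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
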