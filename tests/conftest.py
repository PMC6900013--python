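import numpy as np
import pytest

from trialcal import ErrorModel, OutcomeModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def base_model():
    """Haemoglobin-style generating model used throughout: control mean 120
    g/L, treatment effect 6.9 g/L, residual SD 12.6 g/L."""
    return OutcomeModel(alpha_y=120.0, beta_y=6.9, sigma=12.6)


@pytest.fixture
def systematic_r08():
    """Systematic error, slope 1.05, within-arm R^2 = 0.8 (tau = 6.615)."""
    return ErrorModel.systematic(0.0, 1.05, 6.615)
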