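import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from rodflick import RodParams, StimulusSpec, get_preset

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def fig_params():
    """Control parameter set used for the model-behaviour illustrations
    (unit output scale so magnitudes are dimensionless fractions)."""
    return RodParams(tau_s=0.136, h0=4.0, collecting_area_um2=0.87, ec50=300.0,
                     f_onl=1.0, k0=1.0)


@pytest.fixture
def stim_6hz():
    return StimulusSpec(mean_irradiance=634.0, contrast=0.75, frequency_hz=6.0)


@pytest.fixture
def ctl_p23h():
    return get_preset("rho_wt_p23h_ctl")


@pytest.fixture
def p23h():
    return get_preset("rho_p23h")


@pytest.fixture
def ctl_hemi():
    return get_preset("rho_wt_hemi_ctl")


@pytest.fixture
def hemi():
    return get_preset("rho_hemi")


@pytest.fixture
def sat_strengths():
    """Six saturating flash strengths spanning two decades (R*/rod)."""
    return np.logspace(2, 4, 6)


@pytest.fixture
def dim_strengths():
    """Dim-flash strengths for amplification fitting (<= 100 R*/rod)."""
    return np.array([10.0, 30.0, 100.0])
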