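import numpy as np
import pytest

from faidsim.patient import PatientParams, VariabilityConfig, VirtualPatient


@pytest.fixture
def params() -> PatientParams:
    return PatientParams()


@pytest.fixture
def quiet_var() -> VariabilityConfig:
    """No circadian, absorption, or sensor variability."""
    return VariabilityConfig(si_amplitude=0.0, absorption_cv=0.0,
                             cgm_noise_sd=0.0, seed=0)


@pytest.fixture
def patient(params, quiet_var) -> VirtualPatient:
    return VirtualPatient(params, quiet_var, rng=np.random.default_rng(0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
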