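import numpy as np
import pytest

import dmtpk


@pytest.fixture(scope="session")
def params04():
    """Fitted 0.4 mg/kg parameter set, rescaled dialect (package default)."""
    return dmtpk.load_table2(0.4)


@pytest.fixture(scope="session")
def params02():
    return dmtpk.load_table2(0.2)


@pytest.fixture(scope="session")
def bolus04():
    """The study's reference administration: 0.4 mg/kg over 30 s, 75 kg."""
    return dmtpk.DosingRegimen.per_kg_bolus(0.4, 75.0)


@pytest.fixture(scope="session")
def tuned_effect(params04):
    """Effect-site link calibrated to the 3-min peak-effect observation."""
    return dmtpk.tune_effect_site(params04)


@pytest.fixture(scope="session")
def sampling_times():
    """Wall-clock sampling schedule: 2..60 min after the 45 s administration."""
    return 0.75 + np.array([2.0, 5.0, 10.0, 15.0, 30.0, 60.0])


@pytest.fixture(scope="session")
def gouzoulis_regimen():
    """Constant-rate literature protocol: 22.5 mg bolus + 1.5 mg/min x 84 min."""
    return dmtpk.DosingRegimen.per_kg_bolus(0.3, 75.0).with_infusion(1.5, 84.0, 1.5)


@pytest.fixture(scope="session")
def linear_params():
    """A linear-clearance two-compartment set for closed-form comparisons."""
    return dmtpk.PKParameters(Vc=90.0, Vp=300.0, Q12=50.0, CL=8.0)
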