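import numpy as np
import pytest
from hypothesis import settings

import nirsfusion as nf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table3():
    return nf.load_fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return nf.load_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return nf.load_fixture("table5")


@pytest.fixture(scope="session")
def table6():
    return nf.load_fixture("table6")


@pytest.fixture(scope="session")
def table7():
    return nf.load_fixture("table7")


@pytest.fixture(scope="session")
def exp1():
    return nf.make_protocol_exp1()


@pytest.fixture(scope="session")
def exp2():
    return nf.make_protocol_exp2(seed=1)


def quiet_params(**kw):
    """Generator parameters with every nuisance source switched off."""
    defaults = dict(coupling={}, noise_sd=0.0, physio_amps={}, drift_slope=0.0,
                    artifact_rate=0.0, latent_sd=0.0)
    defaults.update(kw)
    return nf.SubjectParams(**defaults)


@pytest.fixture(scope="session")
def noiseless_exp2_session(exp2):
    """Noiseless forward model: unit fusion response on CH12 only."""
    beta = np.zeros(14)
    beta[11] = 1.0
    params = quiet_params(beta_true={nf.FORG: beta, nf.RORG: 0.0})
    return nf.simulate_session(exp2, params, seed=3)
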