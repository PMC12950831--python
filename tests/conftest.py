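import numpy as np
import pytest

from pescreen import simulate


@pytest.fixture
def system():
    # chest-wall term disabled so occluded deflections are closed-form
    return simulate.RespiratorySystem(
        resistance=10.0, compliance_rs=45.0, elastance_cw=0.0, peep=5.0
    )


@pytest.fixture
def effort():
    return simulate.EffortProfile(p_max=10.0, t_insp=1.0, respiratory_rate=18.0)


@pytest.fixture
def vent():
    return simulate.VentilatorConfig()


@pytest.fixture
def clean_balloon():
    return simulate.BalloonModel(
        lambda_transmission=1.0, pes_offset=8.0, cardiac_amplitude=0.0, noise_sd=0.0
    )


def make_balloon(lam=1.0, offset=8.0, cardiac=0.0, noise=0.0, rate=80.0):
    return simulate.BalloonModel(
        lambda_transmission=lam,
        pes_offset=offset,
        cardiac_amplitude=cardiac,
        cardiac_rate=rate,
        noise_sd=noise,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
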