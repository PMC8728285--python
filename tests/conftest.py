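import pytest

from thermoscribe import AqueousConditions
from thermoscribe.fixtures import make_toy_atp_world, make_toy_universe


@pytest.fixture(scope="session")
def atp_world():
    return make_toy_atp_world()


@pytest.fixture()
def cond_i0():
    """Default pH/pMg at zero ionic strength (keeps transforms closed-form)."""
    return AqueousConditions(p_h=7.0, p_mg=3.0, ionic_strength=0.0, temperature=298.15)


@pytest.fixture(scope="session")
def noisefree_universe():
    return make_toy_universe(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_universe():
    return make_toy_universe(noise_sd=1.0, seed=13)
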