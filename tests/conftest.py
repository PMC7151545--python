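import pytest

from mutload import make_parameters


@pytest.fixture
def params_f005():
    """Canonical human-genome parameters at the running-example f = 0.05."""
    return make_parameters(f=0.05)


@pytest.fixture
def params_f005_recessive(params_f005):
    return params_f005.with_(scheme="recessive")


@pytest.fixture
def params_f025():
    """The illustration parameters for the simulated distributions."""
    return make_parameters(f=0.25)
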