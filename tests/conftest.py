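import hypothesis
import pytest

from truescoreci import IQ_SCALE, T_SCALE

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=200, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def t_scale():
    return T_SCALE


@pytest.fixture
def iq_scale():
    return IQ_SCALE
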