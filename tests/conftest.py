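import pytest

from slicephys import CCProtocol, NeuronParams


@pytest.fixture
def passive_params():
    """Purely passive membrane: no spike term, no sag, no adaptation."""
    return NeuronParams(delta_t_mv=0.0, v_t_mv=1e9, b_pa=0.0)


@pytest.fixture
def small_protocol():
    return CCProtocol(amplitudes_pa=(-20.0,), pre_s=0.2, step_s=1.0, post_s=0.1)
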