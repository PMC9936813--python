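import numpy as np
import pytest

from olmcell.io import reference_model


@pytest.fixture(scope="session")
def model():
    """The packaged reduced OLM cell model."""
    return reference_model()


@pytest.fixture(scope="session")
def passive_model(model):
    """Leak-only variant: every gated conductance zeroed."""
    return model.with_gbar({c.name: 0.0 for c in model.channels if c.gates})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230203)
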