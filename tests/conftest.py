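import numpy as np
import pytest

from oxyplankton import ModelParams


@pytest.fixture
def baseline():
    """Baseline kinetic constants with neutral mortality/timescale knobs."""
    return ModelParams.baseline(mu1=0.1, mu2=0.1, epsilon=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240527)


def random_admissible_states(rng, n=100, scale=3.0):
    """Random biologically admissible (c, u, v) states."""
    return rng.uniform(0.01, scale, size=(n, 3))
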