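import numpy as np
import pytest

from camsignal.network import integrate
from camsignal.parameters import apply_variant, default_parameters
from camsignal.stimulus import make_protocol


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def sim(params):
    """Cached (protocol, variant) → SimulationResult at tight tolerances."""
    cache = {}

    def run(protocol: str, variant: str = "wt", mode: str = "reduced_pka"):
        key = (protocol, variant, mode)
        if key not in cache:
            proto = make_protocol(protocol, Ca_basal=params.Ca_basal,
                                  tau=params.tau_decay)
            cache[key] = integrate(apply_variant(params, variant), proto,
                                   mode=mode)
        return cache[key]

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
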