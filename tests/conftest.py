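import numpy as np
import pytest
from hypothesis import settings

import rheonmr as rn

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return rn.CouetteGeometry()


@pytest.fixture(scope="session")
def pgse_dt2():
    """D-T2 acquisition: 32 gradient steps 0.1-6.6 T/m, delta 1 ms, Delta 200 ms."""
    return rn.PGSEParams(tuple(np.linspace(0.1, 6.6, 32)), 1e-3, 0.2)


@pytest.fixture(scope="session")
def pgse_minispec():
    """Droplet-sizing acquisition: Delta 211 ms, delta 2 ms, g up to 3 T/m."""
    return rn.PGSEParams(tuple(np.linspace(0.05, 3.0, 32)), 2e-3, 0.211)
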