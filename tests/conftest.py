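import numpy as np
import pytest

from playnet.network import TransitionNetwork
from playnet.zones import N_ZONES, default_zone_map


@pytest.fixture(scope="session")
def zm():
    return default_zone_map()


@pytest.fixture(scope="session")
def plate_vertices(zm):
    return sorted(zm.plate_vertices)


def make_network(transitions, zm, variant="direct"):
    """Build a TransitionNetwork directly from (origin, dest) pairs."""
    T = np.zeros((N_ZONES, N_ZONES), dtype=np.int64)
    for o, d in transitions:
        T[o, d] += 1
    return TransitionNetwork(
        T=T, variant=variant, zone_map=zm, transitions=list(transitions)
    )
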