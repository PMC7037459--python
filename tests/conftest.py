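import numpy as np
import pytest

from capi.synthetic_data import make_bridge_pdb, make_ring_cation


@pytest.fixture
def bridge_fixture():
    """Planted double-lateral bridge: one ARG CZ against two TRP rings."""
    model, rings = make_bridge_pdb((80.0, 15.0, 4.2), (85.0, 10.0, 4.0), decoys=3, seed=7)
    return model, rings


@pytest.fixture
def hexagon():
    """Regular hexagon of radius 1.4 A in the z=0 plane, as a coordinate array."""
    ang = np.deg2rad(np.arange(0, 360, 60))
    return np.column_stack([1.4 * np.cos(ang), 1.4 * np.sin(ang), np.zeros(6)])
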