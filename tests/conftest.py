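import numpy as np
import pytest

from tube3d import build_phantom
from tube3d.presets import specimen_phantom_spec, specimen_protocol, tiny_phantom_spec


@pytest.fixture(scope="session")
def specimen():
    """Reference specimen phantom (38 deg twist) + ground truth; built once."""
    vol, truth = build_phantom(specimen_phantom_spec())
    return vol, truth


@pytest.fixture(scope="session")
def specimen_proto():
    return specimen_protocol(seed=0)


@pytest.fixture(scope="session")
def tiny():
    """Small twisted phantom + protocol for fast experiments."""
    spec, proto = tiny_phantom_spec(twist_total_deg=20.0, n_sections=12)
    vol, truth = build_phantom(spec)
    return spec, proto, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_straight_tracks(n=60, z_step=0.363, jitter=0.0, rng=None):
    """Synthetic colinear fiducial tracks: three near-parallel 3D lines."""
    z = np.arange(n) * z_step
    anchors = np.array([[5.0, 2.0], [9.5, 8.0], [1.5, 8.5]])
    slopes = np.array([[0.01, 0.005], [-0.008, 0.004], [0.003, -0.009]])
    coords = anchors[None, :, :] + z[:, None, None] * slopes[None, :, :]
    if jitter and rng is not None:
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    return coords, z
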