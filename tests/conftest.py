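import numpy as np
import pytest

from npckit import synthetic
from npckit.volume import WedgeModel


def correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


@pytest.fixture(scope="session")
def c1_reference():
    """Small asymmetric (C1) reference used for pose-recovery tests."""
    spec = synthetic.GroundTruthComplex(
        n_spokes=1, ring_radius=50.0, box_size=32, voxel_size=10.0,
        spoke_blob_spec=[((0.0, 0.0, 20.0), 15.0, 1.0),
                         ((15.0, 30.0, 0.0), 12.0, 0.8),
                         ((-40.0, -20.0, -20.0), 18.0, 0.9)])
    volume, _ = synthetic.make_complex(spec)
    return volume


@pytest.fixture(scope="session")
def c1_reference_small():
    """24^3 C1 reference for brute-force oracle comparisons."""
    spec = synthetic.GroundTruthComplex(
        n_spokes=1, ring_radius=40.0, box_size=24, voxel_size=10.0,
        spoke_blob_spec=[((0.0, 0.0, 15.0), 14.0, 1.0),
                         ((10.0, 20.0, 0.0), 11.0, 0.8)])
    volume, _ = synthetic.make_complex(spec)
    return volume


@pytest.fixture(scope="session")
def c8_spec():
    return synthetic.GroundTruthComplex(
        n_spokes=8, ring_radius=90.0, box_size=32, voxel_size=10.0,
        spoke_blob_spec=[((0.0, 0.0, 10.0), 16.0, 1.0)])


@pytest.fixture(scope="session")
def c8_reference(c8_spec):
    volume, _ = synthetic.make_complex(c8_spec)
    return volume


@pytest.fixture
def standard_wedge():
    return WedgeModel(-60.0, 60.0)
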