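import numpy as np
import pytest

from angiolume.phantom import (
    Centerline,
    PhantomSpec,
    _paint_tubes,
    generate_vessel_tree,
    render_channels,
)
from angiolume.volume import ImageVolume


@pytest.fixture(scope="session")
def small_spec():
    """A small anisotropic phantom spec shared by read-only tests."""
    return PhantomSpec(shape=(24, 64, 64), spacing=(3.0, 1.0, 1.0), n_vessels=8, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    truth = generate_vessel_tree(small_spec)
    channels = render_channels(truth, small_spec)
    return small_spec, truth, channels


@pytest.fixture
def straight_tube():
    """Straight axis-aligned cylinder, radius 4 µm, length 100 µm, 1 µm voxels."""
    pts = np.stack(
        [np.full(101, 20.0), np.full(101, 20.0), np.arange(5.0, 106.0)], axis=1
    )
    cl = Centerline(pts, np.full(101, 4.0))
    mask = _paint_tubes((40, 40, 112), (1.0, 1.0, 1.0), [cl])
    return mask, cl


@pytest.fixture
def y_tree():
    """Three tubes meeting at one junction (radius 3 µm)."""

    def line(p0, p1, n=80):
        t = np.linspace(0, 1, n)[:, None]
        return np.asarray(p0, float) + t * (np.asarray(p1, float) - np.asarray(p0, float))

    pj = [24.0, 24.0, 50.0]
    cls = [
        Centerline(line([24.0, 24.0, 10.0], pj), np.full(80, 3.0)),
        Centerline(line(pj, [24.0, 44.0, 85.0]), np.full(80, 3.0)),
        Centerline(line(pj, [24.0, 4.0, 85.0]), np.full(80, 3.0)),
    ]
    return _paint_tubes((48, 48, 96), (1.0, 1.0, 1.0), cls)


@pytest.fixture
def volume_factory():
    def make(data, spacing=(1.0, 1.0, 1.0), role="generic"):
        return ImageVolume(np.asarray(data, float), spacing, role)

    return make
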