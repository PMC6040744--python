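import numpy as np
import pytest

import wormlf as w


@pytest.fixture(scope="session")
def optics():
    return w.NOMINAL_OPTICS


@pytest.fixture(scope="session")
def small_grid(optics):
    return w.SceneGrid(shape=(26, 26), spacing_um=optics.sample_spacing_um)


def make_flat_lightfield(value=1.0, n_spatial=12, n_angular=5, optics=None):
    """Constant-radiance field with a full (all-valid) angular aperture."""
    if optics is None:
        optics = w.OpticalParams(pitch_px=float(n_angular), mla_focal_um=10_000.0,
                                 magnification=10.0, aperture_radius_frac=1.0)
    shape = (n_spatial, n_spatial, n_angular, n_angular)
    return w.LightField4D(radiance=np.full(shape, float(value)),
                          weights=np.ones(shape), optics=optics)


def make_smooth_lightfield(seed=0, n_spatial=24, n_angular=5):
    """Seeded smooth random field (for interpolation-tolerant properties)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.random((n_spatial, n_spatial)), 3.0)
    base = 1.0 + base / max(base.max(), 1e-12)
    L = make_flat_lightfield(1.0, n_spatial, n_angular)
    L.radiance = np.broadcast_to(base[:, :, None, None], L.radiance.shape).copy()
    return L


@pytest.fixture
def flat_lightfield():
    return make_flat_lightfield()


@pytest.fixture
def smooth_lightfield():
    return make_smooth_lightfield()


@pytest.fixture(scope="session")
def point_scene(optics, small_grid):
    """A single bright in-plane point rendered through the phantom optics."""
    def _make(depth_um=0.0, pos=(13, 13)):
        scene = w.SceneTruth(
            image=np.ones(small_grid.shape), footprint=np.zeros(small_grid.shape, bool),
            depth=np.full(small_grid.shape, np.nan), midline_um=np.zeros((2, 3)),
            grid=small_grid)
        scene.footprint[pos] = True
        scene.depth[pos] = depth_um
        scene.image[pos] = 2.0
        return scene
    return _make
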