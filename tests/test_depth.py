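"""Cue responses, confidence, MRF fusion and depth calibration."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

import wormlf as w
from wormlf.depth import DepthParams, mrf_energy
from wormlf.lightfield import shift_refocus

from conftest import make_flat_lightfield


def single_alpha_sweep():
    return w.DepthSweep(alphas=np.array([1.0]), depths=np.array([0.0]))


def make_lf(radiance, optics=None):
    radiance = np.asarray(radiance, dtype=float)
    if optics is None:
        optics = w.OpticalParams(pitch_px=float(radiance.shape[2]),
                                 mla_focal_um=10_000.0, magnification=10.0,
                                 aperture_radius_frac=1.0)
    return w.LightField4D(radiance=radiance, weights=np.ones_like(radiance),
                          optics=optics)


# ---------------------------------------------------------------------------
# independent oracles (explicit loops, no shared code with the implementation)
# ---------------------------------------------------------------------------

def oracle_defocus(img, window):
    """|5-point Laplacian| box-averaged, reflect boundaries, by explicit loops."""
    h, w_ = img.shape
    padded = np.pad(img, 1, mode="symmetric")
    lap = np.empty_like(img)
    for y in range(h):
        for x in range(w_):
            c = padded[y + 1, x + 1]
            lap[y, x] = abs(padded[y, x + 1] + padded[y + 2, x + 1]
                            + padded[y + 1, x] + padded[y + 1, x + 2] - 4 * c)
    r = window // 2
    lp = np.pad(lap, r, mode="symmetric")
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w_):
            out[y, x] = lp[y:y + window, x:x + window].mean()
    return out


def oracle_sigma(radiance, window):
    """Population angular standard deviation, box-averaged, explicit loops."""
    h, w_, nu, nv = radiance.shape
    sigma = np.empty((h, w_))
    for y in range(h):
        for x in range(w_):
            vals = radiance[y, x].ravel()
            sigma[y, x] = np.sqrt(np.mean((vals - vals.mean()) ** 2))
    if window == 1:
        return sigma
    r = window // 2
    sp = np.pad(sigma, r, mode="symmetric")
    out = np.empty((h, w_))
    for y in range(h):
        for x in range(w_):
            out[y, x] = sp[y:y + window, x:x + window].mean()
    return out


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

class TestDefocusResponse:
    def test_constant_image_zero_response(self):
        L = make_flat_lightfield(2.0, 9, 3)
        resp = w.defocus_response(L, single_alpha_sweep(), window=3, dither_px=0)
        assert np.allclose(resp.values, 0.0)

    def test_centre_impulse_matches_hand_expansion(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        L = make_lf(np.broadcast_to(img[:, :, None, None], (7, 7, 3, 3)).copy())
        resp = w.defocus_response(L, single_alpha_sweep(), window=5, dither_px=0)
        expected = oracle_defocus(img, 5)
        assert np.allclose(resp.values[:, :, 0], expected, atol=1e-12)
        # centre value: |Laplacian| has -4 at the impulse and +1 at its 4
        # neighbours; the 5x5 mean is (4 + 4*1)/25
        assert resp.values[3, 3, 0] == pytest.approx(8 / 25)

    def test_window_larger_than_image_rejected(self):
        L = make_flat_lightfield(1.0, 4, 3)
        with pytest.raises(ValueError):
            w.defocus_response(L, single_alpha_sweep(), window=5)

    def test_oracle_equivalence_on_toy_fields(self):
        rng = np.random.default_rng(11)
        optics = w.OpticalParams(pitch_px=3.0, mla_focal_um=10_000.0,
                                 magnification=10.0, aperture_radius_frac=1.0)
        L = make_lf(rng.random((9, 9, 3, 3)), optics)
        sweep = w.DepthSweep.uniform_depth(optics, -30, 30, 5)
        resp = w.defocus_response(L, sweep, window=3, dither_px=0)
        for k, a in enumerate(sweep.alphas):
            img = w.integrate_views(shift_refocus(L, float(a)))
            assert np.allclose(resp.values[:, :, k], oracle_defocus(img, 3), atol=1e-10)


class TestCorrespondenceResponse:
    def test_identical_views_zero_response(self):
        rng = np.random.default_rng(4)
        img = rng.random((8, 8))
        L = make_lf(np.broadcast_to(img[:, :, None, None], (8, 8, 3, 3)).copy())
        resp = w.correspondence_response(L, single_alpha_sweep(), window=1, dither_px=0)
        assert np.allclose(resp.values, 0.0, atol=1e-14)

    def test_toy_population_sigma(self):
        # 1x1 spatial, 2x2 angular views {0, 0, 1, 1}: population sigma = 0.5
        radiance = np.array([0.0, 0.0, 1.0, 1.0]).reshape(1, 1, 2, 2)
        L = make_lf(radiance)
        resp = w.correspondence_response(L, single_alpha_sweep(), window=1, dither_px=0)
        assert resp.values[0, 0, 0] == pytest.approx(0.5)

    def test_oracle_equivalence_on_toy_fields(self):
        rng = np.random.default_rng(12)
        optics = w.OpticalParams(pitch_px=3.0, mla_focal_um=10_000.0,
                                 magnification=10.0, aperture_radius_frac=1.0)
        L = make_lf(rng.random((9, 9, 3, 3)), optics)
        sweep = w.DepthSweep.uniform_depth(optics, -30, 30, 5)
        resp = w.correspondence_response(L, sweep, window=3, dither_px=0)
        for k, a in enumerate(sweep.alphas):
            Lr = shift_refocus(L, float(a))
            # the box average mixes in boundary pixels with partial angular
            # validity, so compare only where the whole window is fully valid
            full = Lr.weights.min(axis=(2, 3)) > 0.999
            full = ndimage.binary_erosion(full, np.ones((3, 3)))
            expected = oracle_sigma(Lr.radiance, 3)
            assert np.allclose(resp.values[full, k], expected[full], atol=1e-10)


class TestPointDepthFromCues:
    @pytest.mark.parametrize("cue", ["defocus", "correspondence"])
    def test_point_depth_within_one_sweep_step(self, optics, point_scene, cue):
        depth_um = 350.0
        _, _, truth = w.render_light_field(point_scene(depth_um), w.RenderConfig(), seed=0)
        sweep = w.DepthSweep.uniform_depth(optics, -800, 800, 41)
        resp = (w.defocus_response if cue == "defocus" else w.correspondence_response)(
            truth, sweep, 5)
        cd = w.cue_extrema(resp)
        step = np.diff(sweep.depths)[0]
        assert abs(cd.depth[13, 13] - depth_um) <= step


# ---------------------------------------------------------------------------
# extrema and confidence
# ---------------------------------------------------------------------------

class TestCueExtrema:
    def _resp(self, profile, cue="defocus"):
        vals = np.asarray(profile, dtype=float).reshape(1, 1, -1)
        sweep = w.DepthSweep(alphas=np.linspace(0.9, 1.1, vals.shape[-1]),
                             depths=np.linspace(-10, 10, vals.shape[-1]))
        return w.ResponseVolume(vals, sweep, cue, 5)

    def test_single_peak_confidence_capped(self):
        cd = w.cue_extrema(self._resp([0, 1, 5, 1, 0]), cap=10.0)
        assert cd.label[0, 0] == 2 and cd.confidence[0, 0] == 10.0

    def test_two_peak_profile_ratio(self):
        cd = w.cue_extrema(self._resp([1, 3, 1, 2, 1]))
        assert cd.label[0, 0] == 1
        assert cd.confidence[0, 0] == pytest.approx(1.5)

    def test_flat_profile_unreliable(self):
        cd = w.cue_extrema(self._resp([2, 2, 2, 2, 2]))
        assert cd.confidence[0, 0] == 1.0 and not cd.reliable[0, 0]

    def test_correspondence_inverted_ratio(self):
        cd = w.cue_extrema(self._resp([5, 2, 5, 3, 5], cue="correspondence"))
        assert cd.label[0, 0] == 1
        assert cd.confidence[0, 0] == pytest.approx(1.5)

    def test_short_sweep_rejected(self):
        with pytest.raises(ValueError):
            w.cue_extrema(self._resp([1, 2]))


# ---------------------------------------------------------------------------
# MRF fusion
# ---------------------------------------------------------------------------

def brute_force_mrf(data_cost, lam, tau):
    """Exhaustive minimization over all labelings (tiny instances only)."""
    H, W, K = data_cost.shape
    best_e, best = np.inf, None
    for assign in itertools.product(range(K), repeat=H * W):
        lab = np.array(assign).reshape(H, W)
        e = mrf_energy(lab, data_cost, lam, tau)
        if e < best_e:
            best_e, best = e, lab
    return best_e, best


def make_cue(labels, conf, sweep):
    labels = np.asarray(labels)
    conf = np.asarray(conf, dtype=float)
    return w.CueDepth(alpha_star=sweep.alphas[labels], depth=sweep.depths[labels],
                      confidence=conf, label=labels,
                      reliable=np.ones_like(conf, dtype=bool), sweep=sweep)


class TestCombineDepth:
    def setup_method(self):
        self.sweep = w.DepthSweep(alphas=np.linspace(0.9, 1.1, 4),
                                  depths=np.linspace(-30, 30, 4))

    def test_consensus_independent_of_lambda(self):
        labels = np.full((3, 3), 2)
        conf = np.full((3, 3), 5.0)
        dd = make_cue(labels, conf, self.sweep)
        dc = make_cue(labels, conf, self.sweep)
        for lam in (0.0, 0.5, 5.0):
            dm = w.combine_depth(dd, dc, footprint=np.ones((3, 3), bool),
                                 params=DepthParams(smoothness=lam))
            assert np.allclose(dm.depth, self.sweep.depths[2])

    def test_degenerate_weights_follow_single_cue(self):
        rng = np.random.default_rng(0)
        lab_d = rng.integers(0, 4, (2, 3))
        dd = make_cue(lab_d, np.full((2, 3), 10.0), self.sweep)
        dc_conf = np.ones((2, 3))
        dc = w.CueDepth(alpha_star=self.sweep.alphas[lab_d * 0],
                        depth=self.sweep.depths[lab_d * 0], confidence=dc_conf,
                        label=lab_d * 0, reliable=np.zeros((2, 3), bool),
                        sweep=self.sweep)
        dm = w.combine_depth(dd, dc, footprint=np.ones((2, 3), bool),
                             params=DepthParams(smoothness=0.0))
        assert np.array_equal(dm.depth, self.sweep.depths[lab_d])

    def test_outlier_strip_matches_exhaustive_optimum(self):
        # 1x5 strip, 3 labels, one low-confidence outlier pixel
        sweep = w.DepthSweep(alphas=np.linspace(0.95, 1.05, 3),
                             depths=np.linspace(-20, 20, 3))
        lab_d = np.array([[0, 0, 2, 0, 0]])
        lab_c = np.array([[0, 0, 0, 0, 0]])
        conf_d = np.array([[5.0, 5.0, 1.2, 5.0, 5.0]])
        conf_c = np.array([[4.0, 4.0, 1.0, 4.0, 4.0]])
        dd = make_cue(lab_d, conf_d, sweep)
        dc = make_cue(lab_c, conf_c, sweep)
        params = DepthParams(smoothness=0.5, truncation=10.0)
        dm = w.combine_depth(dd, dc, footprint=np.ones((1, 5), bool), params=params)
        cap = params.confidence_cap
        data_cost = ((conf_d / cap)[..., None] * np.abs(np.arange(3) - lab_d[..., None])
                     + (conf_c / cap)[..., None] * np.abs(np.arange(3) - lab_c[..., None]))
        best_e, best_lab = brute_force_mrf(data_cost, 0.5, 10.0)
        assert np.array_equal(dm.depth, sweep.depths[best_lab])

    @pytest.mark.parametrize("solver", ["dp"])
    @pytest.mark.parametrize("shape", [(1, 6), (2, 3), (3, 2), (2, 2)])
    def test_solver_reaches_exhaustive_energy(self, solver, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        K = 4
        sweep = w.DepthSweep(alphas=np.linspace(0.9, 1.1, K),
                             depths=np.linspace(-30, 30, K))
        for trial in range(6):
            lab_d = rng.integers(0, K, shape)
            lab_c = rng.integers(0, K, shape)
            conf_d = rng.uniform(1, 10, shape)
            conf_c = rng.uniform(1, 10, shape)
            dd = make_cue(lab_d, conf_d, sweep)
            dc = make_cue(lab_c, conf_c, sweep)
            params = DepthParams(smoothness=rng.uniform(0.1, 1.0),
                                 truncation=rng.choice([2.0, 10.0]), solver=solver)
            dm = w.combine_depth(dd, dc, footprint=np.ones(shape, bool), params=params)
            labels = np.searchsorted(sweep.depths, dm.depth.ravel()).reshape(shape)
            cap = params.confidence_cap
            data_cost = ((conf_d / cap)[..., None] * np.abs(np.arange(K) - lab_d[..., None])
                         + (conf_c / cap)[..., None] * np.abs(np.arange(K) - lab_c[..., None]))
            e_solver = mrf_energy(labels, data_cost, params.smoothness, params.truncation)
            e_best, _ = brute_force_mrf(data_cost, params.smoothness, params.truncation)
            assert e_solver == pytest.approx(e_best, abs=1e-9), (solver, shape, trial)

    def test_icm_consensus_and_no_worse_than_data_only(self):
        rng = np.random.default_rng(2)
        labels = np.full((3, 3), 1)
        dd = make_cue(labels, np.full((3, 3), 8.0), self.sweep)
        dm = w.combine_depth(dd, dd, footprint=np.ones((3, 3), bool),
                             params=DepthParams(solver="icm", smoothness=0.7))
        assert np.allclose(dm.depth, self.sweep.depths[1])

    def test_empty_footprint_rejected(self):
        dd = make_cue(np.zeros((2, 2), int), np.ones((2, 2)), self.sweep)
        with pytest.raises(ValueError):
            w.combine_depth(dd, dd, footprint=np.zeros((2, 2), bool))


# ---------------------------------------------------------------------------
# end-to-end estimate_depth
# ---------------------------------------------------------------------------

class TestEstimateDepth:
    def test_flat_field_unreliable(self):
        L = make_flat_lightfield(1.0, 16, 5)
        sweep = w.DepthSweep.uniform_depth(L.optics, -100, 100, 9)
        dm = w.estimate_depth(L, sweep)
        assert np.all(dm.confidence <= 1.0 + 1e-9)

    def test_tilted_plane_phantom_rms(self, optics):
        # a rod tilted through +/-300 um: per-pixel depth error small
        grid = w.SceneGrid(shape=(26, 26), spacing_um=optics.sample_spacing_um)
        ys, xs = grid.coords()
        skel = np.array([[xs[4], ys[13], -300.0], [xs[-5], ys[13], 300.0]])
        scene = w.render_worm_scene(skel, 40.0, grid, seed=2, texture_strength=0.8,
                                    texture_scale_px=1.0)
        raw, bg, truth = w.render_light_field(scene, w.RenderConfig(), seed=2)
        # step commensurate with the ~0.1 px sub-pixel matching precision
        sweep = w.DepthSweep.uniform_depth(optics, -400, 400, 41)
        dm = w.estimate_depth(truth, sweep, footprint=scene.footprint)
        err = dm.depth[scene.footprint] - scene.depth[scene.footprint]
        step = np.diff(sweep.depths)[0]
        assert np.sqrt(np.mean(err**2)) < 2 * step

    def test_monotone_with_true_depth(self, optics):
        grid = w.SceneGrid(shape=(26, 26), spacing_um=optics.sample_spacing_um)
        cfg = w.RenderConfig()
        sweep = w.DepthSweep.uniform_depth(optics, -900, 900, 65)
        medians = []
        for z in [-700, -350, 0, 350, 700]:
            scene = w.rod_scene(grid, z, seed=4)
            _, _, truth = w.render_light_field(scene, cfg, seed=4)
            dm = w.estimate_depth(truth, sweep, footprint=scene.footprint)
            medians.append(np.median(dm.depth[scene.footprint]))
        assert np.all(np.diff(medians) > 0)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestCalibrateDepthScale:
    def test_identity(self):
        known = np.linspace(-500, 500, 11)
        res = w.calibrate_depth_scale(known, known)
        assert res.gradient == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)

    def test_instrument_like_gradient(self):
        known = np.linspace(-1000, 1000, 21)
        res = w.calibrate_depth_scale(0.883 * known, known)
        assert res.gradient == pytest.approx(0.883)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)

    def test_hand_ols(self):
        res = w.calibrate_depth_scale([-95.0, 5.0, 105.0], [-100.0, 0.0, 100.0])
        assert res.gradient == pytest.approx(1.0)
        assert res.intercept == pytest.approx(5.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            w.calibrate_depth_scale([1.0, 2.0], [1.0, 2.0])

    def test_reciprocal_gradient_applied(self, optics):
        # calibration_gradient divides the fused depth
        L = make_flat_lightfield(1.0, 16, 5)
        rng = np.random.default_rng(0)
        L.radiance += rng.normal(0, 0.1, L.radiance.shape) ** 2
        sweep = w.DepthSweep.uniform_depth(L.optics, -100, 100, 9)
        dm1 = w.estimate_depth(L, sweep)
        dm2 = w.estimate_depth(L, sweep,
                               params=DepthParams(calibration_gradient=0.5))
        assert np.allclose(dm2.depth, dm1.depth / 0.5, equal_nan=True)
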