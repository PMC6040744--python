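"""Ground-truthed synthetic phantoms for the whole pipeline.

Three levels of synthesis, each reproducible from a seed:

1. :func:`generate_locomotion` — 3D undulatory worm locomotion (traveling
   bending wave whose oscillation plane rolls slowly about the body axis),
   returning skeletons with exact angle-vector ground truth.
2. :func:`render_worm_scene` — a tube-shaped body swept along a midline,
   giving the true lateral footprint, a contrast-weighted depth map and a
   textured intensity image on the spatial sample grid.
3. :func:`render_light_field` — a raw tiled-subimage mosaic whose per-view
   parallax is exactly the shear-disparity model the reconstruction assumes
   (the renderer is the adjoint of the refocus operator), plus optional
   vignetting and Gaussian read noise.

The disparity model is shared with the reconstruction by design: pipeline
validation is then exact rather than approximate, and realism knobs (noise,
vignette, blur) are separate, optional degradations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .lightfield import (
    LightField4D,
    OpticalParams,
    aperture_mask,
    depth_to_shear,
)

NOMINAL_OPTICS = OpticalParams(
    pitch_px=19.0, mla_focal_um=10_000.0, magnification=10.0,
    pixel_size_um=6.5, frame_rate_hz=20.0,
)
"""Nominal synthetic optics: pitch 19 px, M = 10, with F chosen so the
reachable refocus band P*F/M**2 = 1.9 mm comfortably covers +/- 1 mm."""


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocomotionParams:
    """Parameters of the synthetic 3D undulatory locomotion model.

    The body bends with a traveling wave
    ``beta(s, t) = amplitude * sin(2*pi*s/wavelength - 2*pi*f*t)`` and the
    plane of oscillation rolls about the body axis once every ``roll_ratio``
    undulation cycles (phase-locked, so the eigenmode amplitudes follow a
    rhodonea curve with k = roll_ratio).
    """

    body_length_um: float = 1000.0
    n_segments: int = 25
    amplitude_rad: float = 0.6
    wavelength_bl: float = 1.5
    frequency_hz: float = 0.5
    roll_ratio: float = 8.5
    speed_um_s: float = 50.0
    angle_noise_rad: float = 0.05
    frame_rate_hz: float = 20.0
    phase0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")
        for name in ("body_length_um", "wavelength_bl", "frequency_hz",
                     "frame_rate_hz", "roll_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.amplitude_rad < 0 or self.angle_noise_rad < 0:
            raise ValueError("amplitudes must be nonnegative")


@dataclass
class Locomotion:
    """Synthetic locomotion sequence with exact ground truth."""

    times: np.ndarray                 # (T,) seconds
    skeletons: np.ndarray             # (T, n_segments + 1, 3) um
    theta: np.ndarray                 # (T, n_segments) mean-zeroed azimuth
    phi: np.ndarray                   # (T, n_segments) mean-zeroed elevation
    params: LocomotionParams


def generate_locomotion(params: LocomotionParams, n_frames: int) -> Locomotion:
    """Generate a seeded 3D locomotion sequence.

    Tangent angles are integrated into coordinates with fixed segment
    lengths, so body length is conserved exactly; the centroid advances
    along +x at the translation speed.
    """
    rng = np.random.default_rng(params.seed)
    nseg = params.n_segments
    seg_len = params.body_length_um / nseg
    s_mid = (np.arange(nseg) + 0.5) / nseg          # body coordinate of segment centres
    times = np.arange(n_frames) / params.frame_rate_hz

    skeletons = np.empty((n_frames, nseg + 1, 3))
    thetas = np.empty((n_frames, nseg))
    phis = np.empty((n_frames, nseg))
    omega = 2 * np.pi * params.frequency_hz
    for k, t in enumerate(times):
        bend = params.amplitude_rad * np.sin(
            2 * np.pi * s_mid / params.wavelength_bl - omega * t + params.phase0)
        if np.isfinite(params.roll_ratio):
            psi = (omega * t + params.phase0) / params.roll_ratio
        else:
            psi = 0.0
        theta = bend * np.cos(psi)
        phi = bend * np.sin(psi)
        if params.angle_noise_rad > 0:
            theta = theta + rng.normal(0, params.angle_noise_rad, nseg)
            phi = phi + rng.normal(0, params.angle_noise_rad, nseg)
        tangents = np.stack([
            np.cos(phi) * np.cos(theta),
            np.cos(phi) * np.sin(theta),
            np.sin(phi),
        ], axis=1)
        pts = np.zeros((nseg + 1, 3))
        pts[1:] = np.cumsum(seg_len * tangents, axis=0)
        pts -= pts.mean(axis=0)
        pts[:, 0] += params.speed_um_s * t
        skeletons[k] = pts
        thetas[k] = theta - theta.mean()
        phis[k] = phi - phi.mean()
    return Locomotion(times=times, skeletons=skeletons, theta=thetas,
                      phi=phis, params=params)


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneGrid:
    """Spatial sample grid (one sample per microlens) in object space."""

    shape: tuple[int, int]
    spacing_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        ys = self.origin_um[0] + np.arange(self.shape[0]) * self.spacing_um
        xs = self.origin_um[1] + np.arange(self.shape[1]) * self.spacing_um
        return ys, xs


@dataclass
class SceneTruth:
    """Rendered scene with ground truth on the spatial sample grid."""

    image: np.ndarray        # intensity, background level 1.0
    footprint: np.ndarray    # bool body footprint
    depth: np.ndarray        # um, NaN outside footprint
    midline_um: np.ndarray   # (n, 3) dense midline used for rendering
    grid: SceneGrid
    background: float = 1.0


def render_worm_scene(skeleton_um: np.ndarray, radius_um, grid: SceneGrid, *,
                      contrast: float = 0.7, texture_strength: float = 0.5,
                      texture_scale_px: float = 1.5, seed: int = 0,
                      n_dense: int = 400) -> SceneTruth:
    """Render a tube-shaped worm body swept along a 3D midline.

    The footprint is the lateral (z) projection of the union of spheres along
    the midline; the per-pixel depth is the z of the nearest midline point,
    matching the instrument's behaviour of reporting a contrast-weighted
    average over the body thickness (the tube centre dominates).  The
    intensity image darkens with chord thickness and carries a smooth
    multiplicative texture so that defocus/correspondence cues are
    informative across the body, as DIC contrast is on a real worm.
    """
    skeleton_um = np.asarray(skeleton_um, dtype=float)
    if skeleton_um.ndim != 2 or skeleton_um.shape[1] != 3:
        raise ValueError("skeleton must be (n, 3)")
    # dense resample of the midline (chord-length parameterized)
    seglen = np.linalg.norm(np.diff(skeleton_um, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seglen)])
    if u[-1] <= 0:
        raise ValueError("degenerate midline")
    ud = np.linspace(0, u[-1], n_dense)
    dense = np.stack([np.interp(ud, u, skeleton_um[:, k]) for k in range(3)], axis=1)
    radius = np.atleast_1d(np.asarray(radius_um, dtype=float))
    if radius.size == 1:
        r_dense = np.full(n_dense, float(radius[0]))
    else:
        sr = np.linspace(0, u[-1], radius.size)
        r_dense = np.interp(ud, sr, radius)

    ys, xs = grid.coords()
    if (dense[:, 0].min() < xs[0] or dense[:, 0].max() > xs[-1]
            or dense[:, 1].min() < ys[0] or dense[:, 1].max() > ys[-1]):
        raise ValueError("worm midline extends outside the scene grid")
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    tree = cKDTree(dense[:, [1, 0]])   # lateral (y, x) positions
    pts = np.stack([gy.ravel(), gx.ravel()], axis=1)
    dist, idx = tree.query(pts)
    # refine to exact point-to-segment distance on the two segments adjacent
    # to the nearest sample, so the footprint boundary is not eroded by the
    # discrete midline sampling
    for lo in (np.maximum(idx - 1, 0), idx):
        hi = np.minimum(lo + 1, n_dense - 1)
        a = dense[lo][:, [1, 0]]
        b = dense[hi][:, [1, 0]]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        tproj = np.where(denom > 0,
                         np.einsum("ij,ij->i", pts - a, ab) / np.where(denom > 0, denom, 1.0),
                         0.0)
        tproj = np.clip(tproj, 0.0, 1.0)
        closest = a + tproj[:, None] * ab
        dist = np.minimum(dist, np.linalg.norm(pts - closest, axis=1))
    dist = dist.reshape(grid.shape)
    idx = idx.reshape(grid.shape)
    r_local = r_dense[idx]
    footprint = dist <= r_local
    depth = np.full(grid.shape, np.nan)
    depth[footprint] = dense[idx[footprint], 2]
    # chord thickness through the tube, normalized; the square root steepens
    # the edge profile, as refraction at the cuticle does under DIC contrast
    chord = np.zeros(grid.shape)
    chord[footprint] = np.sqrt(np.maximum(r_local[footprint] ** 2
                                          - dist[footprint] ** 2, 0.0))
    if chord.max() > 0:
        chord = np.sqrt(chord / chord.max())
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.standard_normal(grid.shape), texture_scale_px)
    if tex.std() > 0:
        tex = tex / tex.std()
    modulation = 1.0 + texture_strength * 0.5 * tex
    image = np.ones(grid.shape)
    image[footprint] = 1.0 - contrast * chord[footprint] * np.clip(
        modulation[footprint], 0.2, 1.8)
    image = np.clip(image, 0.0, None)
    return SceneTruth(image=image, footprint=footprint, depth=depth,
                      midline_um=dense, grid=grid)


# ---------------------------------------------------------------------------
# light field rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    """Raw-mosaic rendering configuration.

    ``noise_sigma`` is Gaussian read noise in units of the background level;
    ``vignette_strength`` in (0, 1] sets how strongly radiance falls off
    towards the subimage edge (cos^4-like profile).
    """

    optics: OpticalParams = NOMINAL_OPTICS
    vignette_strength: float = 0.5
    noise_sigma: float = 0.0
    n_depth_layers: int = 128
    blur_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.vignette_strength <= 1:
            raise ValueError("vignette_strength must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def vignette_profile(n_u: int, n_v: int, pitch: float, strength: float,
                     aperture_radius_frac: float = 0.95) -> np.ndarray:
    """Per-subimage radial attenuation profile (cos^4-like), 0 off-aperture."""
    u = np.arange(n_u) - (n_u - 1) / 2
    v = np.arange(n_v) - (n_v - 1) / 2
    r = np.hypot(u[:, None], v[None, :]) / (pitch / 2.0)
    prof = np.cos(np.clip(r, 0, 1) * np.pi / 2) ** 4
    prof = (1.0 - strength) + strength * prof
    prof[~aperture_mask(n_u, n_v, aperture_radius_frac, pitch)] = 0.0
    return prof


def _tile_mosaic(views: np.ndarray) -> np.ndarray:
    """(n_x, n_y, n_u, n_v) view array -> raw mosaic (n_x*n_u, n_y*n_v)."""
    nx, ny, nu, nv = views.shape
    return views.transpose(0, 2, 1, 3).reshape(nx * nu, ny * nv)


def render_light_field(scene: SceneTruth, cfg: RenderConfig, *, seed: int = 0):
    """Render a raw mosaic (and truth 4D field) from a scene.

    For each valid view (u, v), scene content at depth dz is shifted
    laterally by ``(1 - 1/alpha(dz)) * (u, v)`` spatial samples, where alpha
    inverts the shear/depth relation — exactly the adjoint of the refocus
    operator.  Depth is quantized into layers for warping; vignetting is
    applied per subimage and Gaussian read noise added from the seed.

    Returns
    -------
    raw : ndarray
        Tiled mosaic, background level ``scene.background`` times vignette.
    background : ndarray
        Matching flat-field mosaic for vignetting correction.
    truth : LightField4D
        Noise- and vignette-free 4D light field.
    """
    optics = cfg.optics
    n = int(round(optics.pitch_px))
    nx, ny = scene.grid.shape
    depths = scene.depth[scene.footprint]
    if depths.size and (np.nanmax(np.abs(depths)) >= optics.max_depth_um):
        raise ValueError("scene depth outside the reachable refocus range")

    # depth layers
    if depths.size:
        zmin, zmax = float(np.nanmin(depths)), float(np.nanmax(depths))
    else:
        zmin = zmax = 0.0
    if zmax - zmin < 1e-9:
        edges = np.array([zmin - 0.5, zmin + 0.5])
        centers = np.array([zmin])
    else:
        n_layers = min(cfg.n_depth_layers, max(1, int(np.ceil((zmax - zmin) / 1.0)) + 1))
        edges = np.linspace(zmin, zmax, n_layers + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        edges[0] -= 1e-6
        edges[-1] += 1e-6

    bg = scene.background
    delta = np.where(scene.footprint, scene.image - bg, 0.0)

    layer_imgs = []
    layer_shift = []
    for lo, hi, zc in zip(edges[:-1], edges[1:], centers):
        sel = scene.footprint & (scene.depth > lo) & (scene.depth <= hi)
        if not np.any(sel):
            continue
        layer_imgs.append(np.where(sel, delta, 0.0))
        alpha = depth_to_shear(zc, optics)
        layer_shift.append(1.0 - 1.0 / alpha)

    u = np.arange(n) - (n - 1) / 2
    views = np.empty((nx, ny, n, n))
    for iu, uu in enumerate(u):
        for iv, vv in enumerate(u):
            img = np.full((nx, ny), bg)
            for limg, sh in zip(layer_imgs, layer_shift):
                img += ndimage.shift(limg, (sh * uu, sh * vv), order=3,
                                     mode="constant", cval=0.0)
            views[:, :, iu, iv] = img
    # adjacent depth layers can overlap after warping; radiance stays physical
    views = np.clip(views, 0.0, None)
    if cfg.blur_sigma_px > 0:
        views = ndimage.gaussian_filter(views, (cfg.blur_sigma_px, cfg.blur_sigma_px, 0, 0))

    ap = aperture_mask(n, n, optics.aperture_radius_frac, optics.pitch_px)
    truth = LightField4D(radiance=np.where(ap[None, None], views, 0.0),
                         weights=np.broadcast_to(ap[None, None], views.shape).astype(float).copy(),
                         optics=optics)

    vig = vignette_profile(n, n, optics.pitch_px, cfg.vignette_strength,
                           optics.aperture_radius_frac)
    raw = _tile_mosaic(views * vig[None, None])
    background = _tile_mosaic(np.broadcast_to(bg * vig[None, None], views.shape).copy())
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0.0, cfg.noise_sigma * bg, raw.shape)
        raw = np.clip(raw, 0.0, None)
    return raw, background, truth


# ---------------------------------------------------------------------------
# calibration series
# ---------------------------------------------------------------------------

def rod_scene(grid: SceneGrid, depth_um: float, *, radius_um: float = 40.0,
              length_frac: float = 0.55, seed: int = 0,
              texture_strength: float = 0.8) -> SceneTruth:
    """A straight textured rod phantom at a uniform depth, centred in grid."""
    ys, xs = grid.coords()
    cx = 0.5 * (xs[0] + xs[-1])
    cy = 0.5 * (ys[0] + ys[-1])
    half = 0.5 * length_frac * (xs[-1] - xs[0])
    skel = np.array([[cx - half, cy, depth_um], [cx + half, cy, depth_um]])
    return render_worm_scene(skel, radius_um, grid, seed=seed,
                             texture_strength=texture_strength)


def calibration_series(cfg: RenderConfig, depths_um, *, grid: SceneGrid | None = None,
                       seed: int = 0, radius_um: float = 40.0):
    """Static rod phantom rendered at each listed axial offset.

    Emulates capturing a paralysed specimen while the focusing stage is
    displaced by known amounts.  Returns a list of
    ``(raw, background, scene_truth)`` tuples, reproducible from the seed.
    """
    if grid is None:
        nx = 26
        grid = SceneGrid(shape=(nx, nx), spacing_um=cfg.optics.sample_spacing_um)
    out = []
    for k, z in enumerate(depths_um):
        scene = rod_scene(grid, float(z), radius_um=radius_um, seed=seed)
        raw, bgim, _ = render_light_field(scene, cfg, seed=seed + 1000 + k)
        out.append((raw, bgim, scene))
    return out
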