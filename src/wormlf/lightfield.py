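"""Rectification, refocusing and the shear<->depth mapping for light field micrographs.

A raw light field micrograph is a mosaic of circular microlens subimages.
Rectifying it onto an axis-aligned lattice yields a 4D radiance array
``L(x, y, u, v)`` where ``(x, y)`` index microlenses (spatial samples) and
``(u, v)`` index pixels within a subimage (angular samples, centred so that
``(0, 0)`` is the chief ray).  Computational refocusing shears this array
parallel to the spatial plane:

    L_alpha(x, y, u, v) = L(u (1 - 1/alpha) + x/alpha,
                            v (1 - 1/alpha) + y/alpha, u, v)

and the shear parameter relates to axial position in the sample through

    dz = P (1 - 1/alpha) F / M**2

with P the subimage pitch in camera pixels, F the microlens focal length and
M the transverse magnification of the microscope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalParams:
    """Optical configuration of the light field microscope.

    Parameters
    ----------
    pitch_px : float
        Microlens subimage pitch in camera pixels (P).
    mla_focal_um : float
        Microlens array focal length F in micrometres.
    magnification : float
        Transverse magnification M of the microscope (dimensionless).
    pixel_size_um : float
        Camera pixel size in micrometres.
    frame_rate_hz : float
        Acquisition frame rate.
    aperture_radius_frac : float
        Fraction of P/2 defining the circular angular aperture; subimage
        pixels outside it receive no light in the real instrument.
    """

    pitch_px: float
    mla_focal_um: float
    magnification: float
    pixel_size_um: float = 6.5
    frame_rate_hz: float = 20.0
    aperture_radius_frac: float = 0.95

    def __post_init__(self) -> None:
        if not self.pitch_px > 1:
            raise ValueError("pitch_px must be > 1")
        if not self.mla_focal_um > 0:
            raise ValueError("mla_focal_um must be > 0")
        if not self.magnification > 0:
            raise ValueError("magnification must be > 0")
        if not 0 < self.aperture_radius_frac <= 1:
            raise ValueError("aperture_radius_frac must be in (0, 1]")

    @property
    def max_depth_um(self) -> float:
        """Supremum P*F/M**2 of reachable refocus depths (alpha -> inf)."""
        return self.pitch_px * self.mla_focal_um / self.magnification**2

    @property
    def sample_spacing_um(self) -> float:
        """Object-space spacing of spatial (microlens) samples."""
        return self.pitch_px * self.pixel_size_um / self.magnification


@dataclass(frozen=True)
class LatticeParams:
    """Geometry of the microlens subimage lattice on the sensor.

    ``offset`` is the pixel position (row, col) of one subimage centre.
    """

    pitch: float
    orientation: float
    offset: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.pitch > 1:
            raise ValueError("lattice pitch must be > 1")
        if not abs(self.orientation) < np.pi / 4:
            raise ValueError("lattice orientation must satisfy |rot| < pi/4")


@dataclass
class LightField4D:
    """4D radiance array with per-sample validity weights.

    ``radiance`` has shape ``(n_x, n_y, n_u, n_v)``; ``weights`` (same shape,
    values in [0, 1]) mark valid angular samples — the circular aperture and,
    after shearing, samples that stayed inside the spatial field.
    """

    radiance: np.ndarray
    weights: np.ndarray
    optics: OpticalParams

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.radiance.ndim != 4:
            raise ValueError("radiance must be 4D (x, y, u, v)")
        if self.radiance.shape != self.weights.shape:
            raise ValueError("radiance/weights shape mismatch")
        if np.any(self.radiance[self.weights > 0] < 0):
            raise ValueError("radiance must be nonnegative on valid samples")

    @property
    def n_x(self) -> int:
        return self.radiance.shape[0]

    @property
    def n_y(self) -> int:
        return self.radiance.shape[1]

    @property
    def n_u(self) -> int:
        return self.radiance.shape[2]

    @property
    def n_v(self) -> int:
        return self.radiance.shape[3]

    @property
    def u_coords(self) -> np.ndarray:
        """Centred angular coordinates along u (0 at the chief ray)."""
        return np.arange(self.n_u) - (self.n_u - 1) / 2

    @property
    def v_coords(self) -> np.ndarray:
        return np.arange(self.n_v) - (self.n_v - 1) / 2

    def copy(self) -> "LightField4D":
        return LightField4D(self.radiance.copy(), self.weights.copy(), self.optics)


def aperture_mask(n_u: int, n_v: int, aperture_radius_frac: float, pitch: float) -> np.ndarray:
    """Boolean mask of angular samples inside the inscribed circular aperture."""
    u = np.arange(n_u) - (n_u - 1) / 2
    v = np.arange(n_v) - (n_v - 1) / 2
    r2 = u[:, None] ** 2 + v[None, :] ** 2
    radius = aperture_radius_frac * pitch / 2.0
    return r2 <= radius**2


@dataclass(frozen=True)
class DepthSweep:
    """Ordered shear parameters with their Eq-1 depths (micrometres)."""

    alphas: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        alphas = np.asarray(self.alphas, dtype=float)
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "depths", depths)
        if alphas.size != depths.size or alphas.size == 0:
            raise ValueError("alphas and depths must be nonempty and equal length")
        if np.any(alphas <= 0):
            raise ValueError("all alphas must be positive")
        d = np.diff(depths)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("sweep must be strictly monotone in depth")

    def __len__(self) -> int:
        return int(self.alphas.size)

    @classmethod
    def uniform_depth(cls, optics: OpticalParams, z_min_um: float, z_max_um: float,
                      n: int = 256) -> "DepthSweep":
        """Sweep with uniformly spaced depths (default resolution 256)."""
        depths = np.linspace(z_min_um, z_max_um, n)
        alphas = np.array([depth_to_shear(z, optics) for z in depths])
        return cls(alphas=alphas, depths=depths)


# ---------------------------------------------------------------------------
# shear <-> depth
# ---------------------------------------------------------------------------

def shear_to_depth(alpha: float, optics: OpticalParams) -> float:
    """Axial offset dz (um) simulated by refocusing with shear ``alpha``."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    P, F, M = optics.pitch_px, optics.mla_focal_um, optics.magnification
    return P * (1.0 - 1.0 / alpha) * F / M**2


def depth_to_shear(dz_um: float, optics: OpticalParams) -> float:
    """Inverse of :func:`shear_to_depth`; defined for dz < P*F/M**2."""
    zf = optics.max_depth_um
    if dz_um >= zf:
        raise ValueError(f"depth {dz_um} um is unreachable (limit {zf} um)")
    return 1.0 / (1.0 - dz_um / zf)


# ---------------------------------------------------------------------------
# vignetting
# ---------------------------------------------------------------------------

def correct_vignetting(raw: np.ndarray, background: np.ndarray, *,
                       floor: float = 1e-6, return_mask: bool = False):
    """Flat-field (vignetting) correction by elementwise division.

    Off-axis rays are attenuated by the microlens apertures; dividing by a
    background exposure captured under identical illumination removes the
    radial fall-off.  Pixels where the background is below ``floor`` (relative
    to its maximum) are set to 0 and flagged.
    """
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if raw.shape != background.shape:
        raise ValueError("raw and background must have the same shape")
    peak = background.max() if background.size else 0.0
    if peak <= 0:
        raise ValueError("background is all-zero")
    bad = background < floor * peak
    out = np.zeros_like(raw)
    np.divide(raw, background, out=out, where=~bad)
    out[bad] = 0.0
    if return_mask:
        return out, bad
    return out


# ---------------------------------------------------------------------------
# lattice estimation
# ---------------------------------------------------------------------------

def _fft_lattice_guess(raw: np.ndarray) -> tuple[float, float]:
    """Initial (pitch, orientation) from the dominant Fourier lattice peak."""
    img = raw - raw.mean()
    win0 = np.hanning(img.shape[0])[:, None]
    win1 = np.hanning(img.shape[1])[None, :]
    spec = np.abs(np.fft.fftshift(np.fft.fft2(img * win0 * win1)))
    fy = np.fft.fftshift(np.fft.fftfreq(img.shape[0]))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(img.shape[1]))[None, :]
    fr = np.hypot(fy, fx)
    # plausible band: pitch between 4 px and a tenth of the image
    band = (fr > 10.0 / min(img.shape)) & (fr >= 1.0 / (min(img.shape) / 10)) & (fr <= 1.0 / 4.0)
    if not np.any(band):
        raise ValueError("no microlens lattice detected")
    masked = np.where(band, spec, 0.0)
    iy, ix = np.unravel_index(np.argmax(masked), masked.shape)
    # a genuine lattice peak is a sharp isolated maximum on its frequency
    # ring; smooth image content gives ring ratios of only a few
    dr = 1.5 / min(img.shape)
    ring = band & (np.abs(fr - fr[iy, ix]) < dr)
    noise = np.median(spec[ring])
    if masked[iy, ix] < 30.0 * max(noise, 1e-30):
        raise ValueError("no microlens lattice detected")

    # sub-bin refinement by quadratic interpolation along each frequency axis
    def _subpix(v_m1, v_0, v_p1):
        den = v_m1 - 2 * v_0 + v_p1
        return 0.0 if den == 0 else 0.5 * (v_m1 - v_p1) / den

    dy = _subpix(masked[iy - 1, ix], masked[iy, ix], masked[iy + 1, ix])
    dx = _subpix(masked[iy, ix - 1], masked[iy, ix], masked[iy, ix + 1])
    f_y = fy[iy, 0] + dy * (fy[1, 0] - fy[0, 0])
    f_x = fx[0, ix] + dx * (fx[0, 1] - fx[0, 0])
    pitch = 1.0 / np.hypot(f_y, f_x)
    orientation = np.arctan2(f_y, f_x)
    # fold onto the fundamental axis of the square lattice, |rot| < pi/4
    orientation = (orientation + np.pi / 4) % (np.pi / 2) - np.pi / 4
    return float(pitch), float(orientation)


def _disc_tile_correlation(raw_norm: np.ndarray, pitch: float, orientation: float,
                           offset: tuple[float, float]) -> float:
    """Mean normalized intensity sampled at disc-shaped subimage templates.

    Equivalent (up to a constant) to the 2D cross-correlation between the
    image and a binary mask of tiled discs evaluated at these lattice
    parameters; higher is better.
    """
    h, w = raw_norm.shape
    c, s = np.cos(orientation), np.sin(orientation)
    n0 = int(np.ceil(np.hypot(h, w) / pitch)) + 1
    idx = np.arange(-n0, n0 + 1)
    gi, gj = np.meshgrid(idx, idx, indexing="ij")
    cy = offset[0] + pitch * (c * gi - s * gj)
    cx = offset[1] + pitch * (s * gi + c * gj)
    keep = (cy > pitch) & (cy < h - pitch) & (cx > pitch) & (cx < w - pitch)
    cy, cx = cy[keep], cx[keep]
    if cy.size < 9:
        return -np.inf
    ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    r_in = pitch * 0.2
    # disc samples (centre + ring) minus tile-corner samples: the vignetted
    # corners of every subimage are dark regardless of scene content, so the
    # contrast peaks exactly when the template lands on the lattice
    off_in_y = np.concatenate([[0.0], r_in * np.sin(ang)])
    off_in_x = np.concatenate([[0.0], r_in * np.cos(ang)])
    corner = pitch * 0.45
    off_out_y = corner * np.array([1.0, 1.0, -1.0, -1.0])
    off_out_x = corner * np.array([1.0, -1.0, 1.0, -1.0])

    def _sample(off_y, off_x):
        ys = cy[:, None] + (c * off_y - s * off_x)[None, :]
        xs = cx[:, None] + (s * off_y + c * off_x)[None, :]
        return ndimage.map_coordinates(raw_norm, [ys.ravel(), xs.ravel()], order=1)

    return float(_sample(off_in_y, off_in_x).mean() - _sample(off_out_y, off_out_x).mean())


def estimate_lattice(raw: np.ndarray) -> LatticeParams:
    """Estimate the subimage lattice of a raw mosaic.

    The pitch and orientation come from the prominent peaks of the 2D Fourier
    transform; offset, pitch and orientation are then fine-tuned by maximizing
    the cross-correlation between a binary disc-tile mask and the normalized
    image (coarse offset scan followed by Nelder–Mead refinement).
    """
    raw = np.asarray(raw, dtype=float)
    if min(raw.shape) < 40:
        raise ValueError("image too small for lattice estimation")
    pitch0, orient0 = _fft_lattice_guess(raw)
    lo, hi = np.percentile(raw, [1, 99])
    raw_norm = (raw - lo) / max(hi - lo, 1e-12)

    # coarse offset scan over one lattice period; the FFT peak angle has a
    # sign ambiguity under the axis fold, so score both candidates
    steps = np.linspace(0.0, pitch0, 12, endpoint=False)
    orient_cands = {orient0, -orient0}
    best, best_off = -np.inf, (pitch0 / 2, pitch0 / 2)
    for cand in orient_cands:
        for oy in steps:
            for ox in steps:
                score = _disc_tile_correlation(raw_norm, pitch0, cand, (oy, ox))
                if score > best:
                    best, best_off, orient0 = score, (oy, ox), cand

    from scipy.optimize import minimize

    def neg(p):
        pitch, orient, oy, ox = p
        if pitch < 3 or abs(orient) > np.pi / 4:
            return np.inf
        return -_disc_tile_correlation(raw_norm, pitch, orient, (oy, ox))

    x0 = np.array([pitch0, orient0, best_off[0], best_off[1]])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 800})
    pitch, orient, oy, ox = res.x
    # canonical offset inside the first period
    oy %= pitch
    ox %= pitch
    return LatticeParams(pitch=float(pitch), orientation=float(orient),
                         offset=(float(oy), float(ox)))


# ---------------------------------------------------------------------------
# rectification
# ---------------------------------------------------------------------------

def resample_to_4d(raw: np.ndarray, lattice: LatticeParams,
                   optics: OpticalParams) -> LightField4D:
    """Resample a raw mosaic onto an axis-aligned lattice -> 4D light field.

    Bilinear resampling with ``round(pitch)`` pixels per subimage; the angular
    validity mask keeps samples within the circular aperture.  Subimages whose
    sampling grid extends outside the image are truncated (excluded).
    """
    raw = np.asarray(raw, dtype=float)
    n = int(round(lattice.pitch))
    if n < 3:
        raise ValueError("pitch < 3 px: too few angular samples")
    h, w = raw.shape
    c, s = np.cos(lattice.orientation), np.sin(lattice.orientation)
    oy, ox = lattice.offset

    # lattice index ranges whose centres can fall inside the image
    n_i = int(np.ceil(h / (lattice.pitch * c))) + 2
    n_j = int(np.ceil(w / (lattice.pitch * c))) + 2
    gi = np.arange(max(n_i, 1))
    gj = np.arange(max(n_j, 1))
    # subimage centres under the (small) lattice rotation
    cy = oy + lattice.pitch * (c * gi[:, None] - s * gj[None, :])
    cx = ox + lattice.pitch * (s * gi[:, None] + c * gj[None, :])

    du = np.arange(n) - (n - 1) / 2
    # sample offsets rotated with the lattice, 1 px angular spacing
    sy = c * du[:, None] - s * du[None, :]
    sx = s * du[:, None] + c * du[None, :]
    ys = cy[:, :, None, None] + sy[None, None, :, :]
    xs = cx[:, :, None, None] + sx[None, None, :, :]
    inside = (ys >= 0) & (ys <= h - 1) & (xs >= 0) & (xs <= w - 1)
    vals = ndimage.map_coordinates(raw, [ys.ravel(), xs.ravel()], order=1,
                                   mode="constant", cval=0.0)
    radiance = vals.reshape(ys.shape)
    ap = aperture_mask(n, n, optics.aperture_radius_frac, lattice.pitch)
    weights = (inside & ap[None, None, :, :]).astype(float)
    frac_inside = inside.mean(axis=(2, 3))
    if np.any((frac_inside > 0) & (frac_inside < 1)):
        import warnings

        warnings.warn("lattice extends outside the image; edge subimages truncated")
    # drop lattice rows/cols with no valid sample at all (truncated edge tiles)
    keep_i = weights.sum(axis=(1, 2, 3)) > 0
    keep_j = weights.sum(axis=(0, 2, 3)) > 0
    radiance = radiance[keep_i][:, keep_j]
    weights = weights[keep_i][:, keep_j]
    radiance[weights == 0] = 0.0
    return LightField4D(radiance=radiance, weights=weights, optics=optics)


# ---------------------------------------------------------------------------
# views, refocusing, integration
# ---------------------------------------------------------------------------

def pinhole_view(L: LightField4D, u: int, v: int) -> np.ndarray:
    """Perspective view: the same intra-subimage pixel from every subimage.

    ``(u, v)`` are centred angular coordinates; ``pinhole_view(L, 0, 0)`` is
    the on-axis view used for segmentation.
    """
    iu = int(u + (L.n_u - 1) / 2)
    iv = int(v + (L.n_v - 1) / 2)
    if not (0 <= iu < L.n_u and 0 <= iv < L.n_v):
        raise ValueError(f"angular index ({u}, {v}) outside angular dims")
    if not np.any(L.weights[:, :, iu, iv] > 0):
        raise ValueError(f"angular sample ({u}, {v}) outside the valid aperture")
    return L.radiance[:, :, iu, iv].copy()


def _interp_axis0(arr: np.ndarray, coords: np.ndarray, n: int) -> np.ndarray:
    """Linear interpolation of ``arr`` (axis 1 = spatial, axis 0 = angular)
    at per-(angular, spatial) coordinates ``coords`` (same leading shape);
    out-of-range samples give 0."""
    i0 = np.floor(coords).astype(int)
    t = coords - i0
    i0c = np.clip(i0, 0, n - 1)
    i1c = np.clip(i0 + 1, 0, n - 1)
    a = np.take_along_axis(arr, i0c[..., None, None], axis=1)
    b = np.take_along_axis(arr, i1c[..., None, None], axis=1)
    out = (1.0 - t)[..., None, None] * a + t[..., None, None] * b
    oob = (coords < 0) | (coords > n - 1)
    out[oob] = 0.0
    return out


def refocus(L: LightField4D, alpha: float) -> LightField4D:
    """Shear the light field parallel to the spatial plane (refocusing).

    Bilinear interpolation in (x, y); samples whose source coordinates fall
    outside the spatial extent become invalid (weight 0) rather than zero,
    so downstream integration renormalizes per pixel.  ``refocus(L, 1)``
    returns the field unchanged.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha == 1.0:
        return L.copy()
    nx, ny = L.n_x, L.n_y
    shear = 1.0 - 1.0 / alpha
    cx = L.u_coords[:, None] * shear + np.arange(nx)[None, :] / alpha  # (n_u, n_x)
    cy = L.v_coords[:, None] * shear + np.arange(ny)[None, :] / alpha  # (n_v, n_y)

    pre = L.radiance * L.weights
    # interpolate along x for every (u; y, v)
    pre_t = pre.transpose(2, 0, 1, 3)        # (n_u, n_x, n_y, n_v)
    w_t = L.weights.transpose(2, 0, 1, 3)
    pre_x = _interp_axis0(pre_t, cx, nx)
    w_x = _interp_axis0(w_t, cx, nx)
    # interpolate along y for every (v; x, u)
    pre_xy = _interp_axis0(pre_x.transpose(3, 2, 0, 1), cy, ny)  # (n_v, n_y, n_u, n_x)
    w_xy = _interp_axis0(w_x.transpose(3, 2, 0, 1), cy, ny)
    new_pre = pre_xy.transpose(3, 1, 2, 0)   # back to (n_x, n_y, n_u, n_v)
    new_w = w_xy.transpose(3, 1, 2, 0)

    radiance = np.zeros_like(new_pre)
    good = new_w > 1e-9
    radiance[good] = new_pre[good] / new_w[good]
    new_w[~good] = 0.0
    return LightField4D(radiance=radiance, weights=new_w, optics=L.optics)


def shift_refocus(L: LightField4D, alpha: float, *, dither_px: float = 0.0) -> LightField4D:
    """Pinhole-shift refocusing: each view translated by (1 - 1/alpha)(u, v).

    Equivalent to :func:`refocus` up to the latter's 1/alpha output
    magnification, i.e. it produces the same focused content but keeps every
    spatial pixel anchored to the native (alpha = 1) frame.  Depth-cue
    responses are computed with this variant so that a pixel interrogates the
    same scene point at every shear value.

    ``dither_px`` adds a constant global offset to the sampling coordinates.
    Without it, alpha = 1 is the only shear requiring no interpolation and is
    therefore artificially the sharpest slice of a sweep; a half-pixel dither
    makes every slice equally interpolated.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha == 1.0 and dither_px == 0.0:
        return L.copy()
    nx, ny = L.n_x, L.n_y
    shear = 1.0 - 1.0 / alpha
    cx = L.u_coords[:, None] * shear + np.arange(nx)[None, :] + dither_px
    cy = L.v_coords[:, None] * shear + np.arange(ny)[None, :] + dither_px
    pre = L.radiance * L.weights
    pre_t = pre.transpose(2, 0, 1, 3)
    w_t = L.weights.transpose(2, 0, 1, 3)
    pre_x = _interp_axis0(pre_t, cx, nx)
    w_x = _interp_axis0(w_t, cx, nx)
    pre_xy = _interp_axis0(pre_x.transpose(3, 2, 0, 1), cy, ny)
    w_xy = _interp_axis0(w_x.transpose(3, 2, 0, 1), cy, ny)
    new_pre = pre_xy.transpose(3, 1, 2, 0)
    new_w = w_xy.transpose(3, 1, 2, 0)
    radiance = np.zeros_like(new_pre)
    good = new_w > 1e-9
    radiance[good] = new_pre[good] / new_w[good]
    new_w[~good] = 0.0
    return LightField4D(radiance=radiance, weights=new_w, optics=L.optics)


def integrate_views(L: LightField4D, *, return_mask: bool = False):
    """Weighted mean over valid angular samples -> focused image.

    The mean (rather than the plain sum) makes edge renormalization after
    shearing automatic.  Pixels with no valid sample get 0 and are flagged.
    """
    wsum = L.weights.sum(axis=(2, 3))
    num = (L.radiance * L.weights).sum(axis=(2, 3))
    img = np.zeros_like(num)
    ok = wsum > 1e-9
    img[ok] = num[ok] / wsum[ok]
    if return_mask:
        return img, ~ok
    return img


def focal_stack(L: LightField4D, sweep: DepthSweep) -> np.ndarray:
    """Focal series: ``stack[k] = integrate_views(refocus(L, alpha_k))``."""
    if len(sweep) == 0:
        raise ValueError("sweep must be nonempty")
    return np.stack([integrate_views(refocus(L, a)) for a in sweep.alphas])
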