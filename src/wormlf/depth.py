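"""Depth from combined defocus and correspondence cues.

For each shear value alpha in a sweep the light field is refocused and two
per-pixel responses are computed on the view-integrated image L̄_alpha:

* defocus response  D_alpha = box-mean over a window W_D of |Laplacian(L̄_alpha)|
  (sharpness — maximal at the true depth);
* correspondence response  C_alpha = box-mean over W_C of the angular
  standard deviation sigma_alpha of the refocused views (photo-consistency —
  minimal at the true depth), with sigma^2 using population (1/N)
  normalization.

Per-pixel optima alpha_D* = argmax D, alpha_C* = argmin C give two depth
estimates whose confidences are the ratio of the response at the optimum to
the next-best local extremum (>= 1, capped).  The two cues are fused by a
Markov-random-field optimisation over the discrete sweep labels with L1 data
terms weighted by normalized confidence and truncated-linear smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .lightfield import DepthSweep, LightField4D, integrate_views, shift_refocus


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ResponseVolume:
    """Per-pixel cue response over a depth sweep; values (n_x, n_y, K)."""

    values: np.ndarray
    sweep: DepthSweep
    cue: str                 # "defocus" | "correspondence"
    window: int

    def __post_init__(self) -> None:
        if self.cue not in ("defocus", "correspondence"):
            raise ValueError("cue must be 'defocus' or 'correspondence'")
        if self.values.shape[-1] != len(self.sweep):
            raise ValueError("response depth axis does not match sweep")


@dataclass
class CueDepth:
    """Single-cue depth estimate with per-pixel confidence (>= 1)."""

    alpha_star: np.ndarray
    depth: np.ndarray          # um
    confidence: np.ndarray
    label: np.ndarray          # sweep index of the optimum
    reliable: np.ndarray       # False where the response was flat
    sweep: DepthSweep


@dataclass
class DepthMap:
    """Fused per-pixel depth (um) + confidence inside a footprint mask."""

    depth: np.ndarray
    confidence: np.ndarray
    footprint: np.ndarray

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.depth[self.footprint])):
            raise ValueError("depth must be finite inside the footprint")


@dataclass(frozen=True)
class CalibrationResult:
    """OLS line estimated = gradient * known + intercept."""

    gradient: float
    intercept: float
    r_squared: float
    rmse: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")


@dataclass(frozen=True)
class DepthParams:
    """Tunables of the fusion pipeline (windows in px, lambda/tau in labels)."""

    window_defocus: int = 5
    window_correspondence: int = 5
    smoothness: float = 0.5       # lambda
    truncation: float = 10.0      # tau, in label units
    confidence_cap: float = 10.0
    solver: str = "dp"            # "dp" | "icm"
    calibration_gradient: float | None = None


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

def _check_window(w: int, shape: tuple[int, int], minimum: int) -> None:
    if w < minimum or w % 2 == 0:
        raise ValueError(f"window must be odd and >= {minimum}")
    if w > min(shape):
        raise ValueError("window larger than image")


def _defocus_slice(img: np.ndarray, window: int) -> np.ndarray:
    lap = np.abs(ndimage.laplace(img, mode="reflect"))
    return ndimage.uniform_filter(lap, size=window, mode="reflect")


def _correspondence_slice(L: LightField4D, img: np.ndarray, window: int) -> np.ndarray:
    wsum = L.weights.sum(axis=(2, 3))
    dev2 = ((L.radiance - img[:, :, None, None]) ** 2 * L.weights).sum(axis=(2, 3))
    sigma = np.zeros_like(img)
    ok = wsum > 1e-9
    sigma[ok] = np.sqrt(dev2[ok] / wsum[ok])
    if window > 1:
        sigma = ndimage.uniform_filter(sigma, size=window, mode="reflect")
    return sigma


def sweep_responses(L: LightField4D, sweep: DepthSweep, *,
                    window_defocus: int = 5, window_correspondence: int = 5,
                    cues: tuple[str, ...] = ("defocus", "correspondence"),
                    dither_px: float = 0.5
                    ) -> tuple[ResponseVolume | None, ResponseVolume | None]:
    """Compute the requested cue responses in a single pass over the sweep.

    ``dither_px`` (default half a pixel) offsets every slice's resampling
    identically so that no single shear value is privileged by being
    interpolation-free; set it to 0 to evaluate the responses on the
    unmodified field (e.g. for single-shear checks).
    """
    shape = (L.n_x, L.n_y)
    want_d = "defocus" in cues
    want_c = "correspondence" in cues
    if want_d:
        _check_window(window_defocus, shape, 3)
    if want_c:
        _check_window(window_correspondence, shape, 1)
    K = len(sweep)
    dvol = np.empty(shape + (K,)) if want_d else None
    cvol = np.empty(shape + (K,)) if want_c else None
    for k, a in enumerate(sweep.alphas):
        Lr = shift_refocus(L, float(a), dither_px=dither_px)
        img = integrate_views(Lr)
        if want_d:
            dvol[:, :, k] = _defocus_slice(img, window_defocus)
        if want_c:
            cvol[:, :, k] = _correspondence_slice(Lr, img, window_correspondence)
    return (ResponseVolume(dvol, sweep, "defocus", window_defocus) if want_d else None,
            ResponseVolume(cvol, sweep, "correspondence", window_correspondence) if want_c else None)


def defocus_response(L: LightField4D, sweep: DepthSweep, window: int = 5,
                     dither_px: float = 0.5) -> ResponseVolume:
    """Sharpness (|Laplacian|) response over the sweep; maximal in focus."""
    return sweep_responses(L, sweep, window_defocus=window, cues=("defocus",),
                           dither_px=dither_px)[0]


def correspondence_response(L: LightField4D, sweep: DepthSweep, window: int = 5,
                            dither_px: float = 0.5) -> ResponseVolume:
    """Angular-deviation response over the sweep; minimal in focus."""
    return sweep_responses(L, sweep, window_correspondence=window,
                           cues=("correspondence",), dither_px=dither_px)[1]


# ---------------------------------------------------------------------------
# extrema + confidence
# ---------------------------------------------------------------------------

_EPS_FLAT = 1e-12


def cue_extrema(resp: ResponseVolume, *, cap: float = 10.0) -> CueDepth:
    """Per-pixel optimum of a cue response with peak-ratio confidence.

    Confidence is response(optimum) / response(next-best strict local
    extremum) for defocus (inverted for correspondence), so confidence >= 1
    always means "better"; with no second extremum it is set to ``cap`` and a
    flat response gives confidence 1 with the pixel flagged unreliable.
    """
    if len(resp.sweep) < 3:
        raise ValueError("sweep length must be >= 3")
    vals = resp.values
    if resp.cue == "correspondence":
        vals = -vals      # work with maxima throughout
    K = vals.shape[-1]
    best_idx = np.argmax(vals, axis=-1)
    best_val = np.take_along_axis(vals, best_idx[..., None], axis=-1)[..., 0]
    flat = (vals.max(axis=-1) - vals.min(axis=-1)) <= _EPS_FLAT

    # strict local maxima (epsilon-flattened); sweep endpoints count if they
    # exceed their single neighbour
    pad = np.concatenate([vals[..., :1] - 1.0, vals, vals[..., -1:] - 1.0], axis=-1)
    is_max = (pad[..., 1:-1] > pad[..., :-2] + _EPS_FLAT) & \
             (pad[..., 1:-1] > pad[..., 2:] + _EPS_FLAT)
    # exclude the global optimum itself
    cand = np.where(is_max, vals, -np.inf)
    np.put_along_axis(cand, best_idx[..., None], -np.inf, axis=-1)
    second = cand.max(axis=-1)

    conf = np.full(best_val.shape, cap, dtype=float)
    have_second = np.isfinite(second)
    if resp.cue == "defocus":
        b, s = best_val, second
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((have_second) & (s > _EPS_FLAT), b / np.where(s > _EPS_FLAT, s, 1.0), cap)
    else:
        b, s = -best_val, -second      # back to raw response values (min best)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((have_second) & (b > _EPS_FLAT), s / np.where(b > _EPS_FLAT, b, 1.0), cap)
    conf = np.clip(ratio, 1.0, cap)
    conf[flat] = 1.0
    return CueDepth(alpha_star=resp.sweep.alphas[best_idx],
                    depth=resp.sweep.depths[best_idx],
                    confidence=conf, label=best_idx,
                    reliable=~flat, sweep=resp.sweep)


# ---------------------------------------------------------------------------
# MRF fusion
# ---------------------------------------------------------------------------

def mrf_energy(labels: np.ndarray, data_cost: np.ndarray, lam: float, tau: float) -> float:
    """Total energy of a labelling: unary data costs + truncated-linear
    smoothness over the 4-neighbourhood."""
    e = np.take_along_axis(data_cost, labels[..., None], axis=-1)[..., 0].sum()
    d = np.abs(np.diff(labels, axis=0))
    e += lam * np.minimum(d, tau).sum()
    d = np.abs(np.diff(labels, axis=1))
    e += lam * np.minimum(d, tau).sum()
    return float(e)


def _chain_dp(unary: np.ndarray, lam: float, tau: float) -> np.ndarray:
    """Exact Viterbi over a chain with truncated-linear pairwise cost.

    ``unary`` is (n, K).  The min-convolution with lam*min(|d|, tau) is done
    in O(K) per step via forward/backward cumulative minima plus the
    truncation plateau.
    """
    n, K = unary.shape
    lab = np.arange(K, dtype=float)
    F = np.empty((n, K))
    F[0] = unary[0]
    for i in range(1, n):
        prev = F[i - 1]
        fwd = np.minimum.accumulate(prev - lam * lab) + lam * lab
        bwd = (np.minimum.accumulate((prev + lam * lab)[::-1]))[::-1] - lam * lab
        msg = np.minimum(np.minimum(fwd, bwd), prev.min() + lam * tau)
        F[i] = unary[i] + msg
    labels = np.empty(n, dtype=int)
    labels[-1] = int(np.argmin(F[-1]))
    for i in range(n - 2, -1, -1):
        trans = lam * np.minimum(np.abs(lab - labels[i + 1]), tau)
        labels[i] = int(np.argmin(F[i] + trans))
    return labels


def _band_dp(data_cost: np.ndarray, lam: float, tau: float) -> np.ndarray:
    """Exact Viterbi over columns with whole-column super-labels.

    Globally optimal for any instance where K**min(H, W) is small (narrow
    bands); used automatically so that small instances are solved exactly.
    """
    import itertools

    transposed = data_cost.shape[0] > data_cost.shape[1]
    if transposed:
        data_cost = data_cost.transpose(1, 0, 2)
    H, W, K = data_cost.shape
    states = np.array(list(itertools.product(range(K), repeat=H)))   # (S, H)
    S = states.shape[0]
    intra = lam * np.minimum(np.abs(np.diff(states, axis=1)), tau).sum(axis=1)
    inter = lam * np.minimum(np.abs(states[:, None, :] - states[None, :, :]), tau).sum(axis=2)
    unary = np.stack([data_cost[np.arange(H), c, states].sum(axis=1) + intra
                      for c in range(W)])                             # (W, S)
    F = np.empty((W, S))
    back = np.zeros((W, S), dtype=int)
    F[0] = unary[0]
    for c in range(1, W):
        tot = F[c - 1][:, None] + inter
        back[c] = np.argmin(tot, axis=0)
        F[c] = unary[c] + tot[back[c], np.arange(S)]
    s = int(np.argmin(F[-1]))
    cols = [s]
    for c in range(W - 1, 0, -1):
        s = back[c, s]
        cols.append(s)
    labels = states[cols[::-1]].T.copy()    # (H, W)
    return labels.T.copy() if transposed else labels


def _solve_dp(data_cost: np.ndarray, lam: float, tau: float,
              init: np.ndarray, max_sweeps: int = 12) -> np.ndarray:
    """Block coordinate descent: exact DP per scanline, alternating rows and
    columns, each line conditioned on its frozen perpendicular neighbours."""
    H, W, K = data_cost.shape
    labels = init.copy()
    lab = np.arange(K, dtype=float)
    best_e = mrf_energy(labels, data_cost, lam, tau)
    for _ in range(max_sweeps):
        for axis in (0, 1):
            n_lines = H if axis == 0 else W
            for i in range(n_lines):
                if axis == 0:
                    unary = data_cost[i].copy()      # (W, K)
                    for j in (i - 1, i + 1):
                        if 0 <= j < H:
                            unary += lam * np.minimum(
                                np.abs(lab[None, :] - labels[j][:, None]), tau)
                    labels[i] = _chain_dp(unary, lam, tau)
                else:
                    unary = data_cost[:, i].copy()   # (H, K)
                    for j in (i - 1, i + 1):
                        if 0 <= j < W:
                            unary += lam * np.minimum(
                                np.abs(lab[None, :] - labels[:, j][:, None]), tau)
                    labels[:, i] = _chain_dp(unary, lam, tau)
        e = mrf_energy(labels, data_cost, lam, tau)
        if e >= best_e - 1e-12:
            break
        best_e = e
    return labels


def _solve_icm(data_cost: np.ndarray, lam: float, tau: float,
               init: np.ndarray, max_iters: int = 50) -> np.ndarray:
    H, W, K = data_cost.shape
    labels = init.copy()
    lab = np.arange(K, dtype=float)
    for _ in range(max_iters):
        changed = False
        for y in range(H):
            for x in range(W):
                cost = data_cost[y, x].copy()
                for ny, nx_ in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                    if 0 <= ny < H and 0 <= nx_ < W:
                        cost += lam * np.minimum(np.abs(lab - labels[ny, nx_]), tau)
                new = int(np.argmin(cost))
                if new != labels[y, x]:
                    labels[y, x] = new
                    changed = True
        if not changed:
            break
    return labels


def combine_depth(dd: CueDepth, dc: CueDepth, *, footprint: np.ndarray,
                  params: DepthParams = DepthParams()) -> DepthMap:
    """Fuse defocus and correspondence estimates with an MRF optimisation.

    Minimizes, over the sweep's discrete depth labels z,

        E(z) = sum_p [w_d(p) |z_p - z_d(p)| + w_c(p) |z_p - z_c(p)|]
             + lambda * sum_{p~q} min(|z_p - z_q|, tau)

    with weights w the confidences normalized by the cap (unreliable pixels
    get weight 0).  Solved by exact per-scanline dynamic programming
    alternated over directions (or ICM), starting from the
    confidence-weighted mean of the two cue labels.
    """
    if dd.depth.shape != dc.depth.shape:
        raise ValueError("cue grids differ")
    footprint = np.asarray(footprint, dtype=bool)
    if not np.any(footprint):
        raise ValueError("empty footprint")
    cap = params.confidence_cap
    w_d = np.where(dd.reliable, dd.confidence / cap, 0.0)
    w_c = np.where(dc.reliable, dc.confidence / cap, 0.0)

    # restrict to the bounding box of the footprint for speed
    ys, xs = np.where(footprint)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = np.s_[y0:y1, x0:x1]
    K = len(dd.sweep)
    lab = np.arange(K, dtype=float)
    data_cost = (w_d[sub][..., None] * np.abs(lab - dd.label[sub][..., None])
                 + w_c[sub][..., None] * np.abs(lab - dc.label[sub][..., None]))

    wsum = w_d[sub] + w_c[sub]
    mean_lab = np.where(
        wsum > 0,
        (w_d[sub] * dd.label[sub] + w_c[sub] * dc.label[sub]) / np.where(wsum > 0, wsum, 1.0),
        0.5 * (dd.label[sub] + dc.label[sub]))
    init = np.clip(np.rint(mean_lab), 0, K - 1).astype(int)

    if params.solver == "dp":
        if K ** min(data_cost.shape[0], data_cost.shape[1]) <= 4096:
            # narrow band: exact global optimum over column super-labels
            labels = _band_dp(data_cost, params.smoothness, params.truncation)
        else:
            # block coordinate descent can stop in a local minimum; restart
            # from each cue's own labelling as well and keep the lowest energy
            candidates = [init, dd.label[sub].astype(int), dc.label[sub].astype(int)]
            labels, best_e = None, np.inf
            for cand in candidates:
                sol = _solve_dp(data_cost, params.smoothness, params.truncation, cand)
                e = mrf_energy(sol, data_cost, params.smoothness, params.truncation)
                if e < best_e:
                    labels, best_e = sol, e
    elif params.solver == "icm":
        labels = _solve_icm(data_cost, params.smoothness, params.truncation, init)
    else:
        raise ValueError("solver must be 'dp' or 'icm'")

    depth = np.full(dd.depth.shape, np.nan)
    depth[sub] = dd.sweep.depths[labels]
    conf = np.zeros(dd.depth.shape)
    conf[sub] = 0.5 * (dd.confidence[sub] + dc.confidence[sub])
    depth[~footprint] = np.nan
    conf[~footprint] = 0.0
    return DepthMap(depth=depth, confidence=conf, footprint=footprint)


# ---------------------------------------------------------------------------
# pipeline + calibration
# ---------------------------------------------------------------------------

def estimate_depth(L: LightField4D, sweep: DepthSweep, *,
                   footprint: np.ndarray | None = None,
                   params: DepthParams = DepthParams()) -> DepthMap:
    """Full cue-fusion pipeline for one rectified light field frame.

    Responses -> per-cue extrema -> MRF combination; applies the reciprocal
    calibration gradient when one is configured.  Without a footprint the
    whole frame is processed.
    """
    dvol, cvol = sweep_responses(
        L, sweep, window_defocus=params.window_defocus,
        window_correspondence=params.window_correspondence)
    dd = cue_extrema(dvol, cap=params.confidence_cap)
    dc = cue_extrema(cvol, cap=params.confidence_cap)
    if footprint is None:
        footprint = np.ones(dd.depth.shape, dtype=bool)
    dm = combine_depth(dd, dc, footprint=footprint, params=params)
    if params.calibration_gradient is not None:
        dm = DepthMap(depth=dm.depth / params.calibration_gradient,
                      confidence=dm.confidence, footprint=dm.footprint)
    return dm


def calibrate_depth_scale(estimated_um, known_um) -> CalibrationResult:
    """OLS line of estimated on known depth: gradient, intercept, R², RMSE.

    Downstream correction divides estimates by the gradient so corrected
    estimates regress on known depth with unit slope.
    """
    est = np.asarray(estimated_um, dtype=float)
    known = np.asarray(known_um, dtype=float)
    if est.size != known.size or est.size < 3:
        raise ValueError("need >= 3 paired calibration points")
    if np.unique(known).size < 2:
        raise ValueError("known depths must be distinct")
    fit = stats.linregress(known, est)
    resid = est - (fit.slope * known + fit.intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CalibrationResult(gradient=float(fit.slope),
                             intercept=float(fit.intercept),
                             r_squared=float(np.clip(fit.rvalue**2, 0.0, 1.0)),
                             rmse=rmse)
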