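"""Posture and locomotion metrics from 3D skeleton time series.

Per-frame metrics: centroid speed CS_i = |r_{i+1} - r_i| / (t_{i+1} - t_i);
non-planar deviation NPD = R3/R1, the ratio of shortest to longest principal
axes of the best-fit ellipsoid to the skeleton (0 for planar postures);
curving rate, the angle between successive centroid displacement vectors per
unit time; and the directional autocorrelation
D(n) = (1/(N-n)) sum_i v_i . v_{i+n} of unit displacement directions, with
an exponential decay fit D(t) = A exp(-b t).

Strain comparisons average each metric per worm first (SEM over worms, not
frames) and use Welch's two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .midline import Skeleton3D


# ---------------------------------------------------------------------------
# track container
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Centroid trajectory of one recording.

    ``directions[i]`` is the unit vector of the displacement r_{i+1} - r_i
    (NaN where the displacement is zero).
    """

    times: np.ndarray        # (N,)
    centroids: np.ndarray    # (N, 3) um
    directions: np.ndarray = field(init=False)
    skeletons: list[Skeleton3D] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.times.ndim != 1 or self.centroids.shape != (self.times.size, 3):
            raise ValueError("times (N,) and centroids (N, 3) required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        disp = np.diff(self.centroids, axis=0)
        norm = np.linalg.norm(disp, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.directions = np.where(norm[:, None] > 0, disp / norm[:, None], np.nan)

    @classmethod
    def from_skeletons(cls, skeletons: list[Skeleton3D]) -> "Track":
        times = np.array([s.time_s for s in skeletons])
        centroids = np.array([s.points.mean(axis=0) for s in skeletons])
        return cls(times=times, centroids=centroids, skeletons=skeletons)


# ---------------------------------------------------------------------------
# per-frame metrics
# ---------------------------------------------------------------------------

def centroid_speed(track: Track) -> np.ndarray:
    """Forward-difference centroid speeds (um/s), length N-1."""
    if track.times.size < 2:
        raise ValueError("need at least 2 frames")
    disp = np.linalg.norm(np.diff(track.centroids, axis=0), axis=1)
    return disp / np.diff(track.times)


def non_planar_deviation(points: np.ndarray) -> float:
    """NPD = R3/R1 from the principal axes of the skeleton point cloud."""
    pts = np.asarray(points, dtype=float)
    pts = pts.reshape(-1, 3)
    if pts.shape[0] < 4:
        raise ValueError("need >= 4 points")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / pts.shape[0]
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    radii = np.sqrt(np.clip(eig, 0.0, None))
    if radii[0] <= 0:
        raise ValueError("degenerate skeleton (all points identical)")
    return float(radii[2] / radii[0])


def curving_rate(track: Track, *, signed_angles: bool = False) -> np.ndarray:
    """Turning angle per unit time between successive displacement vectors.

    Frames with zero displacement are skipped.  The default folds angles into
    [0, pi/2] by taking |cos|; ``signed_angles=False`` keeps that convention,
    True uses the plain (unfolded) angle in [0, pi].
    """
    if track.times.size < 3:
        raise ValueError("need at least 3 frames")
    disp = np.diff(track.centroids, axis=0)
    norms = np.linalg.norm(disp, axis=1)
    nz = np.flatnonzero(norms > 0)
    if nz.size < 2:
        warnings.warn("all displacements zero; empty curving-rate series")
        return np.empty(0)
    rates = []
    for a, b in zip(nz[:-1], nz[1:]):
        cosang = np.dot(disp[a], disp[b]) / (norms[a] * norms[b])
        if not signed_angles:
            cosang = abs(cosang)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        dt = track.times[b + 1] - track.times[a + 1]
        rates.append(ang / dt)
    return np.asarray(rates)


def directional_autocorrelation(track: Track, max_lag: int) -> np.ndarray:
    """D(n) = (1/(N-n)) sum v_i . v_{i+n} for n = 0..max_lag; D(0) = 1."""
    v = track.directions
    N = v.shape[0]
    if max_lag >= N:
        raise ValueError("max_lag too large for the track length")
    out = np.empty(max_lag + 1)
    for n in range(max_lag + 1):
        dots = np.einsum("ij,ij->i", v[: N - n], v[n:])
        dots = dots[np.isfinite(dots)]
        if dots.size == 0:
            raise ValueError("no valid direction pairs at lag %d" % n)
        out[n] = dots.mean()
    return out


def fit_direction_decay(D: np.ndarray, lag_times: np.ndarray) -> tuple[float, float, float]:
    """Fit D(t) = A exp(-b t); returns (A, b, residual norm)."""
    D = np.asarray(D, dtype=float)
    t = np.asarray(lag_times, dtype=float)
    if D.size < 3 or D.size != t.size:
        raise ValueError("need >= 3 matching lags")

    def model(t, A, b):
        return A * np.exp(-b * t)

    try:
        popt, _ = optimize.curve_fit(model, t, D, p0=(D[0] if D[0] != 0 else 1.0, 0.1),
                                     bounds=([-np.inf, 0.0], [np.inf, np.inf]),
                                     maxfev=10000)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"exponential decay fit did not converge: {err}")
    resid = float(np.linalg.norm(D - model(t, *popt)))
    return float(popt[0]), float(popt[1]), resid


# ---------------------------------------------------------------------------
# forward runs, explored volume
# ---------------------------------------------------------------------------

def detect_forward_runs(track: Track, *, speed_threshold_um_s: float = 10.0,
                        min_duration_s: float = 0.5) -> list[tuple[int, int]]:
    """Maximal frame intervals of sustained forward locomotion.

    Forward: centroid speed >= threshold and displacement direction with a
    positive component along the tail-to-nose body axis (requires skeletons
    on the track); intervals shorter than ``min_duration_s`` are dropped.
    Returns [start, end) frame-index pairs.
    """
    speeds = centroid_speed(track)
    forward = speeds >= speed_threshold_um_s
    if track.skeletons is not None:
        axes = np.array([s.points[0] - s.points[-1] for s in track.skeletons])
        axes = axes[:-1]
        dots = np.einsum("ij,ij->i", track.directions, axes)
        forward &= np.nan_to_num(dots) > 0
    runs = []
    i = 0
    n = forward.size
    while i < n:
        if forward[i]:
            j = i
            while j < n and forward[j]:
                j += 1
            if track.times[j] - track.times[i] >= min_duration_s:
                runs.append((i, j + 1))
            i = j
        else:
            i += 1
    return runs


def occupied_volume(skeletons: list[Skeleton3D]) -> tuple[float, float]:
    """Axis-aligned bounding-box volumes (mm^3) of all skeleton points and of
    the nose point alone over the sequence."""
    if not skeletons:
        raise ValueError("empty skeleton sequence")
    allpts = np.concatenate([s.points for s in skeletons])
    nose = np.array([s.points[0] for s in skeletons])

    def box(p):
        ext = p.max(axis=0) - p.min(axis=0)
        return float(np.prod(ext) * 1e-9)   # um^3 -> mm^3

    return box(allpts), box(nose)


# ---------------------------------------------------------------------------
# strain comparison
# ---------------------------------------------------------------------------

@dataclass
class StrainSummary:
    """Group means ± SEM (over worms) and Welch t-test p-values per metric."""

    metrics: list[str]
    mean_a: dict
    sem_a: dict
    mean_b: dict
    sem_b: dict
    t_statistic: dict
    p_value: dict
    flagged: dict


def compare_strains(group_a: dict, group_b: dict) -> StrainSummary:
    """Welch two-sample t-test per metric between per-worm mean values.

    ``group_a``/``group_b`` map metric name -> array of per-worm means
    (>= 2 worms per group).  Zero variance in both groups leaves the p-value
    undefined (NaN) and flags the metric.
    """
    metrics = sorted(set(group_a) & set(group_b))
    if not metrics:
        raise ValueError("no common metrics between groups")
    mean_a, sem_a, mean_b, sem_b, tstat, pval, flagged = {}, {}, {}, {}, {}, {}, {}
    for m in metrics:
        a = np.asarray(group_a[m], dtype=float)
        b = np.asarray(group_b[m], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"metric {m}: need >= 2 worms per group")
        mean_a[m], mean_b[m] = float(a.mean()), float(b.mean())
        sem_a[m] = float(a.std(ddof=1) / np.sqrt(a.size))
        sem_b[m] = float(b.std(ddof=1) / np.sqrt(b.size))
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if mean_a[m] == mean_b[m]:
                tstat[m], pval[m] = 0.0, 1.0
            else:
                tstat[m], pval[m] = np.nan, np.nan
            flagged[m] = True
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        tstat[m], pval[m] = float(res.statistic), float(res.pvalue)
        flagged[m] = False
    return StrainSummary(metrics=metrics, mean_a=mean_a, sem_a=sem_a,
                         mean_b=mean_b, sem_b=sem_b, t_statistic=tstat,
                         p_value=pval, flagged=flagged)
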