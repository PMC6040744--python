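"""3D eigenworms and the rhodonea model of swimming.

Eigenworms are the principal components of mean-zeroed 25-element body
tangent-angle vectors.  Azimuthal (theta) and polar (phi) channels give
closely similar bases, so a single shared basis — the azimuthal set — is
used to project both channels, yielding amplitude time series a_i^theta(t),
a_i^phi(t).

For a swimming worm the paired first-mode amplitudes trace a rose (rhodonea)
curve; the model

    a_i^theta(t) = A cos[k (a t + c)] cos[a t + c]
    a_i^phi(t)   = A cos[k (a t + c)] sin[a t + c]

couples a fast undulation (frequency k·a) with a slow rotation of the
oscillation plane (frequency a); k is the ratio of undulation to body-roll
frequency ("rolling frequency" ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .midline import AngleVectors


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PostureEnsemble:
    """Frames-by-25 matrix of mean-zeroed angle vectors from one channel."""

    matrix: np.ndarray
    channel: str                      # "theta" | "phi"
    provenance: list | None = None    # optional per-row tags

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("ensemble must be 2D (frames x segments)")
        if self.channel not in ("theta", "phi"):
            raise ValueError("channel must be 'theta' or 'phi'")
        row_means = self.matrix.mean(axis=1)
        if self.matrix.size and np.max(np.abs(row_means)) > 1e-6:
            raise ValueError("rows must be mean-zero angle vectors")

    @classmethod
    def from_angles(cls, angles: list[AngleVectors], channel: str = "theta",
                    provenance: list | None = None) -> "PostureEnsemble":
        rows = [getattr(a, channel) for a in angles]
        return cls(matrix=np.asarray(rows), channel=channel, provenance=provenance)


@dataclass
class PostureBasis:
    """Orthonormal eigenworm basis with its explained-variance spectrum."""

    eigenworms: np.ndarray            # (n_segments, m), orthonormal columns
    explained_variance: np.ndarray    # descending fractions, sum <= 1
    mean: np.ndarray                  # ensemble column means
    channel: str = "theta"            # channel the basis was computed from

    def __post_init__(self) -> None:
        g = self.eigenworms.T @ self.eigenworms
        if not np.allclose(g, np.eye(g.shape[0]), atol=1e-9):
            raise ValueError("eigenworm columns must be orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained-variance fractions must be descending")
        if self.explained_variance.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must sum to <= 1")

    @property
    def n_modes(self) -> int:
        return self.eigenworms.shape[1]


@dataclass
class ProjectionSeries:
    """Mode amplitudes over time for both angle channels."""

    times: np.ndarray
    a_theta: np.ndarray    # (T, m)
    a_phi: np.ndarray      # (T, m)


@dataclass
class RhodoneaFit:
    """Least-squares rhodonea parameters for one mode pair."""

    amplitude: float
    k: float
    angular_rate: float    # a, rad/s
    phase: float           # c
    residual_norm: float

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.k <= 0:
            raise ValueError("require amplitude >= 0 and k > 0")


# ---------------------------------------------------------------------------
# eigenworms
# ---------------------------------------------------------------------------

def compute_eigenworms(ensemble: PostureEnsemble, m: int) -> PostureBasis:
    """Top-m principal directions of the column-centred angle ensemble.

    Each eigenworm's sign is fixed so its largest-magnitude element is
    positive (PCA sign ambiguity).
    """
    X = ensemble.matrix
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many frames as segments")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD-based PCA
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2
    total = var.sum()
    if total <= 0:
        raise ValueError("ensemble has zero variance after centring")
    rank = int(np.sum(svals > svals[0] * 1e-12))
    if m > rank:
        raise ValueError(f"requested {m} modes but ensemble rank is {rank}")
    comps = Vt[:m].T
    signs = np.sign(comps[np.argmax(np.abs(comps), axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    comps = comps * signs
    return PostureBasis(eigenworms=comps, explained_variance=var[:m] / total,
                        mean=mean, channel=ensemble.channel)


def project_posture(angles: AngleVectors | np.ndarray, basis: PostureBasis,
                    channel: str = "theta") -> np.ndarray:
    """Amplitudes a_i = eigenworm_i . (angles - ensemble mean).

    Both theta and phi channels are projected onto the same (azimuthal)
    basis; the ensemble column mean belongs to the channel the basis was
    computed from, so it is subtracted only when projecting that channel
    (angle vectors are mean-zeroed, so the other channel's ensemble mean is
    zero to numerical precision anyway).
    """
    vec = getattr(angles, channel) if isinstance(angles, AngleVectors) else np.asarray(angles, dtype=float)
    if vec.shape[-1] != basis.eigenworms.shape[0]:
        raise ValueError("angle vector length does not match the basis")
    mean = basis.mean if channel == basis.channel else 0.0
    return (vec - mean) @ basis.eigenworms


def project_series(angles: list[AngleVectors], basis: PostureBasis,
                   times: np.ndarray | None = None) -> ProjectionSeries:
    """Project a frame sequence's theta and phi vectors onto a shared basis."""
    a_th = np.array([project_posture(a, basis, "theta") for a in angles])
    a_ph = np.array([project_posture(a, basis, "phi") for a in angles])
    if times is None:
        times = np.arange(len(angles), dtype=float)
    return ProjectionSeries(times=np.asarray(times, dtype=float),
                            a_theta=a_th, a_phi=a_ph)


def variance_captured(basis: PostureBasis, n: int) -> float:
    """Cumulative explained-variance fraction of the first n eigenworms."""
    if n > basis.n_modes:
        raise ValueError("n exceeds the number of modes in the basis")
    return float(basis.explained_variance[:n].sum())


# ---------------------------------------------------------------------------
# rhodonea fit
# ---------------------------------------------------------------------------

def _rhodonea(t, A, k, a, c):
    u = a * t + c
    env = A * np.cos(k * u)
    return env * np.cos(u), env * np.sin(u)


def fit_rhodonea(a_theta: np.ndarray, a_phi: np.ndarray, times: np.ndarray,
                 *, k_grid: np.ndarray | None = None) -> RhodoneaFit:
    """Joint least-squares fit of the rhodonea model to one mode pair.

    The product of undulation and roll factors has envelope power spectrum
    peaking at 2 k a, which initializes k·a from the dominant spectral peak
    of a_theta**2 + a_phi**2; k is then scanned on a coarse grid (default
    0.5–20, step 0.25) with joint nonlinear refinement of (A, k, a, c) from
    each initialization, keeping the best residual.
    """
    th = np.asarray(a_theta, dtype=float)
    ph = np.asarray(a_phi, dtype=float)
    t = np.asarray(times, dtype=float)
    if th.size != ph.size or th.size != t.size or th.size < 8:
        raise ValueError("need matching series of at least 8 samples")
    if th.std() < 1e-12 and ph.std() < 1e-12:
        raise ValueError("no oscillation detected")

    power = th**2 + ph**2
    dt = np.median(np.diff(t))
    spec = np.abs(np.fft.rfft(power - power.mean()))
    freqs = np.fft.rfftfreq(power.size, dt)
    if spec[1:].max() <= 0:
        raise ValueError("no oscillation detected")
    f_env = freqs[1 + int(np.argmax(spec[1:]))]
    ka_est = np.pi * f_env               # 2*k*a = 2*pi*f_env
    A0 = float(np.sqrt(2.0 * power.mean()))

    if k_grid is None:
        k_grid = np.arange(0.5, 20.0 + 1e-9, 0.25)

    def resid(p):
        A, k, a, c = p
        mth, mph = _rhodonea(t, A, k, a, c)
        return np.concatenate([mth - th, mph - ph])

    best = None
    for k0 in k_grid:
        a0 = ka_est / k0 if ka_est > 0 else 2 * np.pi / (t[-1] - t[0])
        # the cost is oscillatory in c through the fast phase k*c, so the
        # phase scan must resolve it before local refinement
        cs = np.linspace(0, 2 * np.pi, max(16, int(8 * np.ceil(k0))), endpoint=False)
        costs = [np.sum(resid((A0, k0, a0, c0)) ** 2) for c0 in cs]
        c0 = cs[int(np.argmin(costs))]
        try:
            sol = optimize.least_squares(resid, x0=(A0, k0, a0, c0),
                                         bounds=([0, 1e-3, 1e-6, -np.inf],
                                                 [np.inf, 50.0, np.inf, np.inf]),
                                         max_nfev=200)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("rhodonea fit failed")
    best = optimize.least_squares(resid, x0=best.x,
                                  bounds=([0, 1e-3, 1e-6, -np.inf],
                                          [np.inf, 50.0, np.inf, np.inf]),
                                  xtol=1e-14, ftol=1e-14, max_nfev=5000)
    A, k, a, c = best.x
    return RhodoneaFit(amplitude=float(abs(A)), k=float(k), angular_rate=float(a),
                       phase=float(c), residual_norm=float(np.sqrt(2 * best.cost)))


def fit_rhodonea_modes(series: ProjectionSeries, modes=(1, 2)) -> dict:
    """Independent rhodonea fits per mode (1-based indices) with mean/SD of k."""
    fits = {}
    for m in modes:
        fits[m] = fit_rhodonea(series.a_theta[:, m - 1], series.a_phi[:, m - 1],
                               series.times)
    ks = np.array([f.k for f in fits.values()])
    return {"fits": fits, "k_mean": float(ks.mean()),
            "k_sd": float(ks.std(ddof=1)) if ks.size > 1 else 0.0}
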