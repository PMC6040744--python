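"""End-to-end synthetic experiments: depth calibration and eigenworm compactness.

These drive the full pipeline on phantom data — render raw mosaics, correct
vignetting, rectify, estimate depth, calibrate — and are shared by the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .depth import CalibrationResult, DepthParams, calibrate_depth_scale, estimate_depth
from .lightfield import DepthSweep, correct_vignetting, estimate_lattice, resample_to_4d
from .midline import Skeleton3D, skeleton_angles
from .phantom import (
    LocomotionParams,
    RenderConfig,
    calibration_series,
    generate_locomotion,
)
from .posture import PostureEnsemble, compute_eigenworms, variance_captured


def run_depth_calibration(*, noise_sigma: float = 0.0, seed: int = 42,
                          n_depths: int = 21, z_max_um: float = 1000.0,
                          sweep_steps: int = 256,
                          cfg: RenderConfig | None = None
                          ) -> tuple[CalibrationResult, np.ndarray, np.ndarray]:
    """Full-pipeline depth calibration on a rendered rod series.

    A static rod phantom is rendered at ``n_depths`` known axial offsets
    spanning +/- ``z_max_um``; every frame goes through vignetting
    correction, lattice rectification and combined defocus/correspondence
    depth estimation.  The lattice is estimated once from the flat-field
    background exposure, whose mosaic shows the microlens lattice free of
    scene content and sensor noise.  The per-frame depth is summarized by
    the median over the phantom footprint and regressed against the known
    offsets.

    Returns the calibration fit plus the (known, estimated) depth arrays.
    """
    if cfg is None:
        cfg = RenderConfig(noise_sigma=noise_sigma)
    elif noise_sigma:
        raise ValueError("give noise_sigma through cfg when cfg is supplied")
    optics = cfg.optics
    depths = np.linspace(-z_max_um, z_max_um, n_depths)
    series = calibration_series(cfg, depths, seed=seed)
    # sweep slightly wider than the calibrated range so no frame sits on the
    # sweep boundary
    sweep = DepthSweep.uniform_depth(optics, -1.1 * z_max_um, 1.1 * z_max_um,
                                     sweep_steps)
    lattice = estimate_lattice(series[0][1])
    estimated = np.empty(n_depths)
    for i, (raw, background, scene) in enumerate(series):
        corrected = correct_vignetting(raw, background)
        L = resample_to_4d(corrected, lattice, optics)
        dm = estimate_depth(L, sweep, footprint=scene.footprint,
                            params=DepthParams())
        estimated[i] = np.median(dm.depth[scene.footprint])
    fit = calibrate_depth_scale(estimated, depths)
    return fit, depths, estimated


def run_eigenworm_compactness(*, n_frames: int = 2000, seed: int = 7,
                              n_modes: int = 4) -> float:
    """Variance captured by the first azimuthal eigenworms of synthetic
    undulatory 3D locomotion, computed through the skeleton->angle path.

    Returns the cumulative explained-variance fraction (0..1).
    """
    params = LocomotionParams(amplitude_rad=0.6, wavelength_bl=1.5,
                              roll_ratio=8.5, angle_noise_rad=0.05, seed=seed)
    loco = generate_locomotion(params, n_frames)
    rows = []
    for pts in loco.skeletons:
        av = skeleton_angles(Skeleton3D(points=pts))
        rows.append(av.theta)
    ensemble = PostureEnsemble(matrix=np.asarray(rows), channel="theta")
    basis = compute_eigenworms(ensemble, max(n_modes, 8))
    return variance_captured(basis, n_modes)
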