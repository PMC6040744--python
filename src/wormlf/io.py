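"""File I/O: TIFF stacks, optics configs, light field containers, skeleton CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .lightfield import LightField4D, OpticalParams
from .midline import N_POINTS, Skeleton3D


def read_tiff(path) -> np.ndarray:
    """Read a single- or multipage grayscale TIFF as float array
    (frames, h, w) or (h, w)."""
    arr = tifffile.imread(str(path))
    return np.asarray(arr, dtype=float)


def write_tiff(path, arr: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.float32))


_OPTICS_KEYS = {
    "pitch_px": "pitch_px",
    "mla_focal_um": "mla_focal_um",
    "magnification": "magnification",
    "pixel_size_um": "pixel_size_um",
    "frame_rate_hz": "frame_rate_hz",
    "aperture_radius_frac": "aperture_radius_frac",
}


def load_optics(path) -> OpticalParams:
    """Optics config from YAML or JSON (keys: pitch_px, mla_focal_um,
    magnification, pixel_size_um, frame_rate_hz[, aperture_radius_frac])."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    kwargs = {dst: data[src] for src, dst in _OPTICS_KEYS.items() if src in data}
    return OpticalParams(**kwargs)


def save_lightfield(path, L: LightField4D) -> None:
    """Persist a 4D light field as an .npz container with a JSON sidecar
    describing shapes and optics."""
    path = Path(path)
    np.savez_compressed(path, radiance=L.radiance, weights=L.weights)
    meta = {
        "shape": list(L.radiance.shape),
        "axes": ["x", "y", "u", "v"],
        "optics": {
            "pitch_px": L.optics.pitch_px,
            "mla_focal_um": L.optics.mla_focal_um,
            "magnification": L.optics.magnification,
            "pixel_size_um": L.optics.pixel_size_um,
            "frame_rate_hz": L.optics.frame_rate_hz,
            "aperture_radius_frac": L.optics.aperture_radius_frac,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_lightfield(path) -> LightField4D:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    optics = OpticalParams(**meta["optics"])
    return LightField4D(radiance=data["radiance"], weights=data["weights"],
                        optics=optics)


def skeletons_to_frame(skeletons: list[Skeleton3D]) -> pd.DataFrame:
    """Long-format table: frame, time_s, point_index, x_um, y_um, z_um."""
    rows = []
    for s in skeletons:
        for i, (x, y, z) in enumerate(s.points):
            rows.append((s.frame_index, s.time_s, i, x, y, z))
    return pd.DataFrame(rows, columns=["frame", "time_s", "point_index",
                                       "x_um", "y_um", "z_um"])


def frame_to_skeletons(df: pd.DataFrame) -> list[Skeleton3D]:
    out = []
    for frame, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("point_index")
        if len(grp) != N_POINTS:
            raise ValueError(f"frame {frame} has {len(grp)} points, expected {N_POINTS}")
        out.append(Skeleton3D(points=grp[["x_um", "y_um", "z_um"]].to_numpy(),
                              frame_index=int(frame),
                              time_s=float(grp["time_s"].iloc[0])))
    return out
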