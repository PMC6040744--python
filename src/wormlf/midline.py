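"""Worm segmentation and 3D midline skeleton extraction.

The worm's lateral footprint is segmented in the on-axis pinhole view
(adaptive thresholding, morphological cleanup, region-based active-contour
refinement).  Depth maps are temporally filtered with a two-frame Kalman
filter, the mask is thinned to a midline, depth is sampled along it, and a
smoothing spline resampled at 26 equally spaced arc-length positions gives
the 25-segment skeleton.  Each segment's orientation is described by an
azimuthal angle theta (in the xy plane) and an elevation angle phi (out of
the xy plane); both angle vectors are mean-zeroed over the body so that the
representation depends only on posture (and roll), not on heading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from skimage import measure, morphology, segmentation

from .depth import DepthMap

N_POINTS = 26  # midline points -> 25 segments


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SegMask:
    """Single-component, hole-free binary footprint of the worm."""

    mask: np.ndarray
    contour: np.ndarray      # ordered boundary points (n, 2) in (row, col)
    area: int


@dataclass
class Skeleton3D:
    """26 ordered 3D midline points (um), nose/head end first."""

    points: np.ndarray
    frame_index: int = 0
    time_s: float = 0.0
    head_known: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_POINTS, 3):
            raise ValueError(f"skeleton must have exactly {N_POINTS} points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("consecutive skeleton points must be distinct")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())

    def length_plausible(self, min_um: float = 200.0, max_um: float = 1500.0) -> bool:
        """Sanity band for an adult worm's total arc length (configurable)."""
        return min_um <= self.length <= max_um


@dataclass
class AngleVectors:
    """Mean-zeroed per-segment azimuth/elevation, with the removed means and
    segment lengths retained so the skeleton can be reintegrated exactly."""

    theta: np.ndarray
    phi: np.ndarray
    mean_theta: float
    mean_phi: float
    segment_lengths: np.ndarray
    origin: np.ndarray


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationParams:
    window: int = 51          # adaptive threshold window (px)
    offset: float = 0.02      # threshold offset below the local mean
    closing_radius: int = 3
    min_area: int = 200
    active_contour_iters: int = 30
    smoothing: int = 1        # morphological ACWE smoothing passes


def segment_worm(image: np.ndarray,
                 params: SegmentationParams = SegmentationParams()) -> SegMask:
    """Segment the (dark) worm in an on-axis view.

    Adaptive local-mean threshold -> largest connected component -> hole fill
    -> morphological closing -> Chan–Vese-type active-contour refinement with
    a fixed iteration budget -> final single-component, hole-free mask.
    Raises ``ValueError("no worm found")`` when nothing of sufficient area
    survives.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    span = image.max() - image.min()
    if span <= 0:
        raise ValueError("no worm found")
    norm = (image - image.min()) / span
    window = min(params.window, 2 * (min(image.shape) // 2) - 1)
    local_mean = ndimage.uniform_filter(norm, size=window, mode="reflect")
    mask = norm < local_mean - params.offset

    def _largest(m: np.ndarray) -> np.ndarray:
        lbl, n = ndimage.label(m)
        if n == 0:
            raise ValueError("no worm found")
        sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        return lbl == (1 + int(np.argmax(sizes)))

    mask = _largest(mask)
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.closing(mask, morphology.disk(params.closing_radius))
    if params.active_contour_iters > 0:
        refined = segmentation.morphological_chan_vese(
            norm, num_iter=params.active_contour_iters, init_level_set=mask,
            smoothing=params.smoothing)
        # the darker phase is the worm
        if refined.any() and norm[refined > 0].mean() > norm[refined == 0].mean():
            refined = 1 - refined
        if refined.any():
            mask = refined > 0
    mask = _largest(mask)
    mask = ndimage.binary_fill_holes(mask)
    area = int(mask.sum())
    if area < params.min_area:
        raise ValueError("no worm found")
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len) if contours else np.empty((0, 2))
    return SegMask(mask=mask, contour=contour, area=area)


# ---------------------------------------------------------------------------
# temporal filtering
# ---------------------------------------------------------------------------

def temporal_kalman(depth_seq: list[DepthMap], *, q: float = 25.0,
                    r: float = 100.0) -> list[DepthMap]:
    """Two-frame temporal Kalman filter on per-pixel depth.

    Constant-position state model using only the current and previous frame:
    the previous measurement (variance r) propagated through process noise q
    is fused with the current measurement (variance r), giving

        x_t = z_{t-1} + K (z_t - z_{t-1}),   K = (r + q) / (2 r + q).

    The first frame passes through unchanged; pixels without a finite value
    in the previous frame also pass through.
    """
    if len(depth_seq) == 0:
        raise ValueError("empty sequence")
    if len(depth_seq) == 1:
        import warnings

        warnings.warn("single frame: temporal Kalman filter is the identity")
        return [depth_seq[0]]
    gain = (r + q) / (2.0 * r + q)
    out = [depth_seq[0]]
    for prev, cur in zip(depth_seq[:-1], depth_seq[1:]):
        if prev.depth.shape != cur.depth.shape:
            raise ValueError("frames must share a common grid")
        both = np.isfinite(prev.depth) & np.isfinite(cur.depth)
        depth = cur.depth.copy()
        depth[both] = prev.depth[both] + gain * (cur.depth[both] - prev.depth[both])
        out.append(DepthMap(depth=depth, confidence=cur.confidence,
                            footprint=cur.footprint & np.isfinite(depth)))
    return out


# ---------------------------------------------------------------------------
# skeletonization helpers
# ---------------------------------------------------------------------------

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    """8-connected pixel graph of a thinned mask: adjacency dict with
    Euclidean step weights."""
    pts = {tuple(p) for p in np.argwhere(skel)}
    adj: dict[tuple[int, int], list[tuple[tuple[int, int], float]]] = {p: [] for p in pts}
    for (y, x) in pts:
        for dy, dx in _NBRS:
            nb = (y + dy, x + dx)
            if nb in pts:
                adj[(y, x)].append((nb, float(np.hypot(dy, dx))))
    return adj


def _endpoints(adj) -> list:
    return [p for p, nbrs in adj.items() if len(nbrs) == 1]


def _junctions(adj) -> set:
    return {p for p, nbrs in adj.items() if len(nbrs) > 2}


def _prune_branches(adj, prune_len: float):
    """Iteratively remove endpoint-to-junction branches shorter than
    ``prune_len`` (graph edited in place)."""
    changed = True
    while changed:
        changed = False
        junctions = _junctions(adj)
        if not junctions:
            return adj
        for ep in list(_endpoints(adj)):
            if ep not in adj:
                continue
            path = [ep]
            length = 0.0
            cur, prev = ep, None
            while True:
                nbrs = [(p, w) for p, w in adj.get(cur, []) if p != prev]
                if cur in junctions or len(nbrs) != 1:
                    break
                nxt, w = nbrs[0]
                length += w
                prev, cur = cur, nxt
                path.append(cur)
            if cur in junctions and length < prune_len:
                for p in path[:-1]:
                    for nb, _ in adj.pop(p, []):
                        if nb in adj:
                            adj[nb] = [(q, w) for q, w in adj[nb] if q != p]
                changed = True
    return adj


def _farthest(adj, start):
    """Dijkstra from ``start``; returns (farthest node, distances, parents)."""
    import heapq

    dist = {start: 0.0}
    parent = {start: None}
    heap = [(0.0, start)]
    while heap:
        d, node = heapq.heappop(heap)
        if d > dist.get(node, np.inf):
            continue
        for nb, w in adj.get(node, []):
            nd = d + w
            if nd < dist.get(nb, np.inf):
                dist[nb] = nd
                parent[nb] = node
                heapq.heappush(heap, (nd, nb))
    far = max(dist, key=dist.get)
    return far, dist, parent


def _longest_path(adj) -> list:
    """Longest geodesic path (double-Dijkstra, exact on trees)."""
    start = next(iter(adj))
    a, _, _ = _farthest(adj, start)
    b, _, parent = _farthest(adj, a)
    path = [b]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path[::-1]


def _has_cycle(adj) -> bool:
    n_edges = sum(len(v) for v in adj.values()) // 2
    # count connected components
    seen = set()
    n_comp = 0
    for p in adj:
        if p in seen:
            continue
        n_comp += 1
        stack = [p]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(nb for nb, _ in adj[cur] if nb not in seen)
    return n_edges > len(adj) - n_comp


# ---------------------------------------------------------------------------
# midline extraction
# ---------------------------------------------------------------------------

def flag_self_occlusion(seg: SegMask, *, prune_len: float = 8.0,
                        overlap_ratio: float = 1.6) -> bool:
    """Heuristic flag for coiled/self-crossing postures.

    True when the thinned skeleton contains a cycle or keeps more than two
    endpoints after pruning short branches, or when the mask area exceeds
    ``overlap_ratio`` times midline length x modal width (material stacked on
    itself).  Flagged frames are excluded from skeletonization.
    """
    skel = morphology.skeletonize(seg.mask)
    if not skel.any():
        return True
    adj = _skeleton_graph(skel)
    if _has_cycle(adj):
        return True
    adj = _prune_branches(adj, prune_len)
    if len(_endpoints(adj)) > 2:
        return True
    path = _longest_path(adj)
    length = sum(np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in zip(path[:-1], path[1:]))
    if length <= 0:
        return True
    dist_tr = ndimage.distance_transform_edt(seg.mask)
    widths = 2.0 * dist_tr[tuple(np.array(path).T)]
    modal_width = float(np.median(widths))
    if modal_width <= 0:
        return True
    return seg.area / (length * modal_width) > overlap_ratio


def extract_midline(seg: SegMask, depth: DepthMap, *, spacing_um: float = 1.0,
                    smoothing: float = 1.0, prune_len: float = 8.0,
                    prev_skeleton: Skeleton3D | None = None,
                    frame_index: int = 0, time_s: float = 0.0) -> Skeleton3D:
    """Extract the 26-point 3D midline skeleton of a segmented worm.

    The mask is thinned; the longest geodesic path between skeleton endpoints
    (after pruning branches shorter than ``prune_len`` px) is the 2D midline.
    Depth along it is the median over the local cross-section (disc of the
    local half-width).  A smoothing spline through the (x, y, z) samples is
    resampled at 26 equally spaced arc-length positions.  Endpoint ordering
    maximizes continuity with ``prev_skeleton`` when given (first frame:
    arbitrary, ``head_known=False``).
    """
    mask = seg.mask
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        import warnings

        warnings.warn("mask touches the image border; skeleton may be clipped")
    skel = morphology.skeletonize(mask)
    adj = _skeleton_graph(skel)
    if not adj:
        raise ValueError("empty skeleton")
    adj = _prune_branches(adj, prune_len)
    if len(_endpoints(adj)) > 2:
        raise ValueError("branched skeleton")
    path = np.array(_longest_path(adj), dtype=float)    # (n, 2) in (row, col)
    if path.shape[0] < 4:
        raise ValueError("midline too short")

    dist_tr = ndimage.distance_transform_edt(mask)
    zs = np.empty(path.shape[0])
    for i, (py, px) in enumerate(path):
        rad = max(dist_tr[int(py), int(px)], 1.0)
        y0, y1 = int(py - rad), int(py + rad) + 1
        x0, x1 = int(px - rad), int(px + rad) + 1
        y0, x0 = max(y0, 0), max(x0, 0)
        local = depth.depth[y0:y1, x0:x1]
        lm = mask[y0:y1, x0:x1] & np.isfinite(local)
        yy, xx = np.mgrid[y0:y0 + local.shape[0], x0:x0 + local.shape[1]]
        lm &= (yy - py) ** 2 + (xx - px) ** 2 <= rad**2
        if np.any(lm):
            zs[i] = np.median(local[lm])
        else:
            zs[i] = np.nan
    if np.any(np.isnan(zs)):
        ok = np.isfinite(zs)
        if not np.any(ok):
            raise ValueError("depth undefined along the midline")
        zs = np.interp(np.arange(zs.size), np.flatnonzero(ok), zs[ok])

    # physical coordinates: x = col, y = row, z from the depth map
    xyz = np.stack([path[:, 1] * spacing_um, path[:, 0] * spacing_um, zs], axis=1)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xyz, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise ValueError("degenerate midline")
    uu = chord / chord[-1]
    # drop duplicate parameter values to keep the spline well posed
    keep = np.concatenate([[True], np.diff(uu) > 1e-12])
    tck, _ = interpolate.splprep(xyz[keep].T, u=uu[keep], s=smoothing * len(uu),
                                 k=min(3, keep.sum() - 1))
    dense_u = np.linspace(0, 1, 20 * N_POINTS)
    dense = np.array(interpolate.splev(dense_u, tck)).T
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    targets = np.linspace(0, arc[-1], N_POINTS)
    pts = np.stack([np.interp(targets, arc, dense[:, k]) for k in range(3)], axis=1)

    head_known = False
    if prev_skeleton is not None:
        straight = np.linalg.norm(pts - prev_skeleton.points, axis=1).sum()
        flipped = np.linalg.norm(pts[::-1] - prev_skeleton.points, axis=1).sum()
        if flipped < straight:
            pts = pts[::-1].copy()
        head_known = prev_skeleton.head_known or True
    return Skeleton3D(points=pts, frame_index=frame_index, time_s=time_s,
                      head_known=head_known)


# ---------------------------------------------------------------------------
# angle representation
# ---------------------------------------------------------------------------

def skeleton_angles(s: Skeleton3D) -> AngleVectors:
    """Per-segment (theta, phi) with the body means removed.

    theta is the azimuth of the segment direction in the xy plane (unwrapped
    along the body before mean-zeroing); phi is the elevation out of the xy
    plane, zero for planar postures.
    """
    d = np.diff(s.points, axis=0)
    lengths = np.linalg.norm(d, axis=1)
    if np.any(lengths == 0):
        raise ValueError("zero-length segment")
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    phi = np.arctan2(d[:, 2], np.hypot(d[:, 0], d[:, 1]))
    return AngleVectors(theta=theta - theta.mean(), phi=phi - phi.mean(),
                        mean_theta=float(theta.mean()), mean_phi=float(phi.mean()),
                        segment_lengths=lengths, origin=s.points[0].copy())


def angles_to_skeleton(av: AngleVectors) -> np.ndarray:
    """Reintegrate angle vectors (with their stored means, lengths and
    origin) into 26 skeleton coordinates; inverse of :func:`skeleton_angles`."""
    theta = av.theta + av.mean_theta
    phi = av.phi + av.mean_phi
    tangents = np.stack([np.cos(phi) * np.cos(theta),
                         np.cos(phi) * np.sin(theta),
                         np.sin(phi)], axis=1)
    pts = np.zeros((theta.size + 1, 3))
    pts[0] = av.origin
    pts[1:] = av.origin + np.cumsum(av.segment_lengths[:, None] * tangents, axis=0)
    return pts
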