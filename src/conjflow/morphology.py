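"""Vessel segmentation, centerline extraction, and FWHM diametry.

Vessels appear as dark ridges on the time-averaged image.  Frangi
vesselness over a scale range covering 6-75 um radii yields a binary mask,
which is thinned to a 1-px skeleton.  The skeleton is cut at bifurcation
points (>= 3 neighbours, 8-connectivity) into individual segments; segments
with centerline arc length of 50 um or less are discarded.  Diameters are
measured as the full width at half maximum of intensity profiles taken
perpendicular to the (smoothed) centerline at stations every 5 px of arc
length.  A temporal variance filter separates segments with detectable
blood flow from stagnant or spurious ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import frangi, threshold_otsu
from skimage.morphology import disk, skeletonize

from .config import DiametryConfig, SegmentationConfig, VarianceFilterConfig
from .io import RegisteredSequence

VESSEL_TYPES = ("arteriole", "venule", "unlabeled")


class DiametryError(RuntimeError):
    """Segment rejected because the diameter profile could not be measured."""


@dataclass
class VesselSegment:
    """One centerline segment with its geometry and diametry results."""

    segment_id: int
    points: np.ndarray                    # (N, 2) ordered (x, y), sub-pixel
    length_um: float
    parent_vessel_id: int = -1            # connected skeleton component
    stations: np.ndarray | None = None    # (M, 2) station centers (x, y)
    diameters_um: np.ndarray | None = None
    mean_diameter_um: float = float("nan")
    boundaries_left: np.ndarray | None = None
    boundaries_right: np.ndarray | None = None
    vessel_type: str = "unlabeled"
    flow_detected: bool = False
    rejection_reason: str = ""

    @property
    def n_stations(self) -> int:
        return 0 if self.diameters_um is None else int(np.sum(np.isfinite(self.diameters_um)))

    def admissible(self, cfg: DiametryConfig | None = None) -> bool:
        """All admission rules: length, diameter range, valid diametry."""
        cfg = cfg or DiametryConfig()
        return (self.length_um > cfg.min_length_um
                and np.isfinite(self.mean_diameter_um)
                and cfg.min_diameter_um <= self.mean_diameter_um <= cfg.max_diameter_um
                and self.n_stations >= cfg.min_valid_stations)


# ---------------------------------------------------------------------------
# Segmentation and skeleton
# ---------------------------------------------------------------------------

def segment_vessels(avg_image: np.ndarray,
                    cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Binary vessel mask from Frangi vesselness of the dark-ridge image."""
    cfg = cfg or SegmentationConfig()
    img = np.asarray(avg_image, dtype=float)
    if cfg.pre_smooth_px > 0:
        img = ndimage.gaussian_filter(img, cfg.pre_smooth_px)
    v = frangi(img, sigmas=cfg.sigmas(), black_ridges=True)
    nz = v[v > 1e-12]
    if nz.size == 0 or nz.max() <= 0:
        return np.zeros(img.shape, dtype=bool)
    thr = cfg.threshold_scale * threshold_otsu(nz)
    mask = v > thr
    mask = _remove_small(mask, cfg.min_object_px)
    if cfg.closing_px > 0:
        mask = ndimage.binary_closing(
            mask, structure=disk(cfg.closing_px), border_value=0)
    mask = ndimage.binary_fill_holes(mask)
    if cfg.boundary_smooth_px > 0:
        # regularize the outline so thinning yields a clean centerline
        mask = ndimage.gaussian_filter(mask.astype(float),
                                       cfg.boundary_smooth_px) > 0.5
        mask = ndimage.binary_fill_holes(mask)
    if cfg.dilate_px > 0:
        mask = ndimage.binary_dilation(mask, structure=disk(cfg.dilate_px))
    mask = _remove_small(mask, cfg.min_object_px)
    return mask


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def extract_centerlines(mask: np.ndarray) -> np.ndarray:
    """1-px-wide 8-connected skeleton of a binary mask (topology-preserving)."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    return skeletonize(mask.astype(bool))


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """8-connected neighbour count at each skeleton pixel (0 elsewhere)."""
    counts = ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant")
    return np.where(skel, counts, 0)


def find_bifurcations(skel: np.ndarray) -> np.ndarray:
    """(N, 2) array of (x, y) skeleton pixels with >= 3 neighbours."""
    counts = neighbor_counts(skel)
    ys, xs = np.nonzero(counts >= 3)
    return np.column_stack([xs, ys])


def _trace_path(pixels: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order a connected set of degree-<=2 skeleton pixels into a path."""
    if not pixels:
        return []
    neigh = {}
    for (y, x) in pixels:
        nb = [(y + dy, x + dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
              if (dy or dx) and (y + dy, x + dx) in pixels]
        neigh[(y, x)] = nb
    ends = [p for p, nb in neigh.items() if len(nb) <= 1]
    start = min(ends) if ends else min(pixels)  # cycles: deterministic cut
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [p for p in neigh[cur] if p not in seen]
        if not nxt:
            break
        # prefer 4-connected continuation for stable arc lengths on staircases
        nxt.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1]), p))
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return path


def _path_length_px(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.hypot(*np.diff(path, axis=0).T).sum())


def find_bifurcations_and_split(skel: np.ndarray, pixel_size_um: float,
                                min_length_um: float = 50.0,
                                prune_px: int = 0):
    """Cut the skeleton at bifurcation points into individual segments.

    Returns ``(segments, n_discarded)`` where segments with arc length
    <= ``min_length_um`` are discarded (and counted), and each surviving
    segment carries the id of its parent connected skeleton component so
    that multiple measurements of one vessel can be de-duplicated later.
    Spurs shorter than ``prune_px`` are removed before splitting.
    """
    skel = skel.astype(bool)
    if not skel.any():
        return [], 0

    if prune_px > 0:
        skel = _prune_spurs(skel, prune_px)
        if not skel.any():
            return [], 0

    counts = neighbor_counts(skel)
    branch = counts >= 3
    parent_labels, _ = ndimage.label(skel, structure=np.ones((3, 3)))

    cut = skel & ~branch
    labels, n_comp = ndimage.label(cut, structure=np.ones((3, 3)))

    segments: list[VesselSegment] = []
    discarded = 0
    sid = 0
    branch_set = {(int(y), int(x)) for y, x in zip(*np.nonzero(branch))}
    for comp in range(1, n_comp + 1):
        ys, xs = np.nonzero(labels == comp)
        pixset = set(zip(ys.tolist(), xs.tolist()))
        ordered = _trace_path(pixset)
        if not ordered:
            continue
        # re-attach adjacent bifurcation pixels so segment endpoints sit on them
        for end_idx in (0, -1):
            ey, ex = ordered[end_idx]
            adj = [(by, bx) for (by, bx) in branch_set
                   if abs(by - ey) <= 1 and abs(bx - ex) <= 1]
            if adj:
                adj.sort(key=lambda p: (abs(p[0] - ey) + abs(p[1] - ex), p))
                if end_idx == 0:
                    ordered.insert(0, adj[0])
                else:
                    ordered.append(adj[0])
        arr = np.array(ordered, dtype=float)
        pts = arr[:, ::-1].copy()          # (y, x) -> (x, y)
        length_um = _path_length_px(arr) * pixel_size_um
        if length_um <= min_length_um:
            discarded += 1
            continue
        parent = int(parent_labels[ordered[len(ordered) // 2]])
        segments.append(VesselSegment(segment_id=sid, points=pts,
                                      length_um=length_um,
                                      parent_vessel_id=parent))
        sid += 1
    return segments, discarded


def _prune_spurs(skel: np.ndarray, prune_px: int) -> np.ndarray:
    """Remove endpoint branches that reach a bifurcation within ``prune_px``.

    Only true spurs (endpoint-to-branch-point twigs) are deleted; free ends
    of unbranched centerlines are never eroded.  Iterates until stable since
    removing a spur can down-grade its bifurcation to a plain path pixel.
    """
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        counts = neighbor_counts(skel)
        if not (counts >= 3).any():
            break
        pixset = {(int(y), int(x)) for y, x in np.argwhere(skel)}
        deg = {p: counts[p] for p in pixset}
        for ep in [p for p in pixset if deg[p] == 1]:
            if ep not in pixset:
                continue
            path = [ep]
            prev, cur = None, ep
            hit_branch = False
            for _ in range(prune_px):
                nbrs = [(cur[0] + dy, cur[1] + dx)
                        for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                        if (dy or dx) and (cur[0] + dy, cur[1] + dx) in pixset
                        and (cur[0] + dy, cur[1] + dx) != prev]
                if any(deg[p] >= 3 for p in nbrs):
                    hit_branch = True
                    break
                if len(nbrs) != 1:
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
            if hit_branch:
                for p in path:
                    skel[p] = False
                    pixset.discard(p)
                changed = True
    return skel


# ---------------------------------------------------------------------------
# Centerline resampling and FWHM diametry
# ---------------------------------------------------------------------------

def resample_centerline(points: np.ndarray, step_px: float = 1.0,
                        smoothing_sigma_px: float = 2.0) -> np.ndarray:
    """Resample an ordered (x, y) polyline at uniform arc-length steps."""
    pts = np.asarray(points, dtype=float)
    if smoothing_sigma_px > 0 and len(pts) > 4:
        pts = np.column_stack([
            ndimage.gaussian_filter1d(pts[:, 0], smoothing_sigma_px, mode="nearest"),
            ndimage.gaussian_filter1d(pts[:, 1], smoothing_sigma_px, mode="nearest"),
        ])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return pts[:1]
    s = np.arange(0.0, cum[-1] + step_px / 2, step_px)
    return np.column_stack([np.interp(s, cum, pts[:, 0]),
                            np.interp(s, cum, pts[:, 1])])


def _tangents(line: np.ndarray) -> np.ndarray:
    grad = np.gradient(line, axis=0)
    norms = np.linalg.norm(grad, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return grad / norms


def _fwhm_crossings(u: np.ndarray, depth: np.ndarray):
    """Half-maximum crossing positions around the deepest point, or None."""
    k = int(np.argmax(depth))
    peak = depth[k]
    if peak <= 0:
        return None
    half = peak / 2.0
    left = right = None
    for i in range(k, 0, -1):
        if depth[i - 1] < half <= depth[i]:
            f = (depth[i] - half) / (depth[i] - depth[i - 1])
            left = u[i] - f * (u[i] - u[i - 1])
            break
    for i in range(k, len(depth) - 1):
        if depth[i + 1] < half <= depth[i]:
            f = (depth[i] - half) / (depth[i] - depth[i + 1])
            right = u[i] + f * (u[i + 1] - u[i])
            break
    if left is None or right is None:
        return None
    return left, right


def measure_diameter(segment: VesselSegment, avg_image: np.ndarray,
                     pixel_size_um: float,
                     cfg: DiametryConfig | None = None) -> VesselSegment:
    """FWHM diametry at stations every 5 px along the resampled centerline.

    At each station the intensity profile perpendicular to the local tangent
    is sampled by bilinear interpolation, inverted, and referenced to the
    median of its outer tails; the station diameter is the distance between
    the two half-maximum crossings.  Stations without two crossings are
    dropped.  Raises :class:`DiametryError` (and records the reason on the
    segment) if fewer than ``cfg.min_valid_stations`` stations survive.
    """
    cfg = cfg or DiametryConfig()
    img = np.asarray(avg_image, dtype=float)
    h, w = img.shape

    line = resample_centerline(segment.points, step_px=1.0,
                               smoothing_sigma_px=cfg.smoothing_sigma_px)
    tang = _tangents(line)
    idx = np.arange(0, len(line), int(round(cfg.station_spacing_px)))

    half_len_px = cfg.profile_half_length_um / pixel_size_um
    u = np.arange(-half_len_px, half_len_px + cfg.profile_step_px / 2,
                  cfg.profile_step_px)
    n_tail = max(int(len(u) * cfg.tail_fraction / 2), 2)

    stations, diams, lefts, rights = [], [], [], []
    for i in idx:
        cx, cy = line[i]
        tx, ty = tang[i]
        nx, ny = -ty, tx                      # unit normal
        xs = cx + u * nx
        ys = cy + u * ny
        if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
            continue
        prof = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
        background = np.median(np.concatenate([prof[:n_tail], prof[-n_tail:]]))
        depth = background - prof
        if background <= 0 or depth.max() < cfg.min_depth_frac * background:
            continue
        crossings = _fwhm_crossings(u, depth)
        if crossings is None:
            continue
        lo, hi = crossings
        stations.append((cx, cy))
        diams.append((hi - lo) * pixel_size_um)
        lefts.append((cx + lo * nx, cy + lo * ny))
        rights.append((cx + hi * nx, cy + hi * ny))

    if len(diams) < cfg.min_valid_stations:
        segment.rejection_reason = "diametry failed"
        raise DiametryError(
            f"segment {segment.segment_id}: only {len(diams)} valid diameter "
            f"stations (need >= {cfg.min_valid_stations})")

    segment.stations = np.array(stations)
    segment.diameters_um = np.array(diams)
    segment.mean_diameter_um = float(np.mean(diams))
    segment.boundaries_left = np.array(lefts)
    segment.boundaries_right = np.array(rights)
    return segment


# ---------------------------------------------------------------------------
# Flow detection and vessel-type labels
# ---------------------------------------------------------------------------

def filter_by_variance(segments: list[VesselSegment],
                       registered: RegisteredSequence,
                       mask: np.ndarray,
                       cfg: VarianceFilterConfig | None = None) -> list[VesselSegment]:
    """Set ``flow_detected`` by comparing centerline temporal variance to background.

    Background variance is the median temporal variance over pixels outside
    the dilated vessel mask (within the registration-valid region).
    """
    cfg = cfg or VarianceFilterConfig()
    frames = registered.frames
    varmap = frames.var(axis=0)
    h, w = varmap.shape
    bg_region = ~ndimage.binary_dilation(mask, iterations=cfg.dilate_px)
    if registered.valid_mask is not None:
        bg_region &= registered.valid_mask
    bg_var = float(np.median(varmap[bg_region])) if bg_region.any() else 0.0

    for seg in segments:
        line = resample_centerline(seg.points, step_px=1.0, smoothing_sigma_px=0)
        xs = np.clip(np.round(line[:, 0]).astype(int), 0, w - 1)
        ys = np.clip(np.round(line[:, 1]).astype(int), 0, h - 1)
        seg_var = float(varmap[ys, xs].mean())
        seg.flow_detected = seg_var > max(cfg.factor * bg_var, 1e-12)
    return segments


def label_vessel_type(segment: VesselSegment,
                      annotations: dict | None = None) -> VesselSegment:
    """Attach a human/ground-truth arteriole-or-venule label.

    ``annotations`` maps segment id (or parent vessel id as fallback) to a
    label; no automatic classifier is attempted.  Unlabeled segments stay
    "unlabeled" and are excluded from type-stratified statistics.
    """
    label = None
    if annotations:
        label = annotations.get(segment.segment_id,
                                annotations.get(segment.parent_vessel_id))
    if label is None:
        segment.vessel_type = "unlabeled"
        return segment
    if label not in ("arteriole", "venule"):
        raise ValueError(f"unknown vessel type label {label!r}; "
                         "expected 'arteriole' or 'venule'")
    segment.vessel_type = label
    return segment
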