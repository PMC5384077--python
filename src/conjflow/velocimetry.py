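"""Spatio-temporal image (kymograph) construction and band-slope velocimetry.

Intensity is sampled along each flow-detected centerline at 1-px arc-length
steps in every registered frame, giving a (stations x frames) matrix.
Moving red blood cells form oblique bands; their slope in px/frame is the
axial speed.  The slope is found by a projection-variance (Radon-criterion)
search: for each candidate slope the kymograph is sheared so candidate
bands become horizontal rays, and the between-ray mean square of ray means
is scored.  The search grid is uniform in slope (not angle) because the
score peak has roughly constant width in slope units, set by the texture
correlation length over the frame count; a uniform angle grid would
undersample steep bands (fast flow).  A coarse pass is refined by a fine
grid and parabolic interpolation.

V (mm/s) = |slope| * arc_step_um / frame_interval_s / 1000, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import VelocimetryConfig
from .io import RegisteredSequence
from .morphology import VesselSegment, resample_centerline


class VelocimetryError(RuntimeError):
    pass


@dataclass
class STImage:
    """Kymograph matrix plus the slope/velocity estimated from it."""

    data: np.ndarray                  # (stations, frames), detrended
    arc_step_um: float
    frame_interval_s: float
    segment_id: int = -1
    slope_px_per_frame: float | None = None   # signed
    velocity_mm_s: float | None = None        # magnitude
    quality: float | None = None
    reliable: bool | None = None
    aliased: bool = False

    @property
    def n_stations(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def build_sti(registered: RegisteredSequence, segment: VesselSegment,
              cfg: VelocimetryConfig | None = None) -> STImage:
    """Sample the registered stack along the centerline into an STImage.

    Stations falling outside the registration-valid mask are truncated from
    the ends; fewer than ``cfg.min_stations`` remaining stations rejects the
    segment ("too short for velocimetry").  Rows and columns are
    mean-subtracted (two-way detrending) before slope estimation.
    """
    cfg = cfg or VelocimetryConfig()
    frames = registered.frames
    _, h, w = frames.shape
    line = resample_centerline(segment.points, step_px=1.0)
    xs, ys = line[:, 0], line[:, 1]
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if registered.valid_mask is not None:
        xi = np.clip(np.round(xs).astype(int), 0, w - 1)
        yi = np.clip(np.round(ys).astype(int), 0, h - 1)
        inside &= registered.valid_mask[yi, xi]
    # truncate to the longest run of in-mask stations
    if not inside.all():
        best_len, best_start, start = 0, 0, None
        for i, ok in enumerate([*inside, False]):
            if ok and start is None:
                start = i
            elif not ok and start is not None:
                if i - start > best_len:
                    best_len, best_start = i - start, start
                start = None
        line = line[best_start:best_start + best_len]
        xs, ys = line[:, 0], line[:, 1]

    if len(line) < cfg.min_stations:
        raise VelocimetryError(
            f"segment {segment.segment_id}: too short for velocimetry "
            f"({len(line)} stations, need >= {cfg.min_stations})")

    sti = np.empty((len(line), len(frames)))
    for t, frame in enumerate(frames):
        sti[:, t] = ndimage.map_coordinates(frame, [ys, xs], order=1,
                                            mode="nearest")
    detrended = (sti - sti.mean(axis=1, keepdims=True)
                 - sti.mean(axis=0, keepdims=True) + sti.mean())
    return STImage(data=detrended,
                   arc_step_um=1.0 * registered.pixel_size_um,
                   frame_interval_s=registered.frame_interval_s,
                   segment_id=segment.segment_id)


def _shear_scores(data: np.ndarray, slopes: np.ndarray, min_count: int) -> np.ndarray:
    """Band-alignment score per candidate slope: an ANOVA F-ratio.

    For slope m, ray s0 collects samples data[s0 + m*t, t]; the score is the
    between-ray mean square over the within-ray mean square.  Under white
    noise its expectation is ~1 for every m (no envelope in |m|, unlike a
    raw variance of ray means whose ray count grows with slope); when the
    candidate matches the band slope the within-ray variance collapses and
    the ratio peaks sharply.
    """
    S, T = data.shape
    t = np.arange(T)
    mask_src = np.ones_like(data)
    scores = np.full(len(slopes), np.nan)
    for k, m in enumerate(slopes):
        off = m * t
        s0 = np.arange(np.floor(-off.max() if m > 0 else 0) - 1,
                       S + (-off.min() if m < 0 else 0) + 1)
        rows = s0[:, None] + off[None, :]
        cols = np.broadcast_to(t, rows.shape).astype(float)
        vals = ndimage.map_coordinates(data, [rows, cols], order=1,
                                       mode="constant", cval=0.0)
        cnts = ndimage.map_coordinates(mask_src, [rows, cols], order=1,
                                       mode="constant", cval=0.0)
        good = cnts > 0.99          # full in-bounds samples only
        counts = good.sum(axis=1)
        ray_ok = counts >= min_count
        n_rays = int(ray_ok.sum())
        n_total = int(counts[ray_ok].sum())
        if n_rays < 3 or n_total <= n_rays:
            continue
        v = np.where(good, vals, 0.0)[ray_ok]
        cnt = counts[ray_ok]
        sums = v.sum(axis=1)
        means = sums / cnt
        grand = sums.sum() / n_total
        ss_between = (cnt * (means - grand) ** 2).sum()
        ss_within = (v ** 2 * good[ray_ok]).sum() - (cnt * means ** 2).sum()
        ms_between = ss_between / (n_rays - 1)
        ms_within = ss_within / (n_total - n_rays)
        scores[k] = ms_between / max(ms_within, 1e-300)
    return scores


def _parabolic_peak(x: np.ndarray, y: np.ndarray, k: int) -> float:
    if k == 0 or k == len(x) - 1:
        return float(x[k])
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0 or not np.isfinite(denom):
        return float(x[k])
    delta = 0.5 * (y0 - y2) / denom
    return float(x[k] + np.clip(delta, -1, 1) * (x[k + 1] - x[k]))


def estimate_band_slope(sti: STImage,
                        cfg: VelocimetryConfig | None = None) -> STImage:
    """Estimate the band slope and axial velocity of a detrended kymograph.

    Raises :class:`VelocimetryError` on an all-zero kymograph ("no
    detectable bands").  Results whose orientation-criterion contrast falls
    below ``cfg.quality_floor`` are flagged unreliable.  Slopes at the
    aliasing ceiling |m| >= (stations - 1)/2 are flagged ``aliased``.
    """
    cfg = cfg or VelocimetryConfig()
    data = sti.data
    S, T = data.shape
    if S < cfg.min_stations or T < cfg.min_frames:
        raise VelocimetryError("kymograph too small for slope estimation")
    scale = np.abs(data).max()
    if scale < 1e-9:
        raise VelocimetryError("no detectable bands")

    ceiling = (S - 1) / 2.0
    mmax = min(cfg.max_slope, ceiling)
    coarse = np.arange(-mmax, mmax + cfg.coarse_step / 2, cfg.coarse_step)
    scores = _shear_scores(data, coarse, cfg.min_ray_count)
    if not np.isfinite(scores).any():
        raise VelocimetryError("no detectable bands")
    k = int(np.nanargmax(scores))

    fine_step = cfg.coarse_step / cfg.fine_factor
    lo = max(coarse[k] - cfg.coarse_step, -mmax)
    hi = min(coarse[k] + cfg.coarse_step, mmax)
    fine = np.arange(lo, hi + fine_step / 2, fine_step)
    fine_scores = _shear_scores(data, fine, cfg.min_ray_count)
    kf = int(np.nanargmax(fine_scores))
    slope = _parabolic_peak(fine, fine_scores, kf)

    finite = scores[np.isfinite(scores)]
    med = float(np.median(finite))
    quality = float((np.nanmax(fine_scores) - med) / med) if med > 0 else np.inf

    sti.slope_px_per_frame = float(slope)
    sti.velocity_mm_s = (abs(slope) * sti.arc_step_um
                         / sti.frame_interval_s / 1000.0)
    sti.quality = quality
    sti.reliable = quality >= cfg.quality_floor
    sti.aliased = abs(slope) >= ceiling - cfg.coarse_step
    return sti


def measure_velocity(registered: RegisteredSequence, segment: VesselSegment,
                     cfg: VelocimetryConfig | None = None) -> STImage:
    """Build the kymograph and estimate V for one segment."""
    return estimate_band_slope(build_sti(registered, segment, cfg), cfg)
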