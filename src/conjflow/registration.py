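"""Frame-quality screening, run selection, and translational registration.

The screen rejects frames with blinks (outlying mean intensity), large eye
motion (low correlation with the previous valid frame) or illumination
artifacts (strong fitted planar gradient).  The longest consecutive run of
valid frames is then registered to its middle frame by sub-pixel
translation (phase cross-correlation), and a time-averaged image is formed
for the morphological stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .config import QualityConfig, RegistrationConfig
from .io import ImageSequence, RegisteredSequence


class NoUsableFramesError(RuntimeError):
    """Raised when every frame of a sequence fails the quality screen."""


def _plane_gradient_span(frame: np.ndarray, step: int = 4) -> float:
    """Total variation across the frame of the least-squares fitted plane."""
    sub = frame[::step, ::step]
    h, w = sub.shape
    yy, xx = np.mgrid[0:h, 0:w]
    A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
    coef, *_ = np.linalg.lstsq(A, sub.ravel(), rcond=None)
    return abs(coef[0]) * (w - 1) + abs(coef[1]) * (h - 1)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 1.0
    return float((a * b).sum() / denom)


def score_frame_quality(seq: ImageSequence,
                        thresholds: QualityConfig | None = None) -> pd.DataFrame:
    """Flag each frame as valid/invalid with the failing criterion recorded.

    Returns a DataFrame with columns ``frame``, ``valid``, ``reason``
    (empty, "blink", "motion" or "illumination"), plus the raw statistics.
    Raises :class:`NoUsableFramesError` if no frame survives.
    """
    cfg = thresholds or QualityConfig()
    frames = seq.frames
    T = len(frames)
    if T == 0:
        raise NoUsableFramesError("empty sequence")

    means = frames.mean(axis=(1, 2))
    med = np.median(means)
    mad = np.median(np.abs(means - med))
    scale = 1.4826 * mad
    z = np.zeros(T) if scale == 0 else (means - med) / scale

    valid = np.ones(T, dtype=bool)
    reason = [""] * T
    zed = [0.0] * T
    corr = np.full(T, np.nan)
    grad = np.zeros(T)

    for t in range(T):
        zed[t] = float(z[t])
        if abs(z[t]) > cfg.blink_z:
            valid[t] = False
            reason[t] = "blink"

    median_intensity = float(np.median(frames[valid])) if valid.any() else 1.0
    prev_valid = None
    for t in range(T):
        if not valid[t]:
            continue
        grad[t] = _plane_gradient_span(frames[t])
        if median_intensity > 0 and grad[t] > cfg.illum_frac * median_intensity:
            valid[t] = False
            reason[t] = "illumination"
            continue
        if prev_valid is not None:
            # motion check against a coarse version of the previous valid frame
            corr[t] = _ncc(frames[t][::2, ::2], frames[prev_valid][::2, ::2])
            if corr[t] < cfg.motion_corr:
                valid[t] = False
                reason[t] = "motion"
                continue
        prev_valid = t

    if not valid.any():
        raise NoUsableFramesError("no usable frames after quality screening")

    return pd.DataFrame({"frame": np.arange(T), "valid": valid, "reason": reason,
                         "mean_z": zed, "ncc_prev": corr, "gradient_span": grad})


def longest_valid_run(flags) -> tuple[int, int]:
    """Maximal run of consecutive valid frames; ties broken by earliest start.

    ``flags`` may be a boolean array or the DataFrame from
    :func:`score_frame_quality`.  Returns the inclusive ``(first, last)``
    index range.
    """
    if isinstance(flags, pd.DataFrame):
        flags = flags["valid"].to_numpy()
    flags = np.asarray(flags, dtype=bool)
    if not flags.any():
        raise NoUsableFramesError("no usable frames")
    best = (0, -1)  # (length, start)
    start = None
    for i, ok in enumerate([*flags, False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            length = i - start
            if length > best[0]:
                best = (length, start)
            start = None
    return best[1], best[1] + best[0] - 1


def register(seq: ImageSequence, run: tuple[int, int],
             cfg: RegistrationConfig | None = None) -> RegisteredSequence:
    """Register the frames of ``run`` to the run's middle frame.

    Each frame is aligned by a single sub-pixel 2-D translation found by
    phase cross-correlation.  The time-averaged image is the pixel-wise mean
    of the registered run; ``valid_mask`` excludes the border band
    invalidated by the largest shift (borders are filled by edge
    replication during shifting).
    """
    cfg = cfg or RegistrationConfig()
    first, last = run
    if last < first:
        raise ValueError("empty frame run")
    if first < 0 or last >= seq.n_frames:
        raise ValueError("frame run out of bounds")

    frames = seq.frames[first:last + 1]
    n = len(frames)
    ref_local = n // 2
    h, w = frames[0].shape
    max_allowed = cfg.max_shift_frac * w

    # Shifts are estimated against the run mean rather than a single frame:
    # the moving red-blood-cell texture averages out of the mean, so the
    # correlation locks onto the static vascular pattern.  A second pass
    # against the registered mean refines when the raw mean is motion-blurred.
    translations = np.zeros((n, 2))
    oversized: list[int] = []
    target = frames.mean(axis=0)
    for _pass in range(cfg.n_passes):
        registered = np.empty_like(frames)
        oversized = []
        for i in range(n):
            shift, _, _ = phase_cross_correlation(
                target, frames[i], upsample_factor=cfg.upsample_factor,
                normalization=None)
            # an implausibly large shift means the correlation locked onto
            # something other than the static vasculature; report the frame
            # and leave it unshifted rather than corrupt the average
            if np.abs(shift).max() > max_allowed:
                oversized.append(first + i)
                shift = np.zeros(2)
            translations[i] = shift
            registered[i] = ndimage.shift(frames[i], shift, order=1,
                                          mode="nearest")
        target = registered.mean(axis=0)

    # re-zero so the reference (middle) frame carries translation (0, 0)
    translations = translations - translations[ref_local]
    registered = np.empty_like(frames)
    for i in range(n):
        if np.abs(translations[i]).max() < 1e-12:
            registered[i] = frames[i]
        else:
            registered[i] = ndimage.shift(frames[i], translations[i], order=1,
                                          mode="nearest")

    avg = registered.mean(axis=0)
    margin = int(np.ceil(np.abs(translations).max())) if n > 1 else 0
    mask = np.zeros((h, w), dtype=bool)
    mask[margin:h - margin or None, margin:w - margin or None] = True

    out = RegisteredSequence(frames=registered, run=(first, last),
                             translations=translations,
                             reference_index=first + ref_local,
                             time_averaged=avg, valid_mask=mask,
                             pixel_size_um=seq.pixel_size_um,
                             frame_interval_s=seq.frame_interval_s)
    out.oversized_shift_frames = oversized  # type: ignore[attr-defined]
    return out


def register_sequence(seq: ImageSequence,
                      quality: QualityConfig | None = None,
                      cfg: RegistrationConfig | None = None):
    """Screen, select the longest valid run, and register, in one call."""
    report = score_frame_quality(seq, quality)
    run = longest_valid_run(report)
    return register(seq, run, cfg), report
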