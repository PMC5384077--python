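"""Synthetic microvascular scenes and cohorts with known ground truth.

Two generators make the whole pipeline testable without patient data:

``render_sequence``
    Renders a one-second image sequence of dark tubular vessels on a bright
    background.  Each vessel carries a frozen 1-D intensity texture (the
    red-blood-cell / plasma-gap pattern) advected along its centerline at a
    known velocity, so kymograph velocimetry has an exact target.  The
    cross-section is an inverted flattened-Gaussian tube whose full width at
    half maximum equals the requested diameter exactly, so FWHM diametry has
    an analytic target.  Whole-frame jitter, blink frames, illumination
    gradients and sensor noise emulate the acquisition artifacts the
    registration stage must screen and correct.

``simulate_cohort``
    Draws vessel-level descriptor tables with per-subject random intercepts
    and Gaussian residuals (y_ij = mu_g + b_i + eps_ij), plus a subject
    covariate table, for testing the group-comparison statistics.

All randomness comes from one ``numpy.random.Generator`` seeded per call;
rendering is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import ImageSequence, VALID_GROUPS

_LN2 = math.log(2.0)
_PROFILE_EXPONENT = 4  # flattened tube; FWHM == diameter for any exponent


class SceneValidationError(ValueError):
    pass


@dataclass
class VesselSpec:
    """One simulated vessel: geometry, size, flow and appearance."""

    points: np.ndarray                 # (N, 2) control points, columns (x, y), px
    diameter_um: float
    velocity_mm_s: float = 0.0         # signed along the parametrization
    contrast: float = 0.55             # fractional intensity drop at the axis
    texture_corr_um: float = 10.0      # correlation length of the RBC texture
    texture_amplitude: float = 0.5
    vessel_type: str = "unlabeled"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise SceneValidationError("vessel needs >= 2 (x, y) control points")
        if not 6.0 <= self.diameter_um <= 75.0:
            raise SceneValidationError(
                f"diameter {self.diameter_um} um outside the measurable 6-75 um range")
        if not 0 < self.contrast < 1:
            raise SceneValidationError("contrast must be in (0, 1)")
        if self.vessel_type not in ("arteriole", "venule", "unlabeled"):
            raise SceneValidationError(f"unknown vessel type {self.vessel_type!r}")


@dataclass
class SceneSpec:
    """A full field: geometry of all vessels plus acquisition artifacts."""

    shape: tuple[int, int] = (128, 256)    # (H, W) px
    pixel_size_um: float = 1.25
    n_frames: int = 50
    frame_rate_hz: float = 50.0
    background: float = 180.0
    noise_sd: float = 0.0
    illumination_gradient: float = 0.0     # static plane span, fraction of background
    jitter_offsets: np.ndarray | None = None   # (T, 2) explicit (dy, dx)
    jitter_amplitude_px: float = 0.0           # random integer jitter if no offsets
    blink_frames: tuple[int, ...] = ()
    blink_level: float = 0.10              # blink frames render at this x background
    illum_frames: tuple[int, ...] = ()     # frames with an injected strong gradient
    illum_frame_amplitude: float = 0.5
    vessels: list[VesselSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 64 or w < 64:
            raise SceneValidationError("field must be at least 64 x 64 px")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise SceneValidationError("frame rate and pixel size must be positive")
        if self.n_frames < 1:
            raise SceneValidationError("need at least one frame")
        for idx in (*self.blink_frames, *self.illum_frames):
            if not 0 <= idx < self.n_frames:
                raise SceneValidationError(f"artifact frame index {idx} out of range")
        if self.jitter_offsets is not None:
            self.jitter_offsets = np.asarray(self.jitter_offsets, dtype=float)
            if self.jitter_offsets.shape != (self.n_frames, 2):
                raise SceneValidationError("jitter_offsets must be (n_frames, 2)")


def _dense_centerline(points: np.ndarray, step: float = 0.25):
    """Resample a control polyline at uniform arc-length steps (px)."""
    seglen = np.hypot(*np.diff(points, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    s = np.arange(0.0, total + step / 2, step)
    x = np.interp(s, cum, points[:, 0])
    y = np.interp(s, cum, points[:, 1])
    return np.column_stack([x, y]), s, total


def render_sequence(scene: SceneSpec, seed: int = 0):
    """Render a scene to an :class:`ImageSequence` plus a ground-truth table.

    Returns ``(sequence, truth)`` where ``truth`` has one row per vessel:
    vessel id, true diameter (um), true axial velocity (mm/s), centerline
    length (um), vessel type and the per-frame texture displacement in px.
    Raises :class:`SceneValidationError` when a vessel leaves the field or
    its per-frame displacement would alias at the stated frame rate.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.shape
    T = scene.n_frames
    px = scene.pixel_size_um
    dt = 1.0 / scene.frame_rate_hz

    yy, xx = np.mgrid[0:h, 0:w]
    plane = np.ones((h, w))
    if scene.illumination_gradient:
        gx = scene.illumination_gradient
        plane = plane + gx * (xx / max(w - 1, 1) - 0.5)
    base = scene.background * plane

    # Per-vessel static maps: distance to centerline and arc-length coordinate.
    vessel_maps = []
    truth_rows = []
    for vid, v in enumerate(scene.vessels):
        dense, s_dense, total_px = _dense_centerline(v.points)
        half_px = 0.5 * v.diameter_um / px
        support = 2.2 * half_px
        lo = dense.min(axis=0) - support
        hi = dense.max(axis=0) + support
        if lo[0] < -0.5 or lo[1] < -0.5 or hi[0] > w - 0.5 or hi[1] > h - 0.5:
            # tube may extend past the border; only reject if the axis itself leaves
            if (dense[:, 0].min() < 0 or dense[:, 1].min() < 0
                    or dense[:, 0].max() > w - 1 or dense[:, 1].max() > h - 1):
                raise SceneValidationError(f"vessel {vid} centerline leaves the field")
        disp_px = v.velocity_mm_s * 1000.0 * dt / px   # texture shift per frame
        if abs(disp_px) >= 0.5 * total_px:
            raise SceneValidationError(
                f"vessel {vid}: displacement {disp_px:.1f} px/frame aliases over a "
                f"{total_px:.0f} px centerline")

        x0 = max(int(np.floor(lo[0])), 0)
        x1 = min(int(np.ceil(hi[0])) + 1, w)
        y0 = max(int(np.floor(lo[1])), 0)
        y1 = min(int(np.ceil(hi[1])) + 1, h)
        pix = np.column_stack([xx[y0:y1, x0:x1].ravel(), yy[y0:y1, x0:x1].ravel()])
        tree = cKDTree(dense)
        dist, idx = tree.query(pix, workers=1)
        near = dist <= support
        rows = pix[near, 1]
        cols = pix[near, 0]
        r = dist[near]
        s_at = s_dense[idx[near]]
        profile = np.exp(-_LN2 * (r / half_px) ** _PROFILE_EXPONENT)

        # frozen texture covering every arc position sampled over the sequence
        smin = -max(disp_px, 0.0) * (T - 1) - 10.0
        smax = total_px + max(-disp_px, 0.0) * (T - 1) + 10.0
        grid = np.arange(smin, smax + 1.0, 0.5)
        raw = rng.standard_normal(grid.size)
        corr_px = max(v.texture_corr_um / px, 0.5)
        tex = ndimage.gaussian_filter1d(raw, sigma=corr_px / 0.5, mode="wrap")
        tex = tex - tex.mean()
        sd = tex.std()
        if sd > 0:
            tex = np.clip(tex / sd, -1.8, 1.8)

        vessel_maps.append((rows, cols, r, s_at, profile, grid, tex, disp_px, v))
        truth_rows.append({
            "vessel_id": vid,
            "diameter_um": v.diameter_um,
            "velocity_mm_s": v.velocity_mm_s,
            "length_um": total_px * px,
            "vessel_type": v.vessel_type,
            "displacement_px_per_frame": disp_px,
        })

    if scene.jitter_offsets is not None:
        jitter = scene.jitter_offsets
    elif scene.jitter_amplitude_px > 0:
        amp = int(round(scene.jitter_amplitude_px))
        jitter = rng.integers(-amp, amp + 1, size=(T, 2)).astype(float)
        jitter[0] = 0.0
    else:
        jitter = np.zeros((T, 2))

    frames = np.empty((T, h, w))
    blink = set(scene.blink_frames)
    illum = set(scene.illum_frames)
    for t in range(T):
        if t in blink:
            frames[t] = scene.blink_level * scene.background
        else:
            img = base.copy()
            if t in illum:
                img = img * (1.0 + scene.illum_frame_amplitude
                             * (xx / max(w - 1, 1) - 0.5))
            atten = np.ones((h, w))
            for rows, cols, r, s_at, profile, grid, tex, disp_px, v in vessel_maps:
                texval = np.interp(s_at - disp_px * t, grid, tex)
                drop = np.clip(v.contrast * profile * (1.0 + v.texture_amplitude
                                                       * texval), 0.0, 0.98)
                np.multiply.at(atten, (rows, cols), 1.0 - drop)
            img = img * atten
            if jitter[t].any():
                img = ndimage.shift(img, jitter[t], order=1, mode="nearest")
            frames[t] = img
        if scene.noise_sd > 0:
            frames[t] = frames[t] + rng.normal(0.0, scene.noise_sd, size=(h, w))
    np.clip(frames, 0.0, None, out=frames)

    seq = ImageSequence(frames, pixel_size_um=px, frame_interval_s=dt,
                        source=f"synthetic(seed={seed})")
    truth = pd.DataFrame(truth_rows)
    truth.attrs["jitter_offsets"] = jitter.tolist()
    return seq, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

# Per-group covariate distributions of the study population (mean, SD) and
# category proportions; used as simulation inputs.
DEFAULT_COVARIATES = {
    "C":    {"age": (61, 11), "map": (89, 10), "hr": (69, 9),
             "hct": (0.44, 0.05), "hba1c": (5.5, 0.5),
             "female": 0.76, "race": {"AA": 0.12, "White": 0.77, "Hispanic": 0.11}},
    "NDR":  {"age": (55, 14), "map": (92, 11), "hr": (73, 10),
             "hct": (0.42, 0.05), "hba1c": (7.4, 1.5),
             "female": 0.66, "race": {"AA": 0.62, "White": 0.21, "Hispanic": 0.17}},
    "NPDR": {"age": (58, 10), "map": (91, 13), "hr": (78, 12),
             "hct": (0.40, 0.05), "hba1c": (8.4, 1.7),
             "female": 0.60, "race": {"AA": 0.51, "White": 0.16, "Hispanic": 0.33}},
    "PDR":  {"age": (53, 9), "map": (94, 17), "hr": (78, 11),
             "hct": (0.37, 0.06), "hba1c": (8.2, 2.0),
             "female": 0.54, "race": {"AA": 0.51, "White": 0.14, "Hispanic": 0.35}},
}

# Group means of the measured descriptors, by vessel type (simulation inputs).
DEFAULT_MEANS = {
    "arteriole": {
        "D": {"C": 18.0, "NDR": 19.0, "NPDR": 18.0, "PDR": 18.0},
        "V": {"C": 0.70, "NDR": 0.54, "NPDR": 0.62, "PDR": 0.64},
    },
    "venule": {
        "D": {"C": 20.0, "NDR": 21.0, "NPDR": 21.0, "PDR": 20.0},
        "V": {"C": 0.59, "NDR": 0.54, "NPDR": 0.57, "PDR": 0.52},
    },
}

DEFAULT_GROUP_SIZES = {"C": 34, "NDR": 47, "NPDR": 45, "PDR": 35}


class CohortValidationError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Statistical structure of a simulated cohort."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    descriptor_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MEANS["venule"].items()})
    # D spreads widely across vessels within a subject (the detectable range
    # spans 6-75 um) while per-subject mean D varies little between subjects
    sigma_b: dict | float = field(default_factory=lambda: {"D": 1.5, "V": 0.08})
    sigma_e: dict | float = field(default_factory=lambda: {"D": 8.0, "V": 0.15})
    vessels_per_subject_mean: float = 12.0
    vessels_per_subject_sd: float = 5.0
    min_vessels: int = 3
    vd_slope_s: dict | float | None = None   # V-on-D slope per group (s^-1)
    vessel_type: str = "venule"
    covariates: dict = field(default_factory=lambda: DEFAULT_COVARIATES)
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.group_sizes) - set(VALID_GROUPS)
        if bad:
            raise CohortValidationError(
                f"unknown group labels {sorted(bad)}; expected subset of {VALID_GROUPS}")
        for g, n in self.group_sizes.items():
            if int(n) <= 0:
                raise CohortValidationError(f"non-positive subject count for group {g}")
        if self.vessels_per_subject_mean <= 0 or self.min_vessels <= 0:
            raise CohortValidationError("vessel counts must be positive")
        for name, means in self.descriptor_means.items():
            missing = set(self.group_sizes) - set(means)
            if missing:
                raise CohortValidationError(
                    f"descriptor {name!r} missing means for groups {sorted(missing)}")
        for sig in (self.sigma_b, self.sigma_e):
            vals = sig.values() if isinstance(sig, dict) else [sig]
            if any(v < 0 for v in vals):
                raise CohortValidationError("standard deviations must be >= 0")

    def _sigma(self, which: str, descriptor: str) -> float:
        sig = self.sigma_b if which == "b" else self.sigma_e
        if isinstance(sig, dict):
            return float(sig.get(descriptor, 0.0))
        return float(sig)


def simulate_cohort(spec: CohortSpec):
    """Draw (subject table, vessel-level descriptor table) per the spec.

    Each descriptor follows y_ij = mu_g + b_i + eps_ij with subject random
    intercepts b_i ~ N(0, sigma_b^2) and residuals eps_ij ~ N(0, sigma_e^2).
    When ``vd_slope_s`` is given (units s^-1) and both D and V are simulated,
    V additionally tracks D within subject:
    V_ij = mu_Vg + slope_g/1000 * (D_ij - mu_Dg) + b_i + eps_ij.
    """
    rng = np.random.default_rng(spec.seed)
    descriptors = list(spec.descriptor_means)

    subj_rows, vessel_rows = [], []
    for g, n_subj in spec.group_sizes.items():
        cov = spec.covariates.get(g, DEFAULT_COVARIATES.get(g, DEFAULT_COVARIATES["C"]))
        race_labels = list(cov["race"])
        race_p = np.array([cov["race"][r] for r in race_labels], dtype=float)
        race_p /= race_p.sum()
        for i in range(int(n_subj)):
            sid = f"{g}{i:03d}"
            age = rng.normal(*cov["age"])
            mapv = rng.normal(*cov["map"])
            hr = rng.normal(*cov["hr"])
            hct = float(np.clip(rng.normal(*cov["hct"]), 0.15, 0.60))
            hba1c = max(rng.normal(*cov["hba1c"]), 3.5)
            sex = "F" if rng.random() < cov["female"] else "M"
            race = race_labels[rng.choice(len(race_labels), p=race_p)]
            subj_rows.append({"subject_id": sid, "group": g, "age": age,
                              "sex": sex, "race": race, "map": mapv, "hr": hr,
                              "hct": hct, "hba1c": hba1c})

            n_v = int(np.clip(round(rng.normal(spec.vessels_per_subject_mean,
                                               spec.vessels_per_subject_sd)),
                              spec.min_vessels, None))
            b = {d: rng.normal(0.0, spec._sigma("b", d)) for d in descriptors}
            eps = {d: rng.normal(0.0, spec._sigma("e", d), size=n_v)
                   for d in descriptors}
            vals = {}
            for d in descriptors:
                vals[d] = spec.descriptor_means[d][g] + b[d] + eps[d]
            if spec.vd_slope_s is not None and "D" in vals and "V" in vals:
                slope = (spec.vd_slope_s.get(g, 0.0)
                         if isinstance(spec.vd_slope_s, dict)
                         else float(spec.vd_slope_s))
                vals["V"] = (spec.descriptor_means["V"][g]
                             + slope / 1000.0
                             * (vals["D"] - spec.descriptor_means["D"][g])
                             + b["V"] + eps["V"])
            for j in range(n_v):
                row = {"subject_id": sid, "group": g,
                       "vessel_id": f"{sid}-v{j:03d}",
                       "vessel_type": spec.vessel_type}
                for d in descriptors:
                    row[d] = float(vals[d][j])
                vessel_rows.append(row)

    return pd.DataFrame(subj_rows), pd.DataFrame(vessel_rows)
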