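"""Pipeline configuration.

All tunable constants of the analysis live here, grouped by stage, with
defaults matching the acquisition protocol (50 frames/s, 1.25 um/px,
one-second sequences) and the filtering rules used throughout the package
(50 um minimum centerline length, 6-75 um measurable diameter range,
diameter stations every 5 px).  Configs round-trip through YAML so every
run can emit a provenance record of the exact thresholds used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class AcquisitionConfig:
    """Acquisition constants of the imaging system."""

    pixel_size_um: float = 1.25
    frame_rate_hz: float = 50.0
    duration_s: float = 1.0

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz


@dataclass
class QualityConfig:
    """Frame-quality screen thresholds (blink / motion / illumination)."""

    blink_z: float = 4.0             # robust z-score on frame mean intensity
    motion_corr: float = 0.5         # min NCC with previous valid frame; set low
                                     # enough that red-cell texture turnover at
                                     # fast flow is not mistaken for eye motion
    illum_frac: float = 0.20         # max planar gradient span / median intensity


@dataclass
class RegistrationConfig:
    upsample_factor: int = 20        # sub-pixel resolution = 1/upsample_factor px
    max_shift_frac: float = 0.10     # shifts above this fraction of width are reported
    n_passes: int = 2                # estimate vs raw mean, then vs registered mean


@dataclass
class SegmentationConfig:
    """Frangi vesselness segmentation of the time-averaged image."""

    sigma_min_px: float = 1.0
    sigma_max_px: float = 30.0
    n_scales: int = 8
    pre_smooth_px: float = 2.0       # denoise the average before vesselness
    threshold_scale: float = 0.10    # mask threshold = scale * Otsu(vesselness > 0)
    closing_px: int = 3              # bridge core dropouts of wide flat vessels
    boundary_smooth_px: float = 3.0  # outline regularization before thinning
    dilate_px: int = 2               # recover the outer tube footprint
    min_object_px: int = 60
    prune_px: int = 30               # skeleton spurs up to half the widest vessel

    def sigmas(self) -> np.ndarray:
        return np.geomspace(self.sigma_min_px, self.sigma_max_px, self.n_scales)


@dataclass
class DiametryConfig:
    station_spacing_px: float = 5.0
    profile_half_length_um: float = 60.0
    profile_step_px: float = 0.5
    tail_fraction: float = 0.25      # outer fraction of the profile used as background
    min_depth_frac: float = 0.02     # peak depth must exceed this fraction of background
    min_valid_stations: int = 3
    min_length_um: float = 50.0      # admit only segments strictly longer than this
    min_diameter_um: float = 6.0
    max_diameter_um: float = 75.0
    smoothing_sigma_px: float = 2.0  # centerline smoothing before tangents


@dataclass
class VarianceFilterConfig:
    factor: float = 2.0              # flow if centerline variance > factor * background
    dilate_px: int = 5               # mask dilation when estimating background variance


@dataclass
class VelocimetryConfig:
    min_stations: int = 20
    min_frames: int = 10
    max_slope: float = 60.0          # px/frame search ceiling (also aliasing-capped)
    coarse_step: float = 0.2         # px/frame
    fine_factor: int = 25            # fine grid step = coarse_step / fine_factor
    quality_floor: float = 6.0       # below this the estimate is flagged unreliable
    min_ray_count: int = 3


@dataclass
class HemodynamicsConfig:
    velocity_profile_factor: float = 1.6   # axial-to-mean conversion Vs = V / k
    plasma_viscosity_mpa_s: float = 1.2
    reference_hct: float = 0.45            # reference hematocrit of the viscosity law


@dataclass
class StatsConfig:
    covariates: tuple[str, ...] = (
        "age", "race", "sex", "map", "hr", "hct", "hba1c",
    )
    alpha: float = 0.05
    reference_group: str = "C"


@dataclass
class PipelineConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    diametry: DiametryConfig = field(default_factory=DiametryConfig)
    variance_filter: VarianceFilterConfig = field(default_factory=VarianceFilterConfig)
    velocimetry: VelocimetryConfig = field(default_factory=VelocimetryConfig)
    hemodynamics: HemodynamicsConfig = field(default_factory=HemodynamicsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            sub = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name != "seed":
                sub_cls = f.default_factory().__class__  # type: ignore[misc]
                known = {x.name for x in dataclasses.fields(sub_cls)}
                sub_kwargs = {k: v for k, v in sub.items() if k in known}
                if "covariates" in sub_kwargs:
                    sub_kwargs["covariates"] = tuple(sub_kwargs["covariates"])
                kwargs[f.name] = sub_cls(**sub_kwargs)
            else:
                kwargs[f.name] = sub
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Stable hash of the full configuration, for provenance records."""
        payload = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
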