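"""Image-sequence container and file I/O.

Coordinate convention used throughout the package: 0-based pixel indices,
``x`` = column (increasing right), ``y`` = row (increasing down), origin at
the top-left corner.  Frames are stored as float64 arrays indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageSequence:
    """An ordered stack of grayscale frames plus acquisition constants."""

    frames: np.ndarray               # (T, H, W) float
    pixel_size_um: float = 1.25
    frame_interval_s: float = 0.02
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / self.frame_interval_s


@dataclass
class RegisteredSequence:
    """Output of translational registration of a consecutive frame run."""

    frames: np.ndarray               # (T, H, W) registered frames
    run: tuple[int, int]             # retained frame range [first, last], inclusive
    translations: np.ndarray         # (T, 2) applied (dy, dx) per retained frame
    reference_index: int             # index into the *original* sequence
    time_averaged: np.ndarray = field(repr=False, default=None)
    valid_mask: np.ndarray = field(repr=False, default=None)
    pixel_size_um: float = 1.25
    frame_interval_s: float = 0.02


def read_sequence(path: str | Path, pixel_size_um: float = 1.25,
                  frame_rate_hz: float = 50.0) -> ImageSequence:
    """Read a multi-page TIFF or AVI into an :class:`ImageSequence`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        frames = tifffile.imread(path)
    else:
        frames = iio.imread(path)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # RGB(A) video -> luminance
        frames = frames[..., :3].mean(axis=-1)
    return ImageSequence(frames, pixel_size_um=pixel_size_um,
                         frame_interval_s=1.0 / frame_rate_hz, source=str(path))


def write_sequence(path: str | Path, seq: ImageSequence | np.ndarray) -> None:
    """Write a frame stack as a multi-page float32 TIFF."""
    frames = seq.frames if isinstance(seq, ImageSequence) else np.asarray(seq)
    tifffile.imwrite(Path(path), frames.astype(np.float32))


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject covariate table.

    Required columns: subject_id, group; groups must be drawn from
    {C, NDR, NPDR, PDR}.  MAP is derived from SBP/DBP when absent.
    """
    df = pd.read_csv(path)
    return validate_subjects(df)


VALID_GROUPS = ("C", "NDR", "NPDR", "PDR")


def validate_subjects(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise ValueError("subject table is empty")
    df = df.copy()
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"subject table missing required column {col!r}")
    bad = set(df["group"].unique()) - set(VALID_GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; "
                         f"expected one of {VALID_GROUPS}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in subject table")
    if "map" not in df.columns and {"sbp", "dbp"} <= set(df.columns):
        from .hemodynamics import compute_map
        df["map"] = [compute_map(s, d) for s, d in zip(df["sbp"], df["dbp"])]
    return df
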