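"""Shared containers: image sequences, wall-motion trajectories, rigid disturbances.

Conventions used throughout the package:

* frames are 2D arrays with rows = radial/depth axis and columns =
  longitudinal/vessel axis;
* per-frame rigid quantities are expressed relative to frame 1 (index 0),
  whose entry is identically zero;
* physical displacements are in millimetres, rotations in degrees, time in
  seconds.  Pixel-unit transforms appear only inside the registration module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class ArgumentError(ValueError):
    """Invalid argument to an operation (bad shapes, nonpositive sizes, ...)."""


class DegenerateInputError(ValueError):
    """Input without enough variation to carry out the operation."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ArgumentError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ImageSequence:
    """Ordered stack of 2D grayscale frames with physical metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Grayscale frames (uint8 for B-mode output, float for feature images).
    pixel_spacing_mm : float
        Isotropic pixel spacing in mm/px.
    frame_interval_s : float
        Time between successive frames in seconds.
    """

    frames: np.ndarray
    pixel_spacing_mm: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ArgumentError("frames must be a (n, rows, cols) stack")
        if self.pixel_spacing_mm <= 0 or self.frame_interval_s <= 0:
            raise ArgumentError("pixel spacing and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, k: int) -> np.ndarray:
        return self.frames[k]

    def save(self, path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar with the metadata."""
        path = Path(path)
        tifffile.imwrite(path, self.frames)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "frame_interval_s": self.frame_interval_s,
        }))

    @classmethod
    def load(cls, path) -> "ImageSequence":
        path = Path(path)
        frames = tifffile.imread(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(frames, meta["pixel_spacing_mm"], meta["frame_interval_s"])


@dataclass
class MotionTrajectory:
    """Per-frame 2D displacement of the tracked wall ROI relative to frame 1.

    The differential-mode signal of interest: positive ``d_rad_mm`` points
    toward increasing row (deeper), positive ``d_long_mm`` toward increasing
    column.
    """

    d_long_mm: np.ndarray
    d_rad_mm: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.d_long_mm = _as_1d(self.d_long_mm, "d_long_mm")
        self.d_rad_mm = _as_1d(self.d_rad_mm, "d_rad_mm")
        self.times_s = _as_1d(self.times_s, "times_s")
        n = len(self.times_s)
        if len(self.d_long_mm) != n or len(self.d_rad_mm) != n:
            raise ArgumentError("trajectory components must share one length")
        if n and not (abs(self.d_long_mm[0]) < 1e-9 and abs(self.d_rad_mm[0]) < 1e-9):
            raise ArgumentError("frame 1 of a trajectory must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    @property
    def amplitude_mm(self) -> np.ndarray:
        """Euclidean motion amplitude per frame."""
        return np.hypot(self.d_long_mm, self.d_rad_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(1, self.n_frames + 1),
            "time_s": self.times_s,
            "d_long_mm": self.d_long_mm,
            "d_rad_mm": self.d_rad_mm,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MotionTrajectory":
        df = pd.read_csv(path)
        return cls(df["d_long_mm"].to_numpy(), df["d_rad_mm"].to_numpy(),
                   df["time_s"].to_numpy())


@dataclass
class RigidDisturbance:
    """Per-frame global rigid disturbance (shift + rotation) relative to frame 1.

    The common-mode signal (probe jitter, breathing) to estimate and remove.
    Rotation is about the image centre, in degrees.
    """

    d_long_mm: np.ndarray
    d_rad_mm: np.ndarray
    theta_deg: np.ndarray
    times_s: np.ndarray
    n_glitches: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.d_long_mm = _as_1d(self.d_long_mm, "d_long_mm")
        self.d_rad_mm = _as_1d(self.d_rad_mm, "d_rad_mm")
        self.theta_deg = _as_1d(self.theta_deg, "theta_deg")
        self.times_s = _as_1d(self.times_s, "times_s")
        n = len(self.times_s)
        for name in ("d_long_mm", "d_rad_mm", "theta_deg"):
            comp = getattr(self, name)
            if len(comp) != n:
                raise ArgumentError("disturbance components must share one length")
            if not np.all(np.isfinite(comp)):
                raise ArgumentError(f"{name} contains non-finite values")
        if n and max(abs(self.d_long_mm[0]), abs(self.d_rad_mm[0]),
                     abs(self.theta_deg[0])) > 1e-9:
            raise ArgumentError("frame 1 of a disturbance must be (0, 0, 0)")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    def components(self) -> dict:
        return {"d_long_mm": self.d_long_mm, "d_rad_mm": self.d_rad_mm,
                "theta_deg": self.theta_deg}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(1, self.n_frames + 1),
            "time_s": self.times_s,
            "d_long_mm": self.d_long_mm,
            "d_rad_mm": self.d_rad_mm,
            "theta_deg": self.theta_deg,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RigidDisturbance":
        df = pd.read_csv(path)
        return cls(df["d_long_mm"].to_numpy(), df["d_rad_mm"].to_numpy(),
                   df["theta_deg"].to_numpy(), df["time_s"].to_numpy())

    @classmethod
    def zeros(cls, times_s) -> "RigidDisturbance":
        z = np.zeros(len(times_s))
        return cls(z, z.copy(), z.copy(), np.asarray(times_s, dtype=float),
                   n_glitches=0)
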