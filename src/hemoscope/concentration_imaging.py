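"""From calibrated video frames to chromophore concentration series and maps.

The processing chain is: ROI spatial averaging of the RGB frames, RGB -> XYZ
through the camera matrix N1, XYZ -> (Cm, CHbO, CHbR) through the simulated
regression N2, and Ctb = CHbO + CHbR. Because both stages are affine, mapping
then averaging equals averaging then mapping, so per-frame ROI means are
processed rather than every pixel; per-pixel maps are computed on demand for
single frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .color_calibration import CameraMapping, apply_camera_mapping
from .skin_optics import ConcentrationRegression, apply_concentration_regression

__all__ = [
    "FrameSequence",
    "ROIMask",
    "ConcentrationSeries",
    "ConcentrationMap",
    "spatial_average",
    "concentration_time_series",
    "concentration_map",
    "scan_line",
]


@dataclass(frozen=True)
class FrameSequence:
    """Ordered RGB frames with a frame rate and timestamps.

    ``frames`` is (T, H, W, 3) float data on a [0, 1] scale (ingest should
    divide by the sensor full-scale value); timestamps default to t = k/fs.
    """

    frames: np.ndarray
    fs: float
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError("frames must be a (T, H, W, 3) array")
        if not self.fs > 0:
            raise ValueError("frame rate must be positive")
        if self.timestamps is None:
            ts = np.arange(arr.shape[0]) / self.fs
        else:
            ts = np.asarray(self.timestamps, dtype=float)
            if ts.shape != (arr.shape[0],) or np.any(np.diff(ts) <= 0):
                raise ValueError("timestamps must be strictly increasing, one per frame")
        object.__setattr__(self, "frames", arr)
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class ROIMask:
    """Binary pixel-selection mask matching the frame size."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be a 2-D image")
        if not m.any():
            raise ValueError("ROI mask selects no pixels")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Per-frame chromophore concentrations (vol%) at the video frame rate."""

    time: np.ndarray
    c_m: np.ndarray
    c_hbo: np.ndarray
    c_hbr: np.ndarray
    fs: float
    clamped_frames: int = 0

    def __post_init__(self) -> None:
        arrs = {
            name: np.asarray(getattr(self, name), dtype=float)
            for name in ("time", "c_m", "c_hbo", "c_hbr")
        }
        n = arrs["time"].size
        if any(a.shape != (n,) for a in arrs.values()):
            raise ValueError("all concentration traces must share the time grid")
        if any(np.any(~np.isfinite(a)) for a in arrs.values()):
            raise ValueError("concentration traces must be finite")
        for name, a in arrs.items():
            object.__setattr__(self, name, a)

    @property
    def c_tb(self) -> np.ndarray:
        """Total blood concentration, the pointwise sum of oxy and deoxy Hb."""
        return self.c_hbo + self.c_hbr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "c_m": self.c_m,
                "c_hbo": self.c_hbo,
                "c_hbr": self.c_hbr,
                "c_tb": self.c_tb,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "ConcentrationSeries":
        df = pd.read_csv(path)
        t = df["time"].to_numpy(float)
        if fs is None:
            dt = np.median(np.diff(t))
            fs = 1.0 / dt
        return cls(
            t,
            df["c_m"].to_numpy(float) if "c_m" in df else np.zeros_like(t),
            df["c_hbo"].to_numpy(float),
            df["c_hbr"].to_numpy(float),
            fs,
        )


@dataclass(frozen=True)
class ConcentrationMap:
    """Per-pixel chromophore estimates for one frame plus a validity mask."""

    c_m: np.ndarray
    c_hbo: np.ndarray
    c_hbr: np.ndarray
    valid: np.ndarray  # True where no clamping occurred

    @property
    def c_tb(self) -> np.ndarray:
        return self.c_hbo + self.c_hbr


def spatial_average(frames: FrameSequence, mask: ROIMask) -> np.ndarray:
    """Unweighted per-frame mean RGB over the selected pixels, shape (T, 3)."""
    if mask.mask.shape != frames.frames.shape[1:3]:
        raise ValueError("mask size does not match the frames")
    return frames.frames[:, mask.mask, :].mean(axis=1)


def concentration_time_series(
    rgb_series: np.ndarray,
    n1: CameraMapping,
    n2: ConcentrationRegression,
    fs: float,
    time: np.ndarray | None = None,
) -> ConcentrationSeries:
    """Map a per-frame mean RGB series through N1 and N2.

    Output length equals the input frame count; frames where the affine
    inversion clamped a negative concentration are counted.
    """
    rgb = np.asarray(rgb_series, dtype=float)
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValueError("rgb_series must be (T, 3)")
    if np.any(~np.isfinite(rgb)):
        raise ValueError("rgb_series must be finite")
    xyz = apply_camera_mapping(rgb, n1)
    conc, clamped = apply_concentration_regression(xyz, n2)
    t = np.arange(rgb.shape[0]) / fs if time is None else np.asarray(time, float)
    return ConcentrationSeries(
        t,
        conc[:, 0],
        conc[:, 1],
        conc[:, 2],
        fs,
        clamped_frames=int(clamped.sum()),
    )


def concentration_map(
    frame: np.ndarray, n1: CameraMapping, n2: ConcentrationRegression
) -> ConcentrationMap:
    """Per-pixel chromophore estimates for a single (H, W, 3) frame."""
    arr = np.asarray(frame, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("frame must be (H, W, 3)")
    xyz = apply_camera_mapping(arr, n1)
    conc, clamped = apply_concentration_regression(xyz, n2)
    return ConcentrationMap(
        conc[..., 0], conc[..., 1], conc[..., 2], valid=~clamped
    )


def scan_line(
    frames: FrameSequence, index: int, axis: str = "row", channel: int | None = None
) -> np.ndarray:
    """Stack one row or column of every frame into a space-time image.

    Returns (T, length, 3), or (T, length) when ``channel`` is given; pixel
    values are copied unmodified (no resampling or magnification).
    """
    arr = frames.frames
    if axis not in ("row", "column"):
        raise ValueError("axis must be 'row' or 'column'")
    size = arr.shape[1] if axis == "row" else arr.shape[2]
    if not 0 <= index < size:
        raise ValueError(f"{axis} {index} lies outside the frame")
    line = arr[:, index, :, :] if axis == "row" else arr[:, :, index, :]
    return line if channel is None else line[..., channel]
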