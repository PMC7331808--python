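"""Camera colour calibration against a 24-patch chart, plus flat-fielding.

A linear 3x3 matrix (N1) mapping camera RGB to CIEXYZ is fitted by least
squares over the chart patches; a white-diffuser reference removes spatial
illumination non-uniformity before the mapping is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ColorCheckerObservation",
    "CameraMapping",
    "WhiteReference",
    "fit_camera_mapping",
    "apply_camera_mapping",
    "flat_field_correct",
]

#: Reflectance of the white calibration diffuser.
DIFFUSER_REFLECTANCE = 0.99


@dataclass(frozen=True)
class ColorCheckerObservation:
    """Mean camera RGB and reference XYZ for the 24 chart patches."""

    labels: tuple[str, ...]
    rgb: np.ndarray  # (24, 3) linear sensor units
    xyz: np.ndarray  # (24, 3) reference tristimulus, Y of white ~ 90-100

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb, dtype=float)
        xyz = np.asarray(self.xyz, dtype=float)
        if len(self.labels) != 24 or rgb.shape != (24, 3) or xyz.shape != (24, 3):
            raise ValueError("a ColorChecker observation has exactly 24 labelled patches")
        if len(set(self.labels)) != 24:
            raise ValueError("patch labels must be unique")
        if np.any(rgb < 0) or np.any(xyz < 0):
            raise ValueError("RGB and XYZ values must be non-negative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "rgb", rgb)
        object.__setattr__(self, "xyz", xyz)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.hstack([self.rgb, self.xyz]),
            columns=["R", "G", "B", "X", "Y", "Z"],
        )
        df.insert(0, "patch", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ColorCheckerObservation":
        df = pd.read_csv(path)
        return cls(
            tuple(df["patch"].astype(str)),
            df[["R", "G", "B"]].to_numpy(float),
            df[["X", "Y", "Z"]].to_numpy(float),
        )


@dataclass(frozen=True)
class CameraMapping:
    """The 3x3 RGB -> XYZ matrix N1 with fit diagnostics."""

    matrix: np.ndarray
    residual_rms: float = 0.0
    condition_number: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or np.any(~np.isfinite(m)):
            raise ValueError("camera mapping must be a finite 3x3 matrix")
        if np.linalg.matrix_rank(m) < 3:
            raise ValueError("camera mapping must be invertible")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "condition_number", float(np.linalg.cond(m)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "matrix": self.matrix.tolist(),
                    "residual_rms": self.residual_rms,
                    "condition_number": self.condition_number,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CameraMapping":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.asarray(payload["matrix"]), payload.get("residual_rms", 0.0))


@dataclass(frozen=True)
class WhiteReference:
    """Response of a 99%-reflectance diffuser under the session illumination.

    ``response`` is either a scalar per channel (shape (3,)) or a per-pixel
    image (H, W) or (H, W, 3); it must be strictly positive wherever applied.
    """

    response: np.ndarray
    diffuser_reflectance: float = DIFFUSER_REFLECTANCE

    def __post_init__(self) -> None:
        r = np.asarray(self.response, dtype=float)
        if np.any(~np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("white reference must be strictly positive and finite")
        if not 0 < self.diffuser_reflectance <= 1:
            raise ValueError("diffuser reflectance must lie in (0, 1]")
        object.__setattr__(self, "response", r)


def fit_camera_mapping(obs: ColorCheckerObservation) -> CameraMapping:
    """Least-squares 3x3 solution of XYZ on RGB over all patches.

    Pure linear map (no intercept), matching the physical assumption of a
    linear sensor under fixed illumination; invariant to patch order.
    """
    if np.linalg.matrix_rank(obs.rgb) < 3:
        raise ValueError("patch RGB set is rank deficient; cannot fit a 3x3 mapping")
    coeff, _, _, _ = np.linalg.lstsq(obs.rgb, obs.xyz, rcond=None)
    n1 = coeff.T
    resid = obs.xyz - obs.rgb @ n1.T
    return CameraMapping(n1, residual_rms=float(np.sqrt(np.mean(resid**2))))


def apply_camera_mapping(rgb: np.ndarray, mapping: CameraMapping) -> np.ndarray:
    """Apply N1 elementwise to a triplet, a series (n, 3) or an image (..., 3)."""
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("RGB input must have 3 components on the last axis")
    return arr @ mapping.matrix.T


def flat_field_correct(frame: np.ndarray, white: WhiteReference) -> np.ndarray:
    """Divide a frame by the normalized white response.

    Each pixel is divided by ``white.response`` scaled so that the diffuser's
    own reflectance (0.99) maps to 1; a uniform scene under the recorded
    illumination becomes uniform after correction, and correcting twice with
    a re-measured flat white is idempotent.
    """
    arr = np.asarray(frame, dtype=float)
    resp = white.response
    if resp.ndim >= 2 and resp.shape[:2] != arr.shape[:2]:
        raise ValueError("white reference image does not match the frame size")
    return arr * (white.diffuser_reflectance / resp)
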