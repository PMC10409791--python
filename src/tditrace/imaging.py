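"""Image loading and pixel-to-physical-coordinate calibration.

A TDI screenshot is a raster whose axes carry physical meaning: columns are
time, rows are velocity.  The device renders known tick values, so knowing
two reference pixels per axis is enough to fix an affine map for each axis.
Row 0 is the top image row; because screen y grows downward, the velocity
map usually has negative slope — nothing here assumes a sign.

Images are plain numpy arrays of shape ``(height, width, 3)`` with float
channels in [0, 1]; masks elsewhere are boolean arrays of shape
``(height, width)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import CalibrationError, ContractError, FormatError

__all__ = [
    "AxisCalibration",
    "PhysicalPoint",
    "load_image",
    "write_image",
    "make_calibration",
    "pixel_to_coords",
    "read_config",
    "write_config",
    "calibration_from_config",
    "calibration_to_config",
]


@dataclass(frozen=True)
class PhysicalPoint:
    """A calibrated position: ``time`` in seconds, ``velocity`` in cm/s."""

    time: float
    velocity: float


@dataclass(frozen=True)
class AxisCalibration:
    """Two-point affine calibration for each image axis.

    ``time_refs`` holds two ``(column, seconds)`` pairs and ``velocity_refs``
    two ``(row, cm_per_s)`` pairs.  Each pair of references determines one
    affine map; both maps must be invertible (distinct pixels *and* distinct
    physical values on each axis).
    """

    time_refs: tuple[tuple[float, float], tuple[float, float]]
    velocity_refs: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        (c1, t1), (c2, t2) = self.time_refs
        (r1, v1), (r2, v2) = self.velocity_refs
        for x in (c1, t1, c2, t2, r1, v1, r2, v2):
            if not math.isfinite(x):
                raise CalibrationError("calibration references must be finite")
        if c1 == c2 or t1 == t2:
            raise CalibrationError(
                "time references must differ in both column and seconds"
            )
        if r1 == r2 or v1 == v2:
            raise CalibrationError(
                "velocity references must differ in both row and cm/s"
            )

    @property
    def time_slope(self) -> float:
        (c1, t1), (c2, t2) = self.time_refs
        return (t2 - t1) / (c2 - c1)

    @property
    def velocity_slope(self) -> float:
        (r1, v1), (r2, v2) = self.velocity_refs
        return (v2 - v1) / (r2 - r1)

    def time_at(self, column):
        (c1, t1), _ = self.time_refs
        return t1 + (np.asarray(column, dtype=float) - c1) * self.time_slope

    def velocity_at(self, row):
        (r1, v1), _ = self.velocity_refs
        return v1 + (np.asarray(row, dtype=float) - r1) * self.velocity_slope

    def column_at(self, time):
        (c1, t1), _ = self.time_refs
        return c1 + (np.asarray(time, dtype=float) - t1) / self.time_slope

    def row_at(self, velocity):
        (r1, v1), _ = self.velocity_refs
        return r1 + (np.asarray(velocity, dtype=float) - v1) / self.velocity_slope

    @property
    def baseline_row(self) -> float:
        """Image row (fractional) at which velocity is zero."""
        return float(self.row_at(0.0))

    def check_baseline(self, height: int) -> None:
        """Sanity-check that the zero-velocity row is near the image.

        The baseline must lie within ``[-height, 2*height]``; anything further
        indicates swapped or mistyped references.
        """
        if not -height <= self.baseline_row <= 2 * height:
            raise CalibrationError(
                f"baseline row {self.baseline_row:.1f} far outside image of "
                f"height {height}; check velocity references"
            )


def load_image(path) -> np.ndarray:
    """Load a PNG (8- or 16-bit, RGB/RGBA/gray) as float RGB in [0, 1].

    An alpha channel, if present, is dropped.  Raises ``FileNotFoundError``
    for a missing file and :class:`FormatError` for undecodable content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder failures vary by backend
        raise FormatError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 0 or arr.size == 0:
        raise FormatError(f"image {path} has zero dimension")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise FormatError(f"unsupported image layout {arr.shape} in {path}")
    arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        scale = float(np.iinfo(arr.dtype).max)
    return np.clip(arr.astype(float) / scale, 0.0, 1.0)


def write_image(path, img: np.ndarray) -> None:
    """Write a float RGB image in [0, 1] as an 8-bit PNG."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ContractError(f"expected (H, W, 3) image, got {img.shape}")
    out = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), out, extension=".png")


def make_calibration(time_refs, velocity_refs) -> AxisCalibration:
    """Build an :class:`AxisCalibration` from two reference pairs per axis."""
    (tr1, tr2) = time_refs
    (vr1, vr2) = velocity_refs
    return AxisCalibration(
        time_refs=((float(tr1[0]), float(tr1[1])), (float(tr2[0]), float(tr2[1]))),
        velocity_refs=((float(vr1[0]), float(vr1[1])), (float(vr2[0]), float(vr2[1]))),
    )


def pixel_to_coords(cal: AxisCalibration, column: float, row: float) -> PhysicalPoint:
    """Map a pixel position to physical (time, velocity) coordinates.

    Indices may be fractional and may lie outside the image; the affine maps
    extrapolate.
    """
    if not (math.isfinite(column) and math.isfinite(row)):
        raise ContractError("pixel indices must be finite")
    return PhysicalPoint(
        time=float(cal.time_at(column)), velocity=float(cal.velocity_at(row))
    )


# ---------------------------------------------------------------------------
# key-value config files
#
# Calibration (and optionally segmentation thresholds) travel with each image
# in a small text file of "key = value" lines; '#' starts a comment.
# Reference keys:  time_ref_1 = col,seconds   velocity_ref_1 = row,cm_s

def read_config(path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    out: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(path, mapping: dict[str, str]) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_ref(text: str, key: str) -> tuple[float, float]:
    parts = [p.strip() for p in text.split(",")]
    if len(parts) != 2:
        raise FormatError(f"{key}: expected 'pixel,value', got {text!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise FormatError(f"{key}: non-numeric reference {text!r}") from exc


def calibration_from_config(mapping: dict[str, str]) -> AxisCalibration:
    """Extract an :class:`AxisCalibration` from a parsed config mapping."""
    refs = {}
    for key in ("time_ref_1", "time_ref_2", "velocity_ref_1", "velocity_ref_2"):
        if key not in mapping:
            raise FormatError(f"config missing required key {key!r}")
        refs[key] = _parse_ref(mapping[key], key)
    return make_calibration(
        (refs["time_ref_1"], refs["time_ref_2"]),
        (refs["velocity_ref_1"], refs["velocity_ref_2"]),
    )


def calibration_to_config(cal: AxisCalibration) -> dict[str, str]:
    (tr1, tr2) = cal.time_refs
    (vr1, vr2) = cal.velocity_refs
    return {
        "time_ref_1": f"{tr1[0]:g},{tr1[1]:g}",
        "time_ref_2": f"{tr2[0]:g},{tr2[1]:g}",
        "velocity_ref_1": f"{vr1[0]:g},{vr1[1]:g}",
        "velocity_ref_2": f"{vr2[0]:g},{vr2[1]:g}",
    }
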