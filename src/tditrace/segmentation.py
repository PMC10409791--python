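"""Yellow-signal detection in HSV space and value/neighborhood denoising.

The velocity trace is drawn in yellow tones on a near-black background, so in
HSV coordinates it can be isolated by windowing the hue alone, with loose
saturation/value floors to reject the gray background and annotation text.
Detection leaves behind sparse, almost-black speckle; a single denoising pass
removes flagged pixels that are both dark (low V) and poorly supported by
their 8-neighborhood.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv

from .errors import ContractError

__all__ = ["HsvColor", "SegmentationConfig", "rgb_to_hsv", "detect_yellow", "denoise_mask"]


@dataclass(frozen=True)
class HsvColor:
    """Hue in degrees [0, 360); saturation and value as fractions in [0, 1]."""

    hue: float
    saturation: float
    value: float


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for yellow detection and speckle denoising.

    Defaults target device screenshots where pure yellow (hue 60°) is spread
    by anti-aliasing: hue window [35°, 75°], saturation ≥ 0.25, value ≥ 0.12.
    A flagged pixel is dropped by :func:`denoise_mask` only if its value falls
    below ``denoise_val_min`` *and* fewer than ``denoise_neighbor_min`` of its
    8-neighbors are flagged.  All thresholds are configurable per device.
    """

    hue_min: float = 35.0
    hue_max: float = 75.0
    sat_min: float = 0.25
    val_min: float = 0.12
    denoise_val_min: float = 0.20
    denoise_neighbor_min: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_min < self.hue_max < 360.0:
            raise ContractError("require 0 <= hue_min < hue_max < 360")
        for name in ("sat_min", "val_min", "denoise_val_min"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ContractError(f"{name} must be in [0, 1], got {x}")
        if not 0 <= self.denoise_neighbor_min <= 8:
            raise ContractError("denoise_neighbor_min must be in 0..8")

    @classmethod
    def from_config(cls, mapping: dict[str, str]) -> "SegmentationConfig":
        """Build from a key-value config mapping, using defaults for absent keys."""
        kwargs = {}
        for name, conv in (
            ("hue_min", float),
            ("hue_max", float),
            ("sat_min", float),
            ("val_min", float),
            ("denoise_val_min", float),
            ("denoise_neighbor_min", int),
        ):
            if name in mapping:
                kwargs[name] = conv(mapping[name])
        return cls(**kwargs)


def rgb_to_hsv(r: float, g: float, b: float) -> HsvColor:
    """Convert one RGB triple (fractions in [0, 1]) to HSV.

    Standard hexcone model: value = max(r, g, b); saturation =
    (max - min)/max for non-black pixels; achromatic pixels report hue 0.
    """
    for name, x in (("r", r), ("g", g), ("b", b)):
        if not 0.0 <= x <= 1.0:
            raise ContractError(f"channel {name}={x} outside [0, 1]")
    h, s, v = colorsys.rgb_to_hsv(r, g, b)
    return HsvColor(hue=h * 360.0, saturation=s, value=v)


def hsv_planes(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (hue°, saturation, value) planes for a float RGB image."""
    hsv = _mpl_rgb_to_hsv(np.asarray(img, dtype=float))
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def detect_yellow(img: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Flag pixels inside the yellow hue window with sufficient S and V.

    Returns a boolean mask of the image's shape; a pixel is flagged iff
    ``hue_min <= hue <= hue_max`` and ``saturation >= sat_min`` and
    ``value >= val_min``.
    """
    cfg = cfg or SegmentationConfig()
    hue, sat, val = hsv_planes(img)
    return (
        (hue >= cfg.hue_min)
        & (hue <= cfg.hue_max)
        & (sat >= cfg.sat_min)
        & (val >= cfg.val_min)
    )


def _neighbor_counts(mask: np.ndarray) -> np.ndarray:
    """Number of flagged 8-neighbors per pixel (truncated at the border)."""
    padded = np.pad(mask.astype(np.int32), 1)
    counts = np.zeros_like(mask, dtype=np.int32)
    h, w = mask.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            counts += padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    return counts


def denoise_mask(
    mask: np.ndarray, img: np.ndarray, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Single-pass removal of dark, isolated flagged pixels.

    A flagged pixel survives unless its V component is below
    ``denoise_val_min`` *and* fewer than ``denoise_neighbor_min`` of its
    8-neighbors are flagged (neighbor counts taken on the input mask, so the
    pass is order-independent).  The result is always a subset of the input.
    """
    cfg = cfg or SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(img, dtype=float)
    if img.shape[:2] != mask.shape:
        raise ContractError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    value = img.max(axis=2)
    drop = (value < cfg.denoise_val_min) & (_neighbor_counts(mask) < cfg.denoise_neighbor_min)
    return mask & ~drop
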