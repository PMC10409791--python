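"""Collapse the 2-D signal mask into a single-valued velocity function.

The detected trace is a band several pixels tall, so each image column holds
more than one flagged pixel.  Let ``a`` be the lowest and ``b`` the highest
calibrated velocity among a column's flagged pixels.  Columns entirely above
the baseline keep ``b``, columns entirely below keep ``a``, and columns that
straddle zero take a softmax-style blend of the two extremes whose sharpness
is set by λ (default 10): the endpoint with larger magnitude dominates, so
wave peaks are preserved while near-baseline columns collapse towards zero.

The blend is applied in calibrated velocity units, not raw pixel rows: the
branch tests compare against zero *velocity*, and the blend weights are
invariant to positive rescaling but not to an offset, so the computation must
be baseline-centered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, EmptySignalError
from .imaging import AxisCalibration

__all__ = ["ColumnExtrema", "VelocityTrace", "column_extrema", "collapse_extrema", "extract_trace"]

DEFAULT_LAMBDA = 10.0


@dataclass(frozen=True)
class ColumnExtrema:
    """Extreme calibrated velocities of one column's flagged pixels (a <= b)."""

    column: int
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ContractError("column extrema must be finite")
        if self.a > self.b:
            raise ContractError(f"require a <= b, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class VelocityTrace:
    """A calibrated (time, velocity) function sampled at image columns.

    ``interpolated`` marks samples filled across short signal gaps; ``columns``
    keeps the source column of each sample so that contiguous spans (separated
    by gaps too long to fill) can be recovered.
    """

    times: np.ndarray
    velocities: np.ndarray
    interpolated: np.ndarray
    columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        vels = np.asarray(self.velocities, dtype=float)
        interp = np.asarray(self.interpolated, dtype=bool)
        cols = (
            np.arange(len(times))
            if self.columns is None
            else np.asarray(self.columns, dtype=int)
        )
        if not (len(times) == len(vels) == len(interp) == len(cols)):
            raise ContractError("trace arrays must have equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ContractError("trace times must be strictly increasing")
        if not np.all(np.isfinite(vels)):
            raise ContractError("trace velocities must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "velocities", vels)
        object.__setattr__(self, "interpolated", interp)
        object.__setattr__(self, "columns", cols)

    def __len__(self) -> int:
        return len(self.times)

    def spans(self) -> list[slice]:
        """Contiguous runs of samples (adjacent source columns)."""
        if len(self) == 0:
            return []
        breaks = np.flatnonzero(np.abs(np.diff(self.columns)) > 1)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks + 1, [len(self)]))
        return [slice(int(s), int(e)) for s, e in zip(starts, stops)]

    def to_csv(self, path) -> None:
        header = "time_s,velocity_cm_s,interpolated"
        rows = [
            f"{t:.9g},{v:.9g},{int(f)}"
            for t, v, f in zip(self.times, self.velocities, self.interpolated)
        ]
        with open(path, "w") as fh:
            fh.write(header + "\n" + "\n".join(rows) + "\n")


def column_extrema(
    mask: np.ndarray, cal: AxisCalibration, column: int
) -> ColumnExtrema | None:
    """Lowest (a) and highest (b) calibrated velocity flagged in one column.

    Returns ``None`` when the column holds no flagged pixel.  In screen
    orientation the velocity slope is negative, so ``a`` comes from the
    bottom-most flagged row; the min/max is taken over velocities, not rows,
    so either slope sign works.
    """
    mask = np.asarray(mask, dtype=bool)
    if not 0 <= column < mask.shape[1]:
        raise ContractError(f"column {column} outside mask width {mask.shape[1]}")
    rows = np.flatnonzero(mask[:, column])
    if rows.size == 0:
        return None
    vels = cal.velocity_at(rows)
    return ColumnExtrema(column=int(column), a=float(vels.min()), b=float(vels.max()))


def collapse_extrema(a: float, b: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Collapse a column's velocity extremes to a single velocity.

    Branches on the sign pattern: both non-negative -> ``b``; both
    non-positive -> ``a``; straddling zero -> the exponential blend

        a * w_a + b * w_b,   w_a ∝ exp(-λ a/(b-a)),  w_b ∝ exp(λ b/(b-a))

    whose weights favour the endpoint of larger magnitude.  The result always
    lies in [a, b]; λ > 0 controls how sharply the larger lobe wins.
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ContractError("extrema must be finite")
    if a > b:
        raise ContractError(f"require a <= b, got a={a}, b={b}")
    if lam <= 0:
        raise ContractError(f"lambda must be positive, got {lam}")
    if a >= 0.0:
        return float(b)
    if b <= 0.0:
        return float(a)
    width = b - a
    ea = -lam * a / width
    eb = lam * b / width
    m = max(ea, eb)  # exponents sum to lam; shift for safety at large lam
    wa = math.exp(ea - m)
    wb = math.exp(eb - m)
    return (a * wa + b * wb) / (wa + wb)


def extract_trace(
    mask: np.ndarray,
    cal: AxisCalibration,
    lam: float = DEFAULT_LAMBDA,
    max_gap: int = 5,
) -> VelocityTrace:
    """Collapse every signal-bearing column and bridge short gaps.

    One sample per column with signal; runs of at most ``max_gap`` empty
    columns strictly between signal columns are filled by linear interpolation
    and flagged as interpolated.  Longer gaps stay missing, splitting the
    trace into separate spans.  Leading/trailing empty columns are ignored.
    """
    mask = np.asarray(mask, dtype=bool)
    signal_cols = np.flatnonzero(mask.any(axis=0))
    if signal_cols.size == 0:
        raise EmptySignalError("mask contains no flagged pixels")

    collapsed = {}
    for col in signal_cols:
        ext = column_extrema(mask, cal, int(col))
        collapsed[int(col)] = collapse_extrema(ext.a, ext.b, lam)

    cols: list[int] = []
    vels: list[float] = []
    interp: list[bool] = []
    for i, col in enumerate(signal_cols):
        col = int(col)
        cols.append(col)
        vels.append(collapsed[col])
        interp.append(False)
        if i + 1 < len(signal_cols):
            nxt = int(signal_cols[i + 1])
            gap = nxt - col - 1
            if 0 < gap <= max_gap:
                for c in range(col + 1, nxt):
                    frac = (c - col) / (nxt - col)
                    cols.append(c)
                    vels.append(collapsed[col] * (1 - frac) + collapsed[nxt] * frac)
                    interp.append(True)

    cols_arr = np.array(cols, dtype=int)
    times = cal.time_at(cols_arr)
    if cal.time_slope < 0:  # right-to-left calibrations: keep times increasing
        cols_arr = cols_arr[::-1]
        times = times[::-1]
        vels = vels[::-1]
        interp = interp[::-1]
    return VelocityTrace(
        times=times,
        velocities=np.array(vels, dtype=float),
        interpolated=np.array(interp, dtype=bool),
        columns=cols_arr,
    )
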