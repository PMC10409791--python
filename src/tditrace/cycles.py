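"""Cardiac-cycle segmentation, selection, and length standardization.

One cardiac cycle in a TDI trace is the S wave (positive, systolic) followed
by the E' and A' waves (negative, diastolic); the end of A' marks the end of
the cycle and the start of the next.  Because the S lobe sits above zero and
A' below, the A'→S transition crosses the baseline upward, so upward zero
crossings are used as the cycle boundary operator.

Segmentation is labelled automatic only when each boundary is clean.  It is
flagged for review when the trace oscillates around zero inside the
isovolumetric-contraction gap between A' and S (extra crossings produce
stunted spans with no real S/E'/A' content), or when the trace starts away
from zero velocity so the first boundary cannot come from a crossing.

Selected cycles are standardized to a fixed number of equispaced points
(1001 by default) on [0, 1] by affine time rescaling and linear
interpolation; amplitudes are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CannotSegmentError, ContractError
from .functionalization import VelocityTrace

__all__ = [
    "Cycle",
    "CycleSet",
    "StandardizedCycle",
    "SelectionResult",
    "find_upward_crossings",
    "segment_cycles",
    "standardize_cycle",
    "mean_cycle",
    "select_cycle",
]

N_STANDARD_POINTS = 1001

# A cycle span is considered well-formed when it reaches at least this
# fraction of the trace's peak |velocity| in its positive lobe and, after it,
# in its negative lobe.  Spans created by small blips in the IVCT gap fail.
WELLFORMED_AMP_FRAC = 0.15

# |v| at the first sample above this fraction of peak |velocity| flags a
# trace that does not begin at zero velocity.
NONZERO_START_FRAC = 0.10


@dataclass(frozen=True)
class Cycle:
    """One cardiac cycle: samples from one upward crossing to the next."""

    times: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if len(t) != len(v) or len(t) < 2:
            raise ContractError("cycle needs >= 2 (time, velocity) samples")
        if not np.all(np.diff(t) > 0):
            raise ContractError("cycle times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)

    @property
    def start_time(self) -> float:
        return float(self.times[0])

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class CycleSet:
    """Ordered cycles plus whether segmentation was fully automatic."""

    cycles: tuple[Cycle, ...]
    automatic: bool
    review_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.automatic and not self.review_reason:
            raise ContractError("non-automatic segmentation needs a review_reason")

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass(frozen=True)
class StandardizedCycle:
    """A cycle resampled to equispaced abscissae on [0, 1]."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(g) != len(v):
            raise ContractError("grid and values must have equal length")
        if not np.all(np.isfinite(v)):
            raise ContractError("standardized values must be finite")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SelectionResult:
    """Which cycle was chosen and by which rule."""

    chosen_index: int
    method: str  # only_cycle | min_distance_to_mean | manual | needs_review


def find_upward_crossings(trace: VelocityTrace) -> list[float]:
    """Times where the velocity passes from <= 0 to > 0.

    Each crossing is located by linear interpolation between the bracketing
    samples; a run of exact-zero samples followed by a positive sample counts
    as a single crossing at the last zero.  A dip that only touches zero from
    above (never going strictly negative) is not a crossing.  Crossings are
    computed independently within each contiguous span of the trace.
    """
    if len(trace) < 2:
        raise ContractError("trace needs >= 2 samples")
    out: list[float] = []
    for span in trace.spans():
        t = trace.times[span]
        v = trace.velocities[span]
        if len(t) < 2:
            continue
        armed = v[0] <= 0.0
        for i in range(len(t) - 1):
            if v[i] < 0.0:
                armed = True
            if armed and v[i] <= 0.0 < v[i + 1]:
                if v[i] == 0.0:
                    out.append(float(t[i]))
                else:
                    frac = -v[i] / (v[i + 1] - v[i])
                    out.append(float(t[i] + frac * (t[i + 1] - t[i])))
                armed = False
    return out


def _slice_cycle(trace: VelocityTrace, t0: float, t1: float) -> Cycle:
    """Cycle samples on [t0, t1] with interpolated boundary samples."""
    t = trace.times
    v = trace.velocities
    inner = (t > t0) & (t < t1)
    times = np.concatenate(([t0], t[inner], [t1]))
    vels = np.concatenate(
        ([np.interp(t0, t, v)], v[inner], [np.interp(t1, t, v)])
    )
    keep = np.concatenate(([True], np.diff(times) > 0))
    return Cycle(times=times[keep], velocities=vels[keep])


def _well_formed(cycle: Cycle, vmax: float, amp_frac: float) -> bool:
    """True when the span shows a real S lobe followed by a negative lobe."""
    v = cycle.velocities
    thresh = amp_frac * vmax
    if v.max() < thresh:
        return False
    peak = int(np.argmax(v))
    return v[peak:].min() <= -thresh


def segment_cycles(
    trace: VelocityTrace,
    manual_boundaries: list[float] | None = None,
    amp_frac: float = WELLFORMED_AMP_FRAC,
    start_frac: float = NONZERO_START_FRAC,
) -> CycleSet:
    """Cut the trace into cycles at upward zero crossings.

    Cycles are the spans between consecutive crossings (within one contiguous
    trace span); partial spans before the first and after the last crossing
    are discarded.  Segmentation is automatic only when every cycle shows the
    expected positive-then-negative morphology and the trace starts near zero
    velocity; otherwise ``automatic`` is False with a review reason.  Supplying
    ``manual_boundaries`` overrides crossing detection entirely.
    """
    if manual_boundaries is not None:
        bounds = sorted(float(b) for b in manual_boundaries)
        if len(bounds) < 2:
            raise CannotSegmentError("need at least two manual boundaries")
        cycles = [
            _slice_cycle(trace, b0, b1) for b0, b1 in zip(bounds, bounds[1:])
        ]
        return CycleSet(
            cycles=tuple(cycles),
            automatic=False,
            review_reason="manual boundaries",
        )

    crossings = find_upward_crossings(trace)
    spans = trace.spans()

    def span_of(time: float) -> int:
        for k, sl in enumerate(spans):
            if trace.times[sl][0] <= time <= trace.times[sl][-1]:
                return k
        return -1

    pairs = [
        (t0, t1)
        for t0, t1 in zip(crossings, crossings[1:])
        if span_of(t0) == span_of(t1) != -1
    ]
    if not pairs:
        raise CannotSegmentError(
            f"found {len(crossings)} upward crossing(s); need two in one span"
        )
    cycles = [_slice_cycle(trace, t0, t1) for t0, t1 in pairs]

    vmax = float(np.max(np.abs(trace.velocities)))
    automatic = True
    reason: str | None = None
    if vmax > 0 and not all(_well_formed(c, vmax, amp_frac) for c in cycles):
        automatic = False
        reason = "multiple IVCT crossings"
    elif vmax > 0 and abs(trace.velocities[0]) > start_frac * vmax:
        automatic = False
        reason = "nonzero start"
    return CycleSet(cycles=tuple(cycles), automatic=automatic, review_reason=reason)


def standardize_cycle(cycle: Cycle, n_points: int = N_STANDARD_POINTS) -> StandardizedCycle:
    """Affinely rescale the cycle's time axis to [0, 1] and resample.

    Velocities are linearly interpolated onto ``n_points`` equispaced
    abscissae; endpoints reproduce the cycle's boundary velocities exactly and
    interpolation never overshoots the input range.
    """
    if n_points < 2:
        raise ContractError("n_points must be >= 2")
    if cycle.duration <= 0:
        raise ContractError("cycle has zero duration")
    grid = np.linspace(0.0, 1.0, n_points)
    unit_t = (cycle.times - cycle.start_time) / cycle.duration
    return StandardizedCycle(grid=grid, values=np.interp(grid, unit_t, cycle.velocities))


def mean_cycle(cycles: list[StandardizedCycle]) -> StandardizedCycle:
    """Pointwise arithmetic mean of standardized cycles on their common grid."""
    if not cycles:
        raise ContractError("mean_cycle needs a non-empty list")
    grid = cycles[0].grid
    for c in cycles[1:]:
        if len(c.grid) != len(grid):
            raise ContractError("cycles must share a common grid")
    return StandardizedCycle(
        grid=grid, values=np.mean([c.values for c in cycles], axis=0)
    )


def select_cycle(
    cycle_set: CycleSet, manual_choice: int | None = None
) -> SelectionResult:
    """Pick one cycle per patient.

    A manual choice always wins.  Otherwise: a single cycle selects itself;
    with three or more cycles the one closest (L2 on the standardized
    1001-point grid) to the mean cycle is chosen, ties broken by lowest
    index; exactly two cycles cannot be ranked this way (both are equidistant
    from their own mean, and the published criterion — which waveform
    describes S/E'/A' better — needs expert judgment), so index 0 is returned
    flagged ``needs_review``.
    """
    n = len(cycle_set)
    if n == 0:
        raise ContractError("cycle set is empty")
    if manual_choice is not None:
        if not 0 <= manual_choice < n:
            raise ContractError(f"manual choice {manual_choice} out of range 0..{n - 1}")
        return SelectionResult(chosen_index=manual_choice, method="manual")
    if n == 1:
        return SelectionResult(chosen_index=0, method="only_cycle")
    if n == 2:
        return SelectionResult(chosen_index=0, method="needs_review")
    std = [standardize_cycle(c) for c in cycle_set.cycles]
    mean = mean_cycle(std)
    dists = [float(np.linalg.norm(s.values - mean.values)) for s in std]
    return SelectionResult(
        chosen_index=int(np.argmin(dists)), method="min_distance_to_mean"
    )
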