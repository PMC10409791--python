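"""End-to-end convenience wrapper: image -> standardized cycle."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycles import (
    CycleSet,
    SelectionResult,
    StandardizedCycle,
    segment_cycles,
    select_cycle,
    standardize_cycle,
)
from .functionalization import DEFAULT_LAMBDA, VelocityTrace, extract_trace
from .imaging import AxisCalibration
from .segmentation import SegmentationConfig, denoise_mask, detect_yellow

__all__ = ["ExtractionResult", "run_pipeline"]


@dataclass(frozen=True)
class ExtractionResult:
    """Everything the pipeline produced for one image."""

    mask: np.ndarray
    trace: VelocityTrace
    cycle_set: CycleSet
    selection: SelectionResult
    standardized: StandardizedCycle


def run_pipeline(
    image: np.ndarray,
    calibration: AxisCalibration,
    seg_cfg: SegmentationConfig | None = None,
    lam: float = DEFAULT_LAMBDA,
    max_gap: int = 5,
    manual_boundaries: list[float] | None = None,
    manual_choice: int | None = None,
    n_points: int = 1001,
) -> ExtractionResult:
    """Detect, denoise, collapse, segment, select and standardize.

    Raises the underlying module errors unchanged (empty signal, cannot
    segment, contract violations); callers that need exit codes map them.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    calibration.check_baseline(image.shape[0])
    mask = denoise_mask(detect_yellow(image, seg_cfg), image, seg_cfg)
    trace = extract_trace(mask, calibration, lam=lam, max_gap=max_gap)
    cycle_set = segment_cycles(trace, manual_boundaries=manual_boundaries)
    selection = select_cycle(cycle_set, manual_choice=manual_choice)
    if manual_boundaries is not None and manual_choice is None:
        # boundaries were chosen by hand, so the selection is manual even
        # when the automatic rule picked the index
        selection = SelectionResult(chosen_index=selection.chosen_index, method="manual")
    standardized = standardize_cycle(
        cycle_set.cycles[selection.chosen_index], n_points=n_points
    )
    return ExtractionResult(
        mask=mask,
        trace=trace,
        cycle_set=cycle_set,
        selection=selection,
        standardized=standardized,
    )
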