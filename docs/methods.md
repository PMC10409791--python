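# Methods

## Signal model

A TDI screenshot is modelled as a dark raster with a yellow band tracing
myocardial velocity against time. Columns map to seconds and rows to cm/s
through one affine map per axis, each determined by two reference pixels
with known physical values (device tick labels). Row 0 is the top row, so
the velocity map typically has negative slope; no code path assumes the
sign. The zero-velocity baseline row is derived from the velocity
references and sanity-checked to lie within [−H, 2H] of an H-row image —
anything further almost always means swapped references.

## Segmentation

Detection works in HSV because the device's yellows share a hue regardless
of brightness. A pixel is flagged iff hue ∈ [hue_min, hue_max], saturation
≥ sat_min and value ≥ val_min. Defaults: hue 35°–75° (pure yellow is 60°;
anti-aliasing spreads the hue several degrees either way), sat_min 0.25,
val_min 0.12. The published description of the original workflow names the
inputs to denoising — a pixel's own V and its neighbors' — but not the
rule, so the simplest rule using both is adopted: one pass over the
detected mask removing a pixel iff V < 0.20 *and* fewer than 2 of its
8-neighbors are flagged (neighbor counts taken on the input mask, making
the pass order-independent; borders use the truncated neighborhood). All
six thresholds are per-image configurable; the defaults are validated only
on the synthetic renders, since real-device thresholds are not published.

## Column collapse

With a and b the lowest/highest flagged velocity in a column, the collapse
keeps b when both are ≥ 0, a when both are ≤ 0, and otherwise blends the
endpoints with softmax weights exp(−λa/(b−a)), exp(λb/(b−a)), λ = 10 by
default. Decisions taken where the rule's statement leaves room:

- **Units.** The rule is applied in calibrated velocity units, not pixel
  rows: the branches compare against zero velocity, and the blend weights
  are invariant to positive rescaling but not to an offset, so only a
  baseline-centered scale puts the branch boundary in the right place.
- **Boundaries.** a = 0 or b = 0 fold into the adjacent one-sided branch,
  the continuity limit of the blend; a = b returns that value
  (single-pixel columns are legitimate).
- **Numerics.** The two exponents are non-negative and sum to λ, so the
  blend is evaluated after subtracting their maximum; it is then stable for
  any λ a test exercises (checked to λ = 100).

Columns with no signal inside a run of ≤ max_gap (default 5) columns are
filled by linear interpolation and flagged `interpolated`; longer gaps
split the trace into separate spans, which keeps a weak or dropped-out
region from fabricating data.

## Cycle segmentation, review flags, selection

S sits above zero and A′ below, so the A′→S transition crosses the baseline
upward; upward zero crossings are the cycle boundary operator. A crossing
is located by linear interpolation between the bracketing samples; runs of
exact zeros count once (at the last zero), and a dip that only touches zero
from above does not count — this immunises the detector against the
one-row quantization flicker of near-baseline columns. Crossings are found
per contiguous span; partial spans before the first and after the last
crossing are discarded.

Segmentation is *automatic* only when every cycle shows the expected
morphology. Two review conditions are operationalized:

- **multiple IVCT crossings** — extra sign flips in the A′–S gap create
  stunted spans. A span is well-formed when its positive peak reaches ≥ 15%
  of the trace's global |v| maximum and the samples after that peak dip
  below −15% of it; any ill-formed span flags the set.
- **nonzero start** — |v| at the first sample above 10% of the global
  maximum: the trace begins mid-wave and the first boundary cannot come
  from a crossing.

Both fractions are arguments of `segment_cycles`. Manually supplied
boundaries bypass crossing detection entirely and mark the segmentation
(and the downstream selection) as manual.

Selection: one cycle selects itself; with ≥ 3, all are standardized and
the one with the smallest L2 distance (on the common 1001-point grid) to
their pointwise mean wins, ties to the lowest index. The distance is
computed *after* length standardization so cycles of different durations
are comparable. With exactly two cycles both are equidistant from their own
mean and the published criterion (which describes S/E′/A′ better, judged by
experts) is not computable, so index 0 is returned flagged `needs_review`.
Standardization rescales time affinely to [0, 1] and linearly interpolates
onto 1001 equispaced points; amplitudes are untouched — only length is
standardized.

## Synthetic renderer

The generator emulates what the pipeline must survive, not Doppler physics:
a periodic sum of three Gaussian lobes (defaults S +8, E′ −10, A′ −8 cm/s,
period 0.8 s, lobe centers 0.12/0.45/0.70 of the period, widths 0.05 —
plausible adult septal-annulus values) painted 3 pixels thick with hue
jitter ±4°, on a 600×400 image at 0.05 cm/s per row. The phase default
(0.85) starts the render in the quiet gap after A′ and the duration extends
0.3 periods past the last cycle, so a k-cycle render contains exactly k+1
boundary crossings. Background speckle (rate 0.002) is drawn away from the
yellow hue window except for a 20% "confusable" fraction — yellow hue but
V ≈ 0.15, detected and then removed by denoising. The pathological cases
add per-period extra lobes (+1/−1 cm/s bumps at 0.84/0.88 of the period)
to fabricate IVCT oscillation, or start the phase at the S peak for the
nonzero-start case. The weak-signal case dims V to 0.35 of normal over 15%
of the width — above the detection floors, mirroring a region that is faint
but recoverable. Rendered images are quantized to the 8-bit grid so a PNG
write/read round-trip is pixel-identical, and all randomness flows from one
seed per render.

What the renders do *not* emulate: spectral broadening, ECG overlays,
annotation text, variable beat lengths within one recording, and real
device color palettes. Passing the round-trip suite therefore shows the
geometry of the pipeline is right to within quantization, not that the
default thresholds fit any particular hospital device.

Accuracy bookkeeping: one pixel row is 0.05 cm/s; with a 3-pixel band the
collapse rule biases outward by up to one row, so the round-trip RMSE
tolerance is 1.5 rows (0.075 cm/s). Measured worst-case RMSE over the clean
suite is ≈ 0.055 cm/s.

## Dataset tools

The readers target the published three-CSV schema: 27 order-sensitive
clinical headers (`cxvalv` canonical for previous valve surgery, with
`valvsurgprev` accepted as an alias), a functional file of CTRCD + 1001
grid columns (headers accepted with or without the embedded space, "t 1"
or "t1"), and the combined 1028-column file in which patients without a
preprocessed image carry NAs. Empty cells and "NA" read as missing, the
convention of files exported from R. Summaries use the linear-interpolation
quantile convention (numpy's and R's default — the most plausible producer
of the published tables; a different convention shifts Q1/Q3 slightly but
never min/median/mean/max), and binary percentages divide by the
per-variable non-missing count, which is what the published rows imply
(e.g. hypertension's 381+100 < 531). Validation detects — never corrects —
out-of-range LVEF, non-positive follow-up times, non-binary codes, and
incomplete 1001-point functional rows.

## Problem sizes

The test suite and the acceptance script run entirely on the synthetic
suite: seven 600×400 renders, 100 random cycle-sets for the selection
oracle, and 200-point property sweeps of the blend — the sizes at which the
checked properties are already exact or tolerance-bound. The descriptive
statistics of the published dataset are asserted only when its CSVs are
present locally (see README); they are not shipped with the repository.

## Known limitations

- Default HSV thresholds are placeholders validated on synthetic renders
  only; real devices need per-device configs.
- The review-flag fractions (15% amplitude, 10% start) are heuristics; a
  trace whose true A′ wave is under 15% of its S wave would be flagged
  spuriously.
- Cycles flagged for review are still segmented at the detected crossings;
  the package never guesses manual boundaries.
- No wave labelling or feature extraction (peak S/E′/A′, ratios) and no
  survival modelling on the dataset; those are downstream analyses.
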