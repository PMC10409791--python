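"""Synthetic TDI renderer: ground-truth images for end-to-end testing.

A parametric cardiac waveform — Gaussian S, E' and A' lobes repeated
periodically — is painted as a yellow band onto a dark background, with
hue jitter, random background speckle (a fraction of it dark yellow, to
exercise denoising) and an optional weak-signal region whose brightness is
dimmed.  The renderer records the exact velocity painted in each column, so
extraction error can be measured in physical units, and it is deterministic
given a seed.

Amplitudes default to a plausible adult septal-annulus pattern (S +8 cm/s,
E' -10 cm/s, A' -8 cm/s, period 0.8 s) on a 600x400 screenshot at
0.05 cm/s per pixel row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .errors import ContractError, RenderError
from .functionalization import VelocityTrace
from .imaging import (
    AxisCalibration,
    calibration_to_config,
    make_calibration,
    write_config,
    write_image,
)

__all__ = [
    "WaveformSpec",
    "RenderSpec",
    "Fixture",
    "waveform_velocity",
    "default_calibration",
    "render_tdi",
    "make_fixture_suite",
    "write_fixture_suite",
]


@dataclass(frozen=True)
class WaveformSpec:
    """Periodic S/E'/A' velocity waveform built from Gaussian lobes.

    ``centers`` and ``widths`` are fractions of the period for the S, E' and
    A' lobes in that order.  ``phase`` sets where in the cycle t = 0 falls
    (0.85 starts in the quiet gap just after A', so the rendered trace begins
    near zero velocity); ``tail_frac`` extends the rendered duration past the
    last cycle so its closing boundary crossing is inside the image.
    ``extra_lobes`` adds (amplitude, center, width) bumps per period, used to
    fabricate pathological cases such as oscillation in the gap between A'
    and S.
    """

    period: float = 0.8
    n_cycles: int = 3
    s_amp: float = 8.0
    e_amp: float = -10.0
    a_amp: float = -8.0
    centers: tuple[float, float, float] = (0.12, 0.45, 0.70)
    widths: tuple[float, float, float] = (0.05, 0.05, 0.05)
    phase: float = 0.85
    tail_frac: float = 0.3
    extra_lobes: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.period <= 0 or self.n_cycles < 1:
            raise ContractError("period must be positive and n_cycles >= 1")
        if not (self.s_amp > 0 > self.e_amp and self.a_amp < 0):
            raise ContractError("require s_amp > 0 and e_amp, a_amp < 0")
        cs, ce, ca = self.centers
        if not 0 <= cs < ce < ca < 1:
            raise ContractError("lobe centers must be ordered S < E' < A' in [0,1)")

    @property
    def duration(self) -> float:
        """Rendered time span: n_cycles periods plus the boundary tail."""
        return (self.n_cycles + self.tail_frac) * self.period

    @property
    def velocity_range(self) -> tuple[float, float]:
        amps = [self.s_amp, self.e_amp, self.a_amp] + [a for a, _, _ in self.extra_lobes]
        return min(min(amps), 0.0), max(max(amps), 0.0)


@dataclass(frozen=True)
class RenderSpec:
    """How to paint a waveform: geometry, noise, and degradations.

    ``weak_region`` dims painted pixels' V by ``weak_dim`` over a column
    interval given as fractions of the width.  ``confusable_frac`` of the
    background speckle falls inside the yellow hue window but dark, so it is
    caught by detection and must be removed by denoising.
    """

    height: int = 400
    width: int = 600
    calibration: AxisCalibration | None = None
    line_thickness: int = 3
    hue_jitter: float = 4.0
    background_noise_rate: float = 0.002
    confusable_frac: float = 0.2
    weak_region: tuple[float, float] | None = None
    weak_dim: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.line_thickness < 1:
            raise ContractError("line_thickness must be >= 1")
        if not 0.0 <= self.background_noise_rate < 1.0:
            raise ContractError("background_noise_rate must be in [0, 1)")
        if not 0.0 < self.weak_dim <= 1.0:
            raise ContractError("weak_dim must be in (0, 1]")


@dataclass(frozen=True)
class Fixture:
    """A rendered image with everything needed to check the pipeline on it."""

    name: str
    wspec: WaveformSpec
    rspec: RenderSpec
    image: np.ndarray
    calibration: AxisCalibration
    truth: VelocityTrace
    n_cycles_expected: int
    automatic_expected: bool


def waveform_velocity(spec: WaveformSpec, t) -> np.ndarray | float:
    """Velocity (cm/s) of the periodic waveform at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    u = t / spec.period + spec.phase
    v = np.zeros_like(u)
    lobes = list(
        zip((spec.s_amp, spec.e_amp, spec.a_amp), spec.centers, spec.widths)
    ) + list(spec.extra_lobes)
    for amp, center, width in lobes:
        d = np.mod(u - center + 0.5, 1.0) - 0.5  # wrapped phase distance
        v += amp * np.exp(-0.5 * (d / width) ** 2)
    return v if v.shape else float(v)


def default_calibration(
    wspec: WaveformSpec,
    height: int = 400,
    width: int = 600,
    cm_per_row: float = 0.05,
) -> AxisCalibration:
    """Calibration mapping the waveform into the image with margins.

    Columns span [0, duration]; the zero-velocity baseline row is placed so
    the largest positive excursion fits above it with ~0.6 cm/s to spare.
    """
    _, vmax = wspec.velocity_range
    baseline = round((vmax + 0.6) / cm_per_row)
    return make_calibration(
        time_refs=((0.0, 0.0), (float(width - 1), wspec.duration)),
        velocity_refs=((float(baseline), 0.0), (float(baseline + 100), -100.0 * cm_per_row)),
    )


def render_tdi(
    wspec: WaveformSpec, rspec: RenderSpec
) -> tuple[np.ndarray, VelocityTrace]:
    """Paint the waveform as a yellow band; return image and ground truth.

    Each column's band is ``line_thickness`` pixels centered on the rounded
    calibrated row of the true velocity; the ground-truth trace records the
    un-quantized velocity per column.  Background speckle is laid down before
    the band so the signal always wins.  Deterministic given ``rspec.seed``.
    """
    cal = rspec.calibration or default_calibration(wspec, rspec.height, rspec.width)
    rng = np.random.default_rng(rspec.seed)
    h, w = rspec.height, rspec.width

    img = np.zeros((h, w, 3), dtype=float)
    img += rng.uniform(0.0, 0.04, size=(h, w, 1))  # faint panel glow

    n_speckle = int(round(rspec.background_noise_rate * h * w))
    if n_speckle:
        rows = rng.integers(0, h, n_speckle)
        cols = rng.integers(0, w, n_speckle)
        confusable = rng.random(n_speckle) < rspec.confusable_frac
        hue = np.where(
            confusable,
            rng.uniform(40.0, 70.0, n_speckle),  # yellow but dark
            rng.uniform(100.0, 340.0, n_speckle),  # far from yellow
        )
        sat = rng.uniform(0.6, 1.0, n_speckle)
        val = np.where(
            confusable,
            rng.uniform(0.13, 0.18, n_speckle),
            rng.uniform(0.3, 0.9, n_speckle),
        )
        img[rows, cols] = hsv_to_rgb(np.stack([hue / 360.0, sat, val], axis=-1))

    half_lo = (rspec.line_thickness - 1) // 2
    half_hi = rspec.line_thickness // 2
    weak_cols = None
    if rspec.weak_region is not None:
        f0, f1 = rspec.weak_region
        weak_cols = (int(f0 * w), int(f1 * w))

    columns = np.arange(w)
    times = np.asarray(cal.time_at(columns))
    truth_v = np.asarray(waveform_velocity(wspec, times))
    center_rows = np.round(np.asarray(cal.row_at(truth_v))).astype(int)
    if center_rows.min() - half_lo < 0 or center_rows.max() + half_hi >= h:
        raise RenderError(
            "waveform leaves the image; enlarge the image or rescale the calibration"
        )
    for c in columns:
        r0, r1 = center_rows[c] - half_lo, center_rows[c] + half_hi + 1
        n = r1 - r0
        hue = (60.0 + rng.uniform(-rspec.hue_jitter, rspec.hue_jitter, n)) / 360.0
        sat = rng.uniform(0.85, 1.0, n)
        val = rng.uniform(0.85, 0.98, n)
        if weak_cols is not None and weak_cols[0] <= c < weak_cols[1]:
            val = val * rspec.weak_dim
        img[r0:r1, c] = hsv_to_rgb(np.stack([hue, sat, val], axis=-1))

    img = np.round(img * 255.0) / 255.0  # 8-bit grid: PNG round-trip is exact
    truth = VelocityTrace(
        times=times,
        velocities=truth_v,
        interpolated=np.zeros(w, dtype=bool),
        columns=columns,
    )
    return img, truth


# Extra lobes fabricating an oscillation in the A'-S gap: a small positive
# bump followed by a small negative dip, giving one spurious upward crossing
# (hence one stunted span) per period.
_BLIP_LOBES = ((1.0, 0.84, 0.010), (-1.0, 0.88, 0.010))


def make_fixture_suite(seed: int) -> list[Fixture]:
    """Deterministic fixtures covering the cases the pipeline must handle.

    Clean renders with 1, 2, 3 and 5 cycles; a gap-oscillation ("blip") case
    that defeats automatic segmentation; a trace starting mid-S-lobe away
    from zero velocity; and a weak-signal region dimmed to a third of normal
    brightness.
    """
    cases: list[tuple[str, WaveformSpec, dict, int, bool]] = []
    for k in (1, 2, 3, 5):
        cases.append((f"cycles_{k}", WaveformSpec(n_cycles=k), {}, k, True))
    cases.append(
        ("blip", WaveformSpec(n_cycles=3, extra_lobes=_BLIP_LOBES), {}, 3, False)
    )
    cases.append(
        ("nonzero_start", WaveformSpec(n_cycles=2, phase=0.12), {}, 1, False)
    )
    cases.append(
        (
            "weak_signal",
            WaveformSpec(n_cycles=3),
            {"weak_region": (0.45, 0.60), "weak_dim": 0.35},
            3,
            True,
        )
    )

    suite = []
    for i, (name, wspec, overrides, k, auto) in enumerate(cases):
        rspec = RenderSpec(seed=int(seed) * 100 + i, **overrides)
        cal = default_calibration(wspec, rspec.height, rspec.width)
        rspec = replace(rspec, calibration=cal)
        image, truth = render_tdi(wspec, rspec)
        suite.append(
            Fixture(
                name=name,
                wspec=wspec,
                rspec=rspec,
                image=image,
                calibration=cal,
                truth=truth,
                n_cycles_expected=k,
                automatic_expected=auto,
            )
        )
    return suite


def write_fixture_suite(suite: list[Fixture], outdir) -> Path:
    """Write PNG + calibration config + ground-truth CSV per fixture.

    Returns the manifest path; the manifest lists one line per fixture with
    its files, in a fixed order so regeneration is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = []
    for fx in suite:
        png = outdir / f"{fx.name}.png"
        cfg = outdir / f"{fx.name}.cfg"
        csv = outdir / f"{fx.name}_truth.csv"
        write_image(png, fx.image)
        write_config(cfg, calibration_to_config(fx.calibration))
        fx.truth.to_csv(csv)
        lines.append(
            f"{fx.name}\t{png.name}\t{cfg.name}\t{csv.name}\t"
            f"{fx.n_cycles_expected}\t{int(fx.automatic_expected)}"
        )
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
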