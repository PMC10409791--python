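"""Zero-crossing segmentation, cycle selection, and 1001-point standardization."""

import numpy as np
import pytest

from tditrace.cycles import (
    Cycle,
    CycleSet,
    StandardizedCycle,
    find_upward_crossings,
    mean_cycle,
    segment_cycles,
    select_cycle,
    standardize_cycle,
)
from tditrace.errors import CannotSegmentError, ContractError
from tditrace.functionalization import VelocityTrace


def trace_from(times, velocities, columns=None):
    times = np.asarray(times, dtype=float)
    return VelocityTrace(
        times=times,
        velocities=np.asarray(velocities, dtype=float),
        interpolated=np.zeros(len(times), dtype=bool),
        columns=columns,
    )


class TestUpwardCrossings:
    def test_simple_sign_change_interpolated(self):
        assert find_upward_crossings(trace_from([0, 1], [-1, 1])) == [0.5]

    def test_all_positive_has_no_crossings(self):
        assert find_upward_crossings(trace_from([0, 1, 2], [1, 2, 1])) == []

    def test_exact_zero_sample_counts_once(self):
        t = trace_from([0, 1, 2, 3], [-1, 0, 0, 2])
        assert find_upward_crossings(t) == [2.0]

    def test_zero_touch_from_above_is_not_a_crossing(self):
        t = trace_from([0, 1, 2], [1, 0, 1])
        assert find_upward_crossings(t) == []

    def test_sine_zeros_recovered(self):
        t = np.linspace(0, 4 * np.pi, 400)
        found = find_upward_crossings(trace_from(t, np.sin(t)))
        spacing = t[1] - t[0]
        expected = [0.0, 2 * np.pi]  # upward zeros of sin on [0, 4pi)
        assert len(found) == len(expected)
        for f, e in zip(found, expected):
            assert abs(f - e) <= spacing

    def test_crossings_respect_span_breaks(self):
        # two spans separated by a column gap; the sign flip across the gap
        # must not create a crossing
        t = trace_from(
            [0, 1, 10, 11], [-1, -2, 2, 3], columns=[0, 1, 50, 51]
        )
        assert find_upward_crossings(t) == []


def synthetic_trace(n_cycles=3, period=0.8, n=800, **wave_kwargs):
    from tditrace.synthetic import WaveformSpec, waveform_velocity

    spec = WaveformSpec(n_cycles=n_cycles, period=period, **wave_kwargs)
    t = np.linspace(0.0, spec.duration, n)
    return spec, trace_from(t, waveform_velocity(spec, t))


class TestSegmentCycles:
    def test_counts_and_contiguity_on_clean_waveforms(self):
        for k in (1, 2, 3, 5):
            _, trace = synthetic_trace(n_cycles=k)
            cs = segment_cycles(trace)
            assert len(cs) == k
            assert cs.automatic
            for c0, c1 in zip(cs.cycles, cs.cycles[1:]):
                assert c1.start_time == pytest.approx(c0.end_time, abs=1e-9)

    def test_gap_oscillation_flagged_for_review(self):
        blip = ((1.0, 0.84, 0.01), (-1.0, 0.88, 0.01))
        _, trace = synthetic_trace(n_cycles=3, extra_lobes=blip)
        cs = segment_cycles(trace)
        assert not cs.automatic
        assert cs.review_reason == "multiple IVCT crossings"

    def test_nonzero_start_flagged_for_review(self):
        _, trace = synthetic_trace(n_cycles=2, phase=0.12)  # starts at S peak
        cs = segment_cycles(trace)
        assert not cs.automatic
        assert cs.review_reason == "nonzero start"

    def test_manual_boundaries_override_crossings(self):
        _, trace = synthetic_trace(n_cycles=3)
        cs = segment_cycles(trace, manual_boundaries=[0.5, 1.3, 2.1])
        assert len(cs) == 2
        assert not cs.automatic and cs.review_reason == "manual boundaries"
        assert cs.cycles[0].start_time == pytest.approx(0.5)
        assert cs.cycles[1].end_time == pytest.approx(2.1)

    def test_too_few_crossings_cannot_segment(self):
        with pytest.raises(CannotSegmentError):
            segment_cycles(trace_from([0, 1, 2], [1, 2, 1]))


class TestStandardize:
    def test_output_has_exactly_1001_points_on_unit_grid(self):
        cyc = Cycle(times=np.array([2.0, 2.4, 3.0]), velocities=np.array([0.0, 5.0, 0.0]))
        std = standardize_cycle(cyc)
        assert len(std.values) == 1001
        assert std.grid[0] == 0.0 and std.grid[-1] == 1.0
        assert np.allclose(np.diff(std.grid), 1e-3)
        assert std.values[0] == 0.0 and std.values[-1] == 0.0

    def test_identity_on_already_standard_sampling(self, rng):
        t = np.linspace(5.0, 6.0, 1001)
        v = rng.normal(size=1001)
        std = standardize_cycle(Cycle(times=t, velocities=v))
        assert np.allclose(std.values, v, atol=1e-12)

    def test_linear_ramp_reproduced_exactly(self):
        t = np.array([0.0, 0.3, 1.0])
        std = standardize_cycle(Cycle(times=t, velocities=t))
        assert np.allclose(std.values, std.grid, atol=1e-12)

    def test_never_overshoots_input_range(self, rng):
        t = np.sort(rng.uniform(0, 1, 50))
        t[0], t[-1] = 0.0, 1.0
        v = rng.normal(size=50)
        std = standardize_cycle(Cycle(times=t, velocities=v))
        assert v.min() - 1e-12 <= std.values.min()
        assert std.values.max() <= v.max() + 1e-12

    def test_zero_duration_rejected(self):
        with pytest.raises(ContractError):
            Cycle(times=np.array([1.0, 1.0]), velocities=np.array([0.0, 1.0]))


class TestMeanAndSelection:
    def test_mean_of_one_is_itself_and_opposites_cancel(self, rng):
        grid = np.linspace(0, 1, 1001)
        v = rng.normal(size=1001)
        a = StandardizedCycle(grid=grid, values=v)
        b = StandardizedCycle(grid=grid, values=-v)
        assert np.array_equal(mean_cycle([a]).values, v)
        assert np.allclose(mean_cycle([a, b]).values, 0.0)

    def test_mean_matches_per_point_bruteforce(self, rng):
        grid = np.linspace(0, 1, 11)
        cycles = [StandardizedCycle(grid=grid, values=rng.normal(size=11)) for _ in range(3)]
        got = mean_cycle(cycles).values
        for j in range(11):
            assert got[j] == pytest.approx(
                sum(c.values[j] for c in cycles) / 3, abs=1e-12
            )

    @staticmethod
    def random_cycle_set(rng, n_cycles):
        cycles = []
        t0 = 0.0
        for _ in range(n_cycles):
            dur = rng.uniform(0.5, 1.2)
            n = rng.integers(20, 60)
            t = np.linspace(t0, t0 + dur, n)
            v = rng.normal(scale=5.0, size=n)
            cycles.append(Cycle(times=t, velocities=v))
            t0 += dur
        return CycleSet(cycles=tuple(cycles), automatic=True)

    def test_single_and_double_cycle_rules(self, rng):
        one = self.random_cycle_set(rng, 1)
        assert select_cycle(one).method == "only_cycle"
        two = self.random_cycle_set(rng, 2)
        res = select_cycle(two)
        assert (res.chosen_index, res.method) == (0, "needs_review")

    def test_manual_choice_always_wins(self, rng):
        cs = self.random_cycle_set(rng, 4)
        res = select_cycle(cs, manual_choice=2)
        assert (res.chosen_index, res.method) == (2, "manual")
        with pytest.raises(ContractError):
            select_cycle(cs, manual_choice=9)

    def test_cycle_equal_to_mean_is_chosen(self):
        grid_t = np.linspace(0, 1, 101)
        base = np.sin(2 * np.pi * grid_t)
        cycles = []
        t0 = 0.0
        for offset in (-1.0, 0.0, 1.0):  # middle one equals the mean
            cycles.append(Cycle(times=grid_t + t0, velocities=base + offset))
            t0 += 1.0
        res = select_cycle(CycleSet(cycles=tuple(cycles), automatic=True))
        assert res.chosen_index == 1
        assert res.method == "min_distance_to_mean"

    def test_matches_bruteforce_argmin_on_random_sets(self, rng):
        """100 random >=3-cycle sets: selection equals the brute-force
        argmin of L2 distances to the mean standardized cycle."""
        for _ in range(100):
            cs = self.random_cycle_set(rng, int(rng.integers(3, 7)))
            std = [standardize_cycle(c).values for c in cs.cycles]
            mean = np.mean(std, axis=0)
            dists = [np.sqrt(np.sum((s - mean) ** 2)) for s in std]
            expected = int(np.argmin(dists))
            assert select_cycle(cs).chosen_index == expected
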