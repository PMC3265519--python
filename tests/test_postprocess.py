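"""Drift correction, color coding, statistical crosstalk subtraction."""

import numpy as np
import pandas as pd
import pytest

from smlm.postprocess import (DriftTrace, apply_drift, assign_colors,
                              estimate_crosstalk, estimate_drift,
                              subtract_crosstalk)
from smlm.simulate import (ActivationSchedule, BlinkModel, StructureSpec,
                           events_to_table, make_structure, schedule_blinking)
from smlm.tables import LocalizationTable

RENDER_PX = 25.0


def _tube_table(n_frames=5000, density=800.0, drift=None, seed=0):
    """Idealized localizations of a bent tube, enough structure to correlate."""
    spec = StructureSpec("tube", 75.0,
                         ((300.0, 500.0, 0.0), (2500.0, 1800.0, 0.0),
                          (4700.0, 700.0, 0.0)),
                         density)
    em = make_structure(spec, seed=seed)
    ev = schedule_blinking(em, ActivationSchedule.single_color(),
                           BlinkModel(mean_localizations_per_label=8.0),
                           n_frames, seed=seed + 1)
    return events_to_table(ev, em, n_frames=n_frames, drift=drift,
                           scatter_sigma=(4.0, 4.0, 12.0), seed=seed + 2)


def _linear_trace(total, n_frames, n_bins=200):
    edges = np.linspace(0, n_frames, n_bins + 1)
    f = 0.5 * (edges[:-1] + edges[1:]) / n_frames
    f = f - f[0]  # anchored at the reference (first) bin
    return DriftTrace(edges, total[0] * f, total[1] * f)


class TestDriftTrace:
    def test_bins_must_tile_and_reference_zero(self):
        with pytest.raises(ValueError):
            DriftTrace(np.array([0.0, 10.0]), np.array([5.0]), np.array([0.0]))

    def test_interpolation_is_piecewise_linear_constant_at_ends(self):
        tr = DriftTrace(np.array([0.0, 100.0, 200.0]),
                        np.array([0.0, 10.0]), np.array([0.0, -6.0]))
        dx, dy, _ = tr.offsets_at([0, 50, 100, 150, 199])
        assert dx[1] == 0.0  # first bin center
        assert dx[2] == 5.0  # midway between centers
        assert dx[3] == 10.0
        assert dx[0] == 0.0 and dx[4] == 10.0  # constant extrapolation


class TestEstimateDrift:
    def test_drift_free_offsets_below_half_pixel(self):
        table = _tube_table()
        trace = estimate_drift(table, bin_size=1000, render_pixel=RENDER_PX)
        assert np.max(np.abs(trace.dx)) < RENDER_PX / 2
        assert np.max(np.abs(trace.dy)) < RENDER_PX / 2

    def test_linear_100nm_drift_recovered_per_bin(self):
        n_frames = 10_000
        true = _linear_trace((100.0, -60.0), n_frames)
        table = _tube_table(n_frames=n_frames, drift=true, seed=3)
        trace = estimate_drift(table, bin_size=1000, render_pixel=RENDER_PX)
        centers = trace.bin_centers
        tx, ty, _ = true.offsets_at(centers)
        # offsets are relative to the reference (first) bin
        assert np.max(np.abs((trace.dx - trace.dx[0]) - (tx - tx[0]))) < RENDER_PX / 2
        assert np.max(np.abs((trace.dy - trace.dy[0]) - (ty - ty[0]))) < RENDER_PX / 2

    def test_rigid_shift_of_non_reference_bins(self):
        table = _tube_table(n_frames=4000)
        shifted = table.copy()
        late = shifted.df["frame"] >= 1000
        shifted.df.loc[late, "x_nm"] += 80.0
        trace = estimate_drift(shifted, bin_size=1000, render_pixel=RENDER_PX)
        assert np.allclose(trace.dx[1:], 80.0, atol=RENDER_PX / 2)
        assert trace.dx[0] == 0.0

    def test_single_bin_rejected(self):
        table = _tube_table(n_frames=500)
        with pytest.raises(ValueError, match="bins"):
            estimate_drift(table, bin_size=1000)


class TestApplyDrift:
    def test_zero_trace_is_identity(self):
        table = _tube_table(n_frames=2000)
        out = apply_drift(table, DriftTrace.zero(2000, 4))
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_bin_center_shifted_by_exact_offset(self):
        table = LocalizationTable.from_arrays([1000.0], [1000.0], [150],
                                              n_frames=200)
        tr = DriftTrace(np.array([0.0, 100.0, 200.0]),
                        np.array([0.0, 12.0]), np.array([0.0, -8.0]))
        out = apply_drift(table, tr)
        assert out.df.loc[0, "x_nm"] == pytest.approx(1000.0 - 12.0)
        assert out.df.loc[0, "y_nm"] == pytest.approx(1000.0 + 8.0)

    def test_frame_outside_trace_rejected(self):
        table = LocalizationTable.from_arrays([0.0], [0.0], [500], n_frames=501)
        with pytest.raises(ValueError, match="cover"):
            apply_drift(table, DriftTrace.zero(100, 2))

    def test_correction_then_reestimation_is_fixed_point(self):
        n_frames = 10_000
        true = _linear_trace((100.0, 40.0), n_frames)
        table = _tube_table(n_frames=n_frames, drift=true, seed=9)
        trace = estimate_drift(table, bin_size=1000, render_pixel=RENDER_PX)
        corrected = apply_drift(table, trace)
        residual = estimate_drift(corrected, bin_size=1000,
                                  render_pixel=RENDER_PX)
        assert np.max(np.abs(residual.dx)) < RENDER_PX / 2
        assert np.max(np.abs(residual.dy)) < RENDER_PX / 2

    def test_preserves_counts_photons_z(self):
        table = _tube_table(n_frames=2000)
        out = apply_drift(table, _linear_trace((50.0, 20.0), 2000, 4))
        assert len(out) == len(table)
        assert np.array_equal(out.df["photons"], table.df["photons"])
        assert np.array_equal(out.df["z_nm"], table.df["z_nm"])


MULTI = ActivationSchedule.multicolor(("ch405", "ch457"), n_activation=2,
                                      n_imaging=3)


class TestAssignColors:
    def test_post_activation_frame_gets_activator_channel(self):
        # cycle: a405 a405 img img img a457 a457 img img img
        table = LocalizationTable.from_arrays(
            [0.0, 0.0], [0.0, 0.0], [2, 7], n_frames=10)
        out = assign_colors(table, MULTI)
        assert list(out.df["channel"]) == ["ch405", "ch457"]

    def test_later_imaging_frames_are_nonspecific(self):
        table = LocalizationTable.from_arrays(
            [0.0, 0.0, 0.0], [0.0] * 3, [3, 4, 9], n_frames=10)
        out = assign_colors(table, MULTI)
        assert set(out.df["channel"]) == {"nonspecific"}

    def test_empty_table_passes_through(self):
        table = LocalizationTable.from_arrays([], [], [], n_frames=10)
        assert len(assign_colors(table, MULTI)) == 0

    @pytest.mark.parametrize("schedule", [
        ActivationSchedule.single_color("ch405", 1, 3),
        ActivationSchedule.single_color("ch532", 2, 4),
        ActivationSchedule.multicolor(("ch405", "ch457", "ch532")),
    ])
    def test_pure_function_of_frame_and_schedule(self, schedule, rng):
        frames = rng.integers(0, 40 * schedule.cycle_len, size=300)
        t1 = LocalizationTable.from_arrays(np.zeros(300), np.zeros(300), frames,
                                           n_frames=40 * schedule.cycle_len)
        a = assign_colors(t1, schedule).df["channel"]
        b = assign_colors(t1.copy(), schedule).df["channel"]
        assert list(a) == list(b)
        # frame slot alone decides the channel
        slots = frames % schedule.cycle_len
        for s in np.unique(slots):
            assert a[slots == s].nunique() == 1


def _counts_table(per_slot_counts, schedule, n_cycles):
    """Table with a given number of localizations in each cycle slot."""
    frames = []
    for c in range(n_cycles):
        for slot, k in per_slot_counts.items():
            frames += [c * schedule.cycle_len + slot] * k
    frames = np.asarray(frames)
    return LocalizationTable.from_arrays(
        np.zeros(len(frames)), np.zeros(len(frames)), frames,
        n_frames=n_cycles * schedule.cycle_len)


class TestEstimateCrosstalk:
    def test_stated_subtraction_arithmetic(self):
        # 120 per post-activation frame, 20 in each other imaging frame
        sched = ActivationSchedule.single_color("ch405", 1, 3)
        table = _counts_table({1: 120, 2: 20, 3: 20}, sched, n_cycles=50)
        table = assign_colors(table, sched)
        est = estimate_crosstalk(table, sched)
        assert est.apparent_specific["ch405"] == 120 * 50
        assert est.nonspecific_per_frame == pytest.approx(20.0)
        assert est.actual_specific["ch405"] == pytest.approx(100.0 * 50)

    def test_zero_nonspecific_keeps_apparent(self):
        sched = ActivationSchedule.single_color("ch405", 1, 3)
        table = assign_colors(_counts_table({1: 80}, sched, 40), sched)
        est = estimate_crosstalk(table, sched)
        assert est.actual_specific["ch405"] == est.apparent_specific["ch405"]

    def test_uniform_counts_mean_zero_actual_specific(self):
        sched = ActivationSchedule.single_color("ch405", 1, 3)
        table = assign_colors(_counts_table({1: 30, 2: 30, 3: 30}, sched, 40),
                              sched)
        est = estimate_crosstalk(table, sched)
        assert est.actual_specific["ch405"] == 0.0

    def test_cycle_without_free_imaging_frames_rejected(self):
        sched = ActivationSchedule.single_color("ch405", 1, 1)
        table = assign_colors(_counts_table({1: 10}, sched, 40), sched)
        with pytest.raises(ValueError, match="nonspecific rate"):
            estimate_crosstalk(table, sched)


class TestSubtractCrosstalk:
    def _mixed_table(self, seed=0, n_cycles=400, n_emitters=1500, rate=None):
        """All-ch405 sample imaged with a two-channel schedule: every ch457
        apparent localization is pure crosstalk."""
        rng = np.random.default_rng(seed)
        from smlm.simulate import EmitterSet

        em = EmitterSet(rng.uniform(0, 4000, (n_emitters, 3)) * [1, 1, 0],
                        ["ch405"] * n_emitters, [0] * n_emitters)
        if rate is None:
            rate = 4.0 / (3.0 * n_cycles)  # 25 % apparent crosstalk
        blink = BlinkModel(nonspecific_rate=rate)
        n_frames = n_cycles * MULTI.cycle_len
        ev = schedule_blinking(em, MULTI, blink, n_frames, seed=seed + 1)
        table = events_to_table(ev, em, n_frames=n_frames, seed=seed + 2)
        return assign_colors(table, MULTI)

    def test_zero_rates_leave_table_unchanged(self):
        sched = ActivationSchedule.single_color("ch405", 1, 3)
        table = assign_colors(_counts_table({1: 50}, sched, 40), sched)
        est = estimate_crosstalk(table, sched)
        out, report = subtract_crosstalk(table, est, seed=1)
        pd.testing.assert_frame_equal(out.df, table.df)
        assert report.removed["ch405"] == 0

    def test_seed_determinism(self):
        table = self._mixed_table()
        est = estimate_crosstalk(table, MULTI)
        out1, _ = subtract_crosstalk(table, est, seed=11)
        out2, _ = subtract_crosstalk(table, est, seed=11)
        pd.testing.assert_frame_equal(out1.df, out2.df)

    def test_injected_apparent_crosstalk_removed(self):
        """~25 % wrong-channel apparent count drops below 5 % (10-seed mean)."""
        table = self._mixed_table(seed=5)
        est = estimate_crosstalk(table, MULTI)
        injected = est.apparent_specific["ch457"] / est.apparent_specific["ch405"]
        assert 0.15 < injected < 0.35
        fracs = []
        for seed in range(10):
            out, _ = subtract_crosstalk(table, est, seed=seed)
            ch = out.df["channel"]
            fracs.append((ch == "ch457").sum() / max((ch == "ch405").sum(), 1))
        assert np.mean(fracs) < 0.05

    def test_unbiased_over_seeds(self):
        """Mean corrected count equals the actual-specific estimate."""
        table = self._mixed_table(seed=8)
        est = estimate_crosstalk(table, MULTI)
        counts = []
        for seed in range(30):
            out, _ = subtract_crosstalk(table, est, seed=seed)
            counts.append((out.df["channel"] == "ch405").sum())
        target = est.actual_specific["ch405"]
        se = np.std(counts) / np.sqrt(len(counts)) + 1.0
        assert np.mean(counts) == pytest.approx(target, abs=4 * se)
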