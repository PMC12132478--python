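"""Windowing, exponential background correction, GV ratios, bootstrap,
and the per-cell no-intercept scatter regression."""

import numpy as np
import pytest

import papaquant as pq
from papaquant import ValidationError
from papaquant.quant import (
    CellScatterPoint,
    ExponentialFit,
    cell_scatter_points,
    cell_scatter_regression,
    corrected_pulse_count,
    fit_baseline,
    no_intercept_slope,
)
from papaquant.synthetic_data import simulate_papa_experiment


class TestAssignWindow:
    @pytest.mark.parametrize(
        "frame,expected",
        [
            (0, (0, "baseline_violet")),
            (49, (0, "baseline_violet")),
            (50, (0, "dr")),
            (149, (0, "baseline_green")),
            (150, (0, "papa")),
            (199, (0, "papa")),
            (215, (1, "baseline_violet")),
        ],
    )
    def test_window_boundaries(self, schedule, frame, expected):
        assert pq.assign_window(frame, schedule) == expected

    def test_out_of_range_frame_rejected(self, schedule):
        with pytest.raises(ValidationError):
            pq.assign_window(600, schedule)
        with pytest.raises(ValidationError):
            pq.assign_window(-1, schedule)


class TestFitBaseline:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(50)
        fit = fit_baseline(8.0 * np.exp(-0.1 * t))
        assert fit.status == "fit"
        assert fit.amplitude == pytest.approx(8.0, abs=1e-6)
        assert fit.rate == pytest.approx(0.1, abs=1e-6)

    def test_constant_series_gives_zero_rate(self):
        fit = fit_baseline(np.full(50, 5.0))
        assert fit.amplitude == pytest.approx(5.0, abs=1e-9)
        assert fit.rate == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_series_falls_back_to_zero_amplitude(self):
        fit = fit_baseline(np.zeros(50))
        assert fit.status == "fallback_constant"
        assert fit.amplitude == 0.0 and fit.rate == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            fit_baseline(np.array([1.0, 2.0]))

    def test_poisson_noise_recovery_from_pooled_cells(self):
        """Pooled counts from many cells recover (A, k) within 10%."""
        rng = np.random.default_rng(0)
        t = np.arange(50)
        a_true, k_true, n_cells = 10.0, 0.05, 200
        errs = []
        for _ in range(20):
            pooled = rng.poisson(
                n_cells * a_true * np.exp(-k_true * t)
            ) / n_cells
            fit = fit_baseline(pooled)
            errs.append((abs(fit.amplitude - a_true) / a_true,
                         abs(fit.rate - k_true) / k_true))
        errs = np.array(errs)
        assert (errs < 0.10).all()


class TestCorrectedPulseCount:
    def test_zero_amplitude_returns_raw_sum(self):
        pulse = np.array([3.0, 1.0, 4.0])
        fit = ExponentialFit(0.0, 0.3, "fit")
        assert corrected_pulse_count(pulse, fit, 50) == pulse.sum()

    def test_negative_correction_truncated_to_zero(self):
        # raw sum 10, projected background 12 -> 0
        fit = ExponentialFit(12.0, 0.0, "fit")
        assert corrected_pulse_count(np.full(1, 10.0), fit, 0) == 0.0

    def test_matches_brute_force_frame_sum(self):
        a_coef, rate, offset = 8.0, 0.1, 50
        pulse = np.full(50, 3.0)
        fit = ExponentialFit(a_coef, rate, "fit")
        expected = max(
            0.0,
            sum(3.0 - a_coef * np.exp(-rate * (t + offset)) for t in range(50)),
        )
        assert corrected_pulse_count(pulse, fit, offset) == pytest.approx(expected)


def _cells_with_flat_windows(schedule, dr=4, papa=2, baseline=0, n_cells=3):
    fpw = schedule.frames_per_window
    arr = np.zeros((schedule.n_cycles, 4, fpw), dtype=np.int64)
    arr[:, 0, :] = baseline
    arr[:, 2, :] = baseline
    arr[:, 1, :] = dr
    arr[:, 3, :] = papa
    return [arr.copy() for _ in range(n_cells)]


class TestGvRatioAndProximity:
    def test_equal_totals_give_unit_ratio(self, small_schedule):
        cells = _cells_with_flat_windows(small_schedule, dr=3, papa=3)
        papa, dr, ratio = pq.gv_ratio(cells, small_schedule)
        assert ratio == pytest.approx(1.0)

    def test_forced_arithmetic_half_ratio(self, small_schedule):
        cells = _cells_with_flat_windows(small_schedule, dr=6, papa=3)
        papa, dr, ratio = pq.gv_ratio(cells, small_schedule)
        assert papa == pytest.approx(dr / 2)
        assert ratio == pytest.approx(0.5)

    def test_zero_dr_total_raises_named_error(self, small_schedule):
        cells = _cells_with_flat_windows(small_schedule, dr=0, papa=3)
        with pytest.raises(ValidationError, match="cond-x"):
            pq.gv_ratio(cells, small_schedule, condition="cond-x")

    def test_proximity_index_definition_and_identity(self):
        assert pq.proximity_index(1.8, 0.9) == pytest.approx(2.0)
        assert pq.proximity_index(0.73, 0.73) == 1.0
        with pytest.raises(ValidationError):
            pq.proximity_index(1.0, 0.0)

    def test_gv_matches_hand_computation_on_small_simulated_run(
        self, motion, small_layout
    ):
        """End-to-end spreadsheet-style oracle on one emitted table."""
        schedule = pq.IlluminationSchedule(frames_per_window=10, n_cycles=2)
        photo = pq.PhotophysicsParams(n_receivers=200)
        det, _, _, mask, _ = simulate_papa_experiment(
            schedule, photo, motion, small_layout, True, seed=9,
            render_images=False,
        )
        assigned, _ = pq.assign_detections(det, mask)
        cells = pq.window_counts(assigned, schedule)
        papa_total, dr_total, ratio = pq.gv_ratio(list(cells.values()), schedule)

        # independent recomputation: pool frames by hand, refit, re-correct
        fpw, fpc = schedule.frames_per_window, schedule.frames_per_cycle
        frames = assigned.loc[assigned["nucleus"] > 0, "frame"].to_numpy()
        per_frame = np.bincount(frames, minlength=schedule.total_frames)
        expect = {"dr": 0.0, "papa": 0.0}
        for c in range(schedule.n_cycles):
            for b, p, key in ((0, 1, "dr"), (2, 3, "papa")):
                bwin = per_frame[c * fpc + b * fpw : c * fpc + (b + 1) * fpw]
                pwin = per_frame[c * fpc + p * fpw : c * fpc + (p + 1) * fpw]
                fit = fit_baseline(bwin.astype(float))
                proj = fit.amplitude * np.exp(
                    -fit.rate * (np.arange(fpw) + fpw)
                )
                expect[key] += max(0.0, pwin.sum() - proj.sum())
        assert papa_total == pytest.approx(expect["papa"])
        assert dr_total == pytest.approx(expect["dr"])
        assert ratio == pytest.approx(expect["papa"] / expect["dr"])

    def test_scaling_all_counts_leaves_gv_and_index_unchanged(
        self, small_schedule
    ):
        rng = np.random.default_rng(4)
        cells = [
            rng.poisson(3.0, (small_schedule.n_cycles, 4,
                              small_schedule.frames_per_window))
            for _ in range(5)
        ]
        _, _, base = pq.gv_ratio(cells, small_schedule)
        _, _, scaled = pq.gv_ratio([7 * c for c in cells], small_schedule)
        assert scaled == pytest.approx(base, rel=1e-6)


class TestBootstrap:
    def test_identical_cells_collapse_interval_to_a_point(self, small_schedule):
        cells = _cells_with_flat_windows(small_schedule, dr=5, papa=4, n_cells=6)
        lo, hi, _ = pq.bootstrap_proximity(
            cells, cells, small_schedule, n_boot=50, seed=0
        )
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(1.0)

    def test_fixed_seed_reproduces_interval(self, small_schedule):
        rng = np.random.default_rng(5)
        cells = [
            rng.poisson(4.0, (small_schedule.n_cycles, 4,
                              small_schedule.frames_per_window))
            for _ in range(8)
        ]
        runs = [
            pq.bootstrap_proximity(cells, cells, small_schedule, n_boot=40,
                                   seed=123)
            for _ in range(2)
        ]
        assert runs[0][:2] == runs[1][:2]
        assert np.array_equal(runs[0][2], runs[1][2])

    def test_requires_two_cells_per_condition(self, small_schedule):
        cells = _cells_with_flat_windows(small_schedule, n_cells=1)
        with pytest.raises(ValidationError):
            pq.bootstrap_proximity(cells, cells, small_schedule, seed=0)


def test_expected_proximity_index_monotone_in_papa_near(schedule):
    """Raising the near-sender reactivation probability never lowers the
    expected proximity index (checked on the generative expectation)."""
    import dataclasses

    photo = pq.PhotophysicsParams()
    grid = [0.005, 0.008, 0.012, 0.02, 0.05, 0.1]
    values = [
        pq.expected_gv_enrichment(
            schedule, dataclasses.replace(photo, p_reactivate_papa_near=p)
        )
        for p in grid
    ]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestCellScatter:
    def test_exact_no_intercept_slope(self):
        assert no_intercept_slope([1.0, 2.0], [2.0, 4.0]) == pytest.approx(2.0)

    def test_negative_corrected_value_excluded(self, small_schedule):
        fpw = small_schedule.frames_per_window
        good = np.zeros((small_schedule.n_cycles, 4, fpw), np.int64)
        good[:, 1, :] = 30
        good[:, 3, :] = 20
        bad = good.copy()
        bad[:, 2, :] = 40  # green baseline exceeds papa window -> negative
        points = cell_scatter_points({1: good, 2: bad}, small_schedule,
                                     min_detections=100)
        by_label = {p.label: p for p in points}
        assert by_label[1].included
        assert not by_label[2].included
        assert "negative" in by_label[2].exclusion_reason

    def test_low_count_cells_excluded_literally(self, small_schedule):
        fpw = small_schedule.frames_per_window
        arr99 = np.zeros((small_schedule.n_cycles, 4, fpw), np.int64)
        arr99[0, 1, :] = 6  # 60 DR-window detections
        arr99[0, 3, :] = 3
        arr99[0, 3, 0] = 12  # 39 PAPA-window detections -> 99 total
        arr100 = arr99.copy()
        arr100[0, 3, 0] = 13  # -> exactly 100
        points = cell_scatter_points({1: arr99, 2: arr100}, small_schedule)
        by_label = {p.label: p for p in points}
        assert not by_label[1].included
        assert by_label[2].included

    def test_slope_matches_formula_on_noisy_cells(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(50, 400, 50)
        y = 0.8 * x + rng.normal(0, 10, 50)
        points = [
            CellScatterPoint(i, float(xi), float(yi), 1000, True)
            for i, (xi, yi) in enumerate(zip(x, y))
        ]
        fit = cell_scatter_regression(points, n_boot=100, seed=0)
        assert fit["slope"] == pytest.approx(float((x * y).sum() / (x * x).sum()))
        assert fit["ci_low"] <= fit["slope"] <= fit["ci_high"]

    def test_degenerate_x_rejected(self):
        points = [
            CellScatterPoint(0, 0.0, 1.0, 1000, True),
            CellScatterPoint(1, 0.0, 2.0, 1000, True),
        ]
        with pytest.raises(ValidationError):
            cell_scatter_regression(points, seed=0)
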