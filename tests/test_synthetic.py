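"""Generator contracts: closed-form values, seeded determinism, ground truth."""

import itertools

import numpy as np
import pytest

from mitophys import (
    DynamicsSimParams,
    SpindleSimParams,
    TraceSimParams,
    simulate_cohort,
    simulate_mt_tracks,
    simulate_spindles,
    simulate_trace,
)
from mitophys.synthetic import cell_signal


class TestTraceGenerator:
    def test_noise_free_line_has_closed_form_value(self):
        """With no oscillations/transients/noise the cell signal is exactly
        baseline + slope*t: 100 - 0.001*1000 = 99 at t=1000 s."""
        params = TraceSimParams(
            baseline_f0=100.0, bleach_slope=-0.001,
            oscillation_components=(), noise_sd=0.0,
            background_mean=0.0, background_noise_sd=0.0,
        )
        trace = simulate_trace(params)
        i = np.argmin(np.abs(trace.t - 1000.0))
        assert trace.t[i] == 1000.0
        assert trace.integrated_intensity[i] == pytest.approx(99.0, abs=1e-12)

    def test_same_seed_gives_bit_identical_traces(self):
        params = TraceSimParams(seed=42)
        a, b = simulate_trace(params), simulate_trace(params)
        np.testing.assert_array_equal(a.integrated_intensity, b.integrated_intensity)
        np.testing.assert_array_equal(a.background, b.background)

    def test_trace_mean_over_integer_periods_is_baseline(self):
        """Zero noise, zero slope, oscillation completing integer periods:
        the mean cell signal equals the baseline."""
        # 9 full periods of 800 s over the 7200-s recording
        params = TraceSimParams(
            bleach_slope=0.0, noise_sd=0.0,
            oscillation_components=((1.0 / 800.0, 5.0, 0.0),),
        )
        signal = cell_signal(params, params.time_grid)
        assert signal.mean() == pytest.approx(params.baseline_f0, rel=1e-9)

    def test_time_grid_matches_recording_design(self):
        trace = simulate_trace(TraceSimParams())
        assert trace.n_frames == 720
        assert trace.dt == 10.0
        assert trace.background.shape[0] == 3

    def test_transient_peak_shape_is_gaussian_with_given_fwhm(self):
        params = TraceSimParams(
            bleach_slope=0.0, noise_sd=0.0,
            oscillation_components=(),
            transient_peaks=((3600.0, 8.0, 200.0),),
        )
        y = cell_signal(params, params.time_grid) - params.baseline_f0
        t = params.time_grid
        assert y.max() == pytest.approx(8.0, rel=1e-12)
        # half maximum reached at center ± fwhm/2
        half = np.interp(3600.0 + 100.0, t, y)
        assert half == pytest.approx(4.0, rel=1e-9)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(duration=-1.0),
            dict(sample_interval=0.0),
            dict(noise_sd=-1.0),
            dict(n_background_rois=0),
            dict(bleach_slope=0.5),
            dict(oscillation_components=((0.05, 5.0, 0.0),)),  # at Nyquist
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_trace(TraceSimParams(**bad))


class TestCohort:
    def test_cohort_size_and_labels(self):
        groups = {
            "DMSO": TraceSimParams(seed=1),
            "AnCoA4": TraceSimParams(seed=2),
        }
        traces = simulate_cohort(groups, n_cells=5)
        assert len(traces) == 10
        assert sorted({t.group for t in traces}) == ["AnCoA4", "DMSO"]
        assert len({t.cell_id for t in traces}) == 10

    def test_single_cell_per_group(self):
        traces = simulate_cohort({"g": TraceSimParams()}, n_cells=1)
        assert len(traces) == 1

    def test_derived_seeds_make_all_traces_distinct(self):
        traces = simulate_cohort({"g": TraceSimParams(seed=3)}, n_cells=6)
        for a, b in itertools.combinations(traces, 2):
            assert not np.array_equal(a.integrated_intensity, b.integrated_intensity)

    def test_cohort_reproducible(self):
        groups = {"g": TraceSimParams(seed=9)}
        a = simulate_cohort(groups, 3)
        b = simulate_cohort(groups, 3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.integrated_intensity, y.integrated_intensity)

    def test_empty_group_map_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort({}, 5)


class TestMTTrackGenerator:
    def test_pure_growth_displacement_per_frame(self):
        """12 µm/min with no switching and no noise moves 0.1 µm per 0.5-s
        frame."""
        params = DynamicsSimParams(
            growth_speed=12.0, catastrophe_rate=0.0, rescue_rate=0.0,
            position_noise_sd=0.0, n_tracks=1, seed=0,
        )
        (track,) = simulate_mt_tracks(params)
        steps = np.hypot(np.diff(track.x), np.diff(track.y))
        np.testing.assert_allclose(steps, 0.1, rtol=1e-9)
        assert all(p == "growth" for p in track.phase)

    def test_zero_speed_shrink_start_gives_flat_track(self):
        params = DynamicsSimParams(
            shrink_speed=0.0, rescue_rate=0.0, catastrophe_rate=0.0,
            start_phase="shrink", position_noise_sd=0.0, n_tracks=1, seed=0,
        )
        (track,) = simulate_mt_tracks(params)
        assert np.ptp(track.x) == 0.0 and np.ptp(track.y) == 0.0

    def test_switch_counts_match_renewal_expectation(self):
        """With equal catastrophe and rescue rates λ the active phase always
        switches at rate λ, so per-track switch counts are Poisson(λT):
        λ = 2/min over 1 min tracks ⇒ mean 2, checked within 3 SE."""
        params = DynamicsSimParams(
            catastrophe_rate=2.0, rescue_rate=2.0, n_tracks=200, seed=11,
        )
        tracks = simulate_mt_tracks(params)
        switches = [
            sum(1 for a, b in zip(t.phase, t.phase[1:]) if a != b) for t in tracks
        ]
        mean = np.mean(switches)
        se = np.std(switches, ddof=1) / np.sqrt(len(switches))
        assert abs(mean - 2.0) <= 3 * se

    def test_seeded_determinism(self):
        params = DynamicsSimParams(n_tracks=4, seed=5)
        a, b = simulate_mt_tracks(params), simulate_mt_tracks(params)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.x, y.x)
            np.testing.assert_array_equal(x.phase, y.phase)


class TestSpindleGenerator:
    def test_zero_tilt_poles_share_z(self):
        pairs = simulate_spindles(SpindleSimParams(tilt_angle_deg=0.0, n_cells=3))
        for p in pairs:
            assert p.pole_a[2] == pytest.approx(p.pole_b[2], abs=1e-12)

    def test_ninety_degrees_differs_only_in_z(self):
        pairs = simulate_spindles(SpindleSimParams(tilt_angle_deg=90.0, n_cells=3))
        for p in pairs:
            assert np.hypot(*(p.pole_b - p.pole_a)[:2]) == pytest.approx(0.0, abs=1e-12)
            assert abs(p.pole_b[2] - p.pole_a[2]) == pytest.approx(10.0, rel=1e-12)

    def test_tilt_outside_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_spindles(SpindleSimParams(tilt_angle_deg=97.0))

    def test_callable_tilt_distribution(self):
        pairs = simulate_spindles(
            SpindleSimParams(
                tilt_angle_deg=lambda rng, n: rng.uniform(5, 15, n),
                n_cells=10, seed=2,
            )
        )
        assert len(pairs) == 10
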