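"""Phase classification and dynamic-instability metric contracts."""

import math

import numpy as np
import pytest

from mitophys import (
    DynamicsSimParams,
    MTTrack,
    classify_phases,
    dynamicity,
    growth_length,
    growth_speed,
    simulate_mt_tracks,
    summarize_dynamics,
)


def _track(s, dt=0.5, angle=0.3, origin=(2.0, 5.0), phase=None):
    """Build a track from 1-D positions ``s`` along a straight axis."""
    s = np.asarray(s, dtype=float)
    t = np.arange(s.size) * dt
    x = origin[0] + s * math.cos(angle)
    y = origin[1] + s * math.sin(angle)
    return MTTrack(track_id="t", t=t, x=x, y=y, phase=phase)


class TestClassifyPhases:
    def test_monotone_outward_track_is_all_growth(self):
        tr = _track(np.arange(20) * 0.1)  # 12 µm/min
        labels = classify_phases(tr, pause_threshold=1.0).phase
        assert all(l == "growth" for l in labels)

    def test_out_then_in_gives_one_switch(self):
        s = np.concatenate([np.arange(60) * 0.1, 5.9 - np.arange(1, 61) * 0.1])
        tr = _track(s)
        labels = classify_phases(tr).phase
        runs = [labels[0]]
        for l in labels[1:]:
            if l != runs[-1]:
                runs.append(l)
        assert runs == ["growth", "shrink"]

    def test_matches_generator_ground_truth_without_noise(self):
        params = DynamicsSimParams(position_noise_sd=0.0, n_tracks=50, seed=3)
        tracks = simulate_mt_tracks(params)
        agreement = np.mean(
            [np.mean(classify_phases(t).phase == t.phase) for t in tracks]
        )
        assert agreement >= 0.99

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            classify_phases(_track([0.0, 0.1]))


class TestMetrics:
    def test_growth_speed_from_constant_steps(self):
        """0.1 µm per 0.5-s frame → 12 µm·min⁻¹."""
        tr = classify_phases(_track(np.arange(30) * 0.1))
        assert growth_speed(tr) == pytest.approx(12.0, rel=1e-9)

    def test_stationary_track_has_no_growth_intervals(self):
        tr = classify_phases(_track(np.zeros(10) + 1e-6))
        assert math.isnan(growth_speed(tr))

    def test_growth_length_single_and_multiple_runs(self):
        single = classify_phases(_track(np.linspace(0, 1.2, 13)))
        assert growth_length(single) == pytest.approx(1.2, rel=1e-9)
        # 1.0 µm up, back down, then 2.0 µm up → runs of 1.0 and 2.0
        s = np.concatenate([
            np.linspace(0, 1.0, 11),
            np.linspace(0.9, 0.0, 10),
            np.linspace(0.2, 2.0, 10),
        ])
        multi = classify_phases(_track(s))
        assert growth_length(multi) == pytest.approx(1.5, rel=0.05)

    def test_dynamicity_counts_switches_per_minute(self):
        """growth → shrink → growth inside a 60-s track = 2 switches/min."""
        s = np.concatenate([
            np.arange(41) * 0.1,
            4.0 - np.arange(1, 41) * 0.1,
            np.arange(1, 40) * 0.1,
        ])
        tr = classify_phases(_track(s))
        assert tr.lifetime == pytest.approx(59.5)
        assert dynamicity(tr) == pytest.approx(2 / (59.5 / 60.0))

    def test_monotone_track_has_zero_dynamicity(self):
        tr = classify_phases(_track(np.arange(50) * 0.1))
        assert dynamicity(tr) == 0.0

    def test_metrics_invariant_under_rotation_and_translation(self):
        s = np.concatenate([np.arange(41) * 0.1, 4.0 - np.arange(1, 41) * 0.1])
        a = classify_phases(_track(s, angle=0.0, origin=(0.0, 0.0)))
        b = classify_phases(_track(s, angle=2.1, origin=(-31.0, 17.0)))
        assert growth_speed(a) == pytest.approx(growth_speed(b), rel=1e-9)
        assert growth_length(a) == pytest.approx(growth_length(b), rel=1e-9)
        assert dynamicity(a) == pytest.approx(dynamicity(b), rel=1e-12)

    def test_growth_speed_scales_with_inverse_time_axis(self):
        s = np.arange(30) * 0.1
        slow = classify_phases(_track(s, dt=1.0))
        fast = classify_phases(_track(s, dt=0.5))
        assert growth_speed(fast) == pytest.approx(2 * growth_speed(slow), rel=1e-9)

    def test_mean_growth_length_approaches_speed_over_catastrophe_rate(self):
        """Exponential growth excursions of rate r at speed v have mean
        length v/r when excursions are short relative to the recording
        (negligible censoring): 15 µm/min at 12 catastrophes/min → 1.25 µm."""
        params = DynamicsSimParams(
            growth_speed=15.0, shrink_speed=25.0,
            catastrophe_rate=12.0, rescue_rate=12.0,
            position_noise_sd=0.0, n_tracks=300, seed=21,
        )
        tracks = simulate_mt_tracks(params)
        lengths = [growth_length(t) for t in map(classify_phases, tracks)]
        assert np.nanmean(lengths) == pytest.approx(15.0 / 12.0, rel=0.15)


class TestSummaries:
    def test_single_track_group_summary_equals_track_metrics(self):
        s = np.concatenate([np.arange(41) * 0.1, 4.0 - np.arange(1, 41) * 0.1])
        tr = _track(s)
        tr.group = "g"
        per_track, summary = summarize_dynamics([tr])
        classified = classify_phases(tr)
        assert summary.loc[0, "growth_speed_um_min_mean"] == pytest.approx(
            growth_speed(classified)
        )
        assert summary.loc[0, "n_tracks"] == 1

    def test_two_identical_groups_identical_summaries(self):
        tracks = simulate_mt_tracks(DynamicsSimParams(n_tracks=10, seed=4))
        both = []
        for grp in ("a", "b"):
            for tr in tracks:
                import dataclasses
                both.append(dataclasses.replace(tr, group=grp))
        _, summary = summarize_dynamics(both)
        cols = [c for c in summary.columns if c not in ("group",)]
        assert summary.loc[0, cols].tolist() == summary.loc[1, cols].tolist()

    def test_min_length_filter_counts_exclusions(self):
        good = simulate_mt_tracks(DynamicsSimParams(n_tracks=3, seed=5))
        short = MTTrack("short", t=[0.0, 0.5, 1.0], x=[0, 0.1, 0.2], y=[0, 0, 0])
        _, summary = summarize_dynamics(good + [short], min_frames=4)
        assert summary.loc[0, "n_tracks"] == 3
        assert summary.loc[0, "n_excluded"] == 1

    def test_cohort_contrast_recovered(self):
        """Two cohorts simulated at the control and knockdown growth speeds
        differ by the injected ~8.6% in the recovered cohort means."""
        means = {}
        for gs, seed in [(19.12, 7), (20.77, 8)]:
            tracks = simulate_mt_tracks(
                DynamicsSimParams(growth_speed=gs, n_tracks=100, seed=seed)
            )
            per_track, _ = summarize_dynamics(tracks)
            means[gs] = per_track["growth_speed_um_min"].mean()
        contrast = 100 * (means[20.77] - means[19.12]) / means[19.12]
        assert contrast == pytest.approx(100 * (20.77 - 19.12) / 19.12, abs=1.5)
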