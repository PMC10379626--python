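"""Insole-force turn segmentation, alternation and feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carvemetrics.force_features import (
    ForceTrace,
    apply_exclusions,
    baseline_zero,
    enforce_alternation,
    extract_turn_features,
    features_to_frame,
    segment_turns_force,
    total_force,
)
from carvemetrics.pipeline import run_force_pipeline
from carvemetrics.signal_core import InvalidParameterError, UniformSeries
from carvemetrics.synthetic_data import cosine_keyframes, simulate_run


def _trace_from_total(total, side, fs=100.0):
    """Split a total-force curve 30/40/30 into a ForceTrace."""
    total = np.asarray(total, float)
    mk = lambda p: UniformSeries(total * p, fs)
    return ForceTrace(mk(0.3), mk(0.4), mk(0.3), side)


class TestTotalForce:
    def test_elementwise_sum(self):
        tr = ForceTrace(
            UniformSeries([1.0, 2.0], 100.0),
            UniformSeries([3.0, 4.0], 100.0),
            UniformSeries([5.0, 6.0], 100.0),
            "left",
        )
        assert total_force(tr).values.tolist() == [9.0, 12.0]

    def test_zero_regions_give_zero_total(self):
        tr = _trace_from_total(np.zeros(10), "left")
        assert np.all(total_force(tr).values == 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            ForceTrace(
                UniformSeries([1.0, 2.0], 100.0),
                UniformSeries([1.0, 2.0, 3.0], 100.0),
                UniformSeries([1.0, 2.0], 100.0),
                "left",
            )

    def test_conservation_on_generator_output(self, noise_free_config):
        run = simulate_run(0, "BOA", 1, sim_config=noise_free_config,
                           include_imu=False)
        tr = run.force_left
        expected = (tr.heel.values + tr.medial_forefoot.values
                    + tr.lateral_forefoot.values)
        assert np.allclose(total_force(tr).values, expected, atol=1e-12)


class TestBaselineZero:
    def test_offset_removed_and_floored(self, rng):
        raw = np.abs(rng.normal(300, 50, 1000)) + 40.0
        out = baseline_zero(UniformSeries(raw, 100.0))
        assert out.values.min() >= 0.0
        assert out.values.min() < raw.min()


class TestEnforceAlternation:
    def test_already_alternating_unchanged(self):
        left, right = enforce_alternation([100], [200])
        assert left.tolist() == [100] and right.tolist() == [200]

    def test_duplicate_side_detection_removed(self):
        # L@1s, L@1.5s, R@2s: the subsequent same-side peak is a false
        # detection and is dropped
        left, right = enforce_alternation([100, 150], [200])
        assert left.tolist() == [100] and right.tolist() == [200]

    def test_single_peak_is_trivially_alternating(self):
        left, right = enforce_alternation([], [100])
        assert left.size == 0 and right.tolist() == [100]

    def test_both_empty(self):
        left, right = enforce_alternation([], [])
        assert left.size == 0 and right.size == 0

    @settings(deadline=None, max_examples=200)
    @given(
        left=st.lists(st.integers(0, 1000), max_size=15, unique=True),
        right=st.lists(st.integers(0, 1000), max_size=15, unique=True),
    )
    def test_output_alternates_and_keeps_earliest_of_each_run(self, left, right):
        kept_l, kept_r = enforce_alternation(sorted(left), sorted(right))
        merged = sorted(
            [(i, "L") for i in kept_l] + [(i, "R") for i in kept_r]
        )
        # strict alternation
        for (a, sa), (b, sb) in zip(merged, merged[1:]):
            assert sa != sb
        # independent oracle: scan the merged input, keep first of each run
        events = sorted(
            [(i, "L") for i in sorted(left)] + [(i, "R") for i in sorted(right)],
            key=lambda e: (e[0], e[1] != "L"),
        )
        expect, last = [], None
        for i, s in events:
            if s != last:
                expect.append((i, s))
                last = s
        assert merged == sorted(expect)


class TestExtractFeatures:
    def _ramp_run(self):
        """Two-sided run whose left foot has one raised-cosine bump rising
        300 -> 750 N over 1.5 s: closed-form rfd 300 N/s, average 525 N."""
        fs = 100.0
        t = np.arange(int(8.0 * fs) + 1) / fs
        left = cosine_keyframes(
            t, np.array([0.0, 1.5, 3.0, 4.5, 6.5, 8.0]),
            np.array([500.0, 300.0, 750.0, 300.0, 500.0, 400.0]),
        )
        right = np.full_like(t, 400.0)
        return (_trace_from_total(left, "left"), _trace_from_total(right, "right"))

    def test_closed_form_ramp_features(self):
        left, right = self._ramp_run()
        df = run_force_pipeline(left, right, {"subject_id": "S", "config": "BOA",
                                              "trial_no": 1})
        assert len(df) == 1
        row = df.iloc[0]
        assert row.peak_downhill_force == pytest.approx(750.0, abs=3.0)
        assert row.rfd == pytest.approx(300.0, rel=0.02)
        assert row.time_to_peak == pytest.approx(1.5, abs=0.03)
        assert row.average_force == pytest.approx(525.0, abs=5.0)
        assert row.turn_direction == "right"  # peak under the left foot

    def test_mirrored_run_flips_direction_only(self):
        left, right = self._ramp_run()
        meta = {"subject_id": "S", "config": "BOA", "trial_no": 1}
        a = run_force_pipeline(left, right, meta)
        swapped_left = ForceTrace(right.heel, right.medial_forefoot,
                                  right.lateral_forefoot, "left")
        swapped_right = ForceTrace(left.heel, left.medial_forefoot,
                                   left.lateral_forefoot, "right")
        b = run_force_pipeline(swapped_left, swapped_right, meta)
        assert len(a) == len(b) == 1
        assert b.iloc[0].peak_downhill_force == pytest.approx(
            a.iloc[0].peak_downhill_force, abs=1e-6
        )
        assert b.iloc[0].turn_direction == "left"
        assert b.iloc[0].downhill_foot == "right"

    def test_generator_peaks_recovered_within_two_percent(self, noise_free_config):
        run = simulate_run(2, "Buckle", 1, sim_config=noise_free_config,
                           include_imu=False)
        meta = {"subject_id": run.subject_id, "config": run.config, "trial_no": 1}
        df = run_force_pipeline(run.force_left, run.force_right, meta)
        truth = {
            (t.downhill_foot, round(t.apex_time, 1)): t for t in run.truth.turns
        }
        assert len(df) >= 6
        for _, row in df.iterrows():
            key = (row.downhill_foot, round(row.peak_time, 1))
            if key not in truth:  # detection time may round across the grid
                continue
            t = truth[key]
            assert row.peak_downhill_force == pytest.approx(t.peak_force, rel=0.02)
            assert row.peak_uphill_force == pytest.approx(t.uphill_force, rel=0.02)
            assert row.rfd == pytest.approx(t.rfd, rel=0.02)
            assert row.time_to_peak == pytest.approx(t.time_to_peak, abs=0.05)

    def test_rfd_equals_secant_slope_identity(self, noise_free_config):
        run = simulate_run(1, "BOA", 2, sim_config=noise_free_config,
                           include_imu=False)
        meta = {"subject_id": "S01", "config": "BOA", "trial_no": 2}
        df = run_force_pipeline(run.force_left, run.force_right, meta)
        secant = (df.rise_end_force - df.rise_start_force) / df.time_to_peak
        assert np.allclose(df.rfd, secant, atol=1e-9)

    def test_segmentation_alternates_near_truth_apices(self, noise_free_config):
        run = simulate_run(0, "Buckle", 1, sim_config=noise_free_config,
                           include_imu=False)
        left_t = total_force(run.force_left.truncate())
        right_t = total_force(run.force_right.truncate())
        extrema = segment_turns_force(left_t, right_t)
        fs = left_t.sample_rate
        truth = {
            s: [t.apex_time for t in run.truth.turns
                if t.downhill_foot == s and t.apex_time < left_t.duration - 0.3]
            for s in ("left", "right")
        }
        for side in ("left", "right"):
            got = extrema[side].maxima / fs
            expect = np.asarray(truth[side])
            assert len(got) >= len(expect)
            for apex in expect:
                assert np.min(np.abs(got - apex)) < 0.2

    def test_constant_load_has_no_extrema(self):
        flat = _trace_from_total(np.full(1500, 600.0), "left")
        flat_r = _trace_from_total(np.full(1500, 600.0), "right")
        ex = segment_turns_force(total_force(flat), total_force(flat_r))
        assert ex["left"].maxima.size == 0 and ex["right"].maxima.size == 0


class TestExclusions:
    @staticmethod
    def _features(subject, config, trial, n):
        return pd.DataFrame(
            {
                "subject_id": [subject] * n,
                "config": [config] * n,
                "trial_no": [trial] * n,
                "turn_direction": ["left"] * n,
                "peak_downhill_force": [700.0] * n,
            }
        )

    def test_trial_below_five_turns_dropped_boundary_kept(self):
        df = pd.concat(
            [self._features("A", "BOA", 1, 4), self._features("A", "BOA", 2, 5),
             self._features("A", "BOA", 3, 5)],
            ignore_index=True,
        )
        kept, report = apply_exclusions(df)
        assert ("A", "BOA", "1") in report["dropped_trials"]
        assert set(kept.trial_no) == {2, 3}
        assert report["n_subjects_retained"] == 1

    def test_subject_with_half_of_trials_dropped_is_excluded(self):
        frames = [self._features("A", "BOA", t, 2) for t in (1, 2, 3)]
        frames += [self._features("A", "Buckle", t, 8) for t in (1, 2, 3)]
        frames += [self._features("B", c, t, 8) for c in ("BOA", "Buckle")
                   for t in (1, 2, 3)]
        kept, report = apply_exclusions(pd.concat(frames, ignore_index=True))
        assert report["excluded_subjects"] == ["A"]
        assert report["n_subjects_retained"] == 1
        assert set(kept.subject_id) == {"B"}

    def test_empty_input(self):
        kept, report = apply_exclusions(pd.DataFrame())
        assert kept.empty and report["n_subjects_retained"] == 0
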