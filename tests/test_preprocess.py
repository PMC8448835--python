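"""Validity filtering, the velocity-threshold fixation detector (checked
against a brute-force per-sample oracle), and gaze-step extraction."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_recording, synthetic_trace
from gazedyn.preprocess import (
    DetectionParams,
    compute_gaze_steps,
    count_flips,
    detect_fixations,
    filter_validity,
    subject_inclusion,
)

DT = 1000.0 / 120.0


def _raw_frame(n, validity_left=0, validity_right=0, trial_id=0):
    return pd.DataFrame(
        {
            "timestamp": np.arange(n) * DT,
            "x_left": np.full(n, 100.0),
            "y_left": np.full(n, 100.0),
            "x_right": np.full(n, 102.0),
            "y_right": np.full(n, 104.0),
            "pupil_left": np.full(n, 3.0),
            "pupil_right": np.full(n, 3.2),
            "validity_left": np.full(n, validity_left),
            "validity_right": np.full(n, validity_right),
            "trial_id": np.full(n, trial_id),
        }
    )


class TestFilterValidity:
    def test_all_valid_retained_and_averaged(self):
        rec = make_recording(_raw_frame(10))
        samples, usable = filter_validity(rec)
        assert len(samples) == 10
        assert np.allclose(samples["x"], 101.0)
        assert np.allclose(samples["y"], 102.0)
        assert np.allclose(samples["pupil"], 3.1)
        assert usable.loc[0] == 1.0

    def test_single_bad_eye_drops_sample(self):
        df = _raw_frame(10)
        df.loc[3, "validity_left"] = 1
        samples, usable = filter_validity(make_recording(df))
        assert len(samples) == 9
        assert usable.loc[0] == pytest.approx(0.9)

    def test_all_invalid_returns_empty_not_raise(self):
        samples, usable = filter_validity(make_recording(_raw_frame(5, 4, 4)))
        assert len(samples) == 0
        assert usable.loc[0] == 0.0

    def test_empty_recording_raises(self):
        with pytest.raises(ValueError):
            filter_validity(make_recording(_raw_frame(0)))


class TestSubjectInclusion:
    def test_perfect_data_included(self):
        assert subject_inclusion(pd.Series([1.0] * 10))

    def test_excessive_loss_excluded(self):
        # 40% usable in 30% of trials -> exclude
        fr = pd.Series([0.4] * 3 + [1.0] * 7)
        assert not subject_inclusion(fr)

    def test_boundaries_count_as_acceptable(self):
        # usable exactly 50% is usable; affected fraction exactly 25% includes
        assert subject_inclusion(pd.Series([0.5] * 10))
        assert subject_inclusion(pd.Series([0.4] * 1 + [1.0] * 3))

    def test_no_trials_raises(self):
        with pytest.raises(ValueError):
            subject_inclusion(pd.Series(dtype=float))


def brute_force_detect(samples, params, geometry):
    """Independent per-sample velocity-threshold oracle (naive loops)."""
    out = []
    dt_s = geometry.dt_ms / 1000.0
    k = params.velocity_window // 2
    for trial_id in sorted(samples["trial_id"].unique()):
        tdf = samples[samples["trial_id"] == trial_id]
        t = tdf["timestamp"].tolist()
        x = tdf["x"].tolist()
        y = tdf["y"].tolist()
        n = len(t)
        if n < params.velocity_window:
            continue
        vx, vy = [None] * n, [None] * n
        for i in range(k, n - k):
            sx = sum(x[i + 1 : i + k + 1]) - sum(x[i - k : i])
            sy = sum(y[i + 1 : i + k + 1]) - sum(y[i - k : i])
            vx[i] = sx / (k * (k + 1) * dt_s)
            vy[i] = sy / (k * (k + 1) * dt_s)
        for i in range(k):
            vx[i], vy[i] = vx[k], vy[k]
            vx[n - 1 - i], vy[n - 1 - i] = vx[n - k - 1], vy[n - k - 1]
        med = lambda a: float(np.median(a))
        sx_ = max(med([v**2 for v in vx]) - med(vx) ** 2, 1e-12) ** 0.5
        sy_ = max(med([v**2 for v in vy]) - med(vy) ** 2, 1e-12) ** 0.5
        sacc = [
            (vx[i] / (params.lam * sx_)) ** 2 + (vy[i] / (params.lam * sy_)) ** 2 > 1
            for i in range(n)
        ]
        i = 0
        while i < n:
            if not sacc[i]:
                j = i
                while j < n and not sacc[j]:
                    j += 1
                dur = t[j - 1] - t[i]
                if j - i >= 2 and dur >= params.min_fixation_duration:
                    out.append(
                        {
                            "trial_id": trial_id,
                            "onset": t[i],
                            "offset": t[j - 1],
                            "n_samples": j - i,
                        }
                    )
                i = j
            else:
                i += 1
    return pd.DataFrame(out)


def _piecewise_trace(rng, geometry, n_epochs=4):
    """Stationary epochs joined by fast super-threshold ramps, plus tiny
    jitter so the dispersion estimate is nonzero."""
    chunks = []
    pos = np.array([300.0, 250.0])
    for _ in range(n_epochs):
        n_fix = rng.integers(30, 80)
        jitter = rng.normal(0, 0.3, (n_fix, 2))
        chunks.append(pos + jitter)
        target = pos + rng.uniform(-1, 1, 2) * 150.0
        n_ramp = 3
        ramp = np.linspace(pos, target, n_ramp + 2)[1:-1]
        chunks.append(ramp)
        pos = target
    return np.vstack(chunks)


class TestDetectFixations:
    params = DetectionParams()

    def test_constant_position_one_fixation(self, geometry):
        rng = np.random.default_rng(0)
        pos = np.full((120, 2), 300.0) + rng.normal(0, 0.2, (120, 2))
        fix = detect_fixations(synthetic_trace(pos), self.params, geometry)
        assert len(fix) == 1
        assert abs(fix.iloc[0]["duration"] - 1000.0) <= geometry.dt_ms * 2

    def test_two_epochs_with_ramp(self, geometry):
        rng = np.random.default_rng(1)
        n = 48  # 400 ms epochs
        a = np.full((n, 2), 200.0) + rng.normal(0, 0.2, (n, 2))
        ramp = np.linspace([200, 200], [450, 200], 7)[1:-1]  # ~40 ms, ~10 deg
        b = np.full((n, 2), 450.0)
        b[:, 1] = 200.0
        b += rng.normal(0, 0.2, (n, 2))
        pos = np.vstack([a, ramp, b])
        fix = detect_fixations(synthetic_trace(pos), self.params, geometry)
        assert len(fix) == 2

    def test_dense_jumps_leave_no_fixations(self, geometry):
        """In a region where super-threshold jumps recur faster than the
        minimum fixation duration no stationary run survives (a calm
        leading epoch anchors the dispersion estimate, as the threshold is
        adaptive)."""
        rng = np.random.default_rng(2)
        calm = np.full((150, 2), 300.0) + rng.normal(0, 0.2, (150, 2))
        jumpy = np.full((60, 2), 300.0) + rng.normal(0, 0.2, (60, 2))
        sign = 1.0
        for j in range(3, 60, 4):
            jumpy[j:] += sign * 200.0
            sign = -sign
        pos = np.vstack([calm, jumpy])
        fix = detect_fixations(synthetic_trace(pos), self.params, geometry)
        calm_end_ms = 150 * DT
        assert len(fix) >= 1
        assert (fix["onset"] < calm_end_ms).all()
        assert (fix["offset"] <= calm_end_ms + 5 * DT).all()

    def test_trial_shorter_than_window(self, geometry):
        pos = np.full((3, 2), 100.0)
        fix = detect_fixations(synthetic_trace(pos), self.params, geometry)
        assert len(fix) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, geometry, seed):
        rng = np.random.default_rng(seed)
        pos = _piecewise_trace(rng, geometry)
        samples = synthetic_trace(pos)
        ours = detect_fixations(samples, self.params, geometry)
        oracle = brute_force_detect(samples, self.params, geometry)
        assert len(ours) == len(oracle)
        if len(ours):
            assert np.allclose(ours["onset"].to_numpy(), oracle["onset"].to_numpy())
            assert np.allclose(ours["offset"].to_numpy(), oracle["offset"].to_numpy())

    def test_fixation_durations_bounded_by_trial(self, one_subject, geometry):
        fix = one_subject["fixations"]
        rec = one_subject["recording"]
        ts = rec.samples.groupby("trial_id")["timestamp"]
        trial_dur = ts.max() - ts.min() + geometry.dt_ms
        total = fix.groupby("trial_id")["duration"].sum()
        assert (total <= trial_dur.loc[total.index] + 1e-9).all()


class TestGazeSteps:
    def test_step_lengths_example(self, geometry):
        pos = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        steps, flips = compute_gaze_steps(synthetic_trace(pos), geometry)
        assert np.allclose(steps["length_px"], [5.0, 0.0])

    def test_flip_counting(self):
        assert count_flips(np.array([1.0, 2.0, -1.0, 3.0])) == 2
        assert count_flips(np.array([0.0, 0.0])) == 0
        assert count_flips(np.array([1.0, 0.0, 2.0, -3.0])) == 1

    def test_stationary_trace_zero_steps_and_flips(self, geometry):
        pos = np.full((50, 2), 123.0)
        steps, flips = compute_gaze_steps(synthetic_trace(pos), geometry)
        assert (steps["length_px"] == 0).all()
        assert flips["x_flips"].sum() == 0 and flips["y_flips"].sum() == 0

    def test_no_steps_across_gaps(self, geometry):
        pos = np.tile([50.0, 60.0], (20, 1))
        df = synthetic_trace(pos)
        df.loc[10:, "timestamp"] += 500.0  # dropout gap
        steps, _ = compute_gaze_steps(df, geometry)
        assert len(steps) == 18  # 9 pairs per segment

    def test_translation_invariance(self, geometry):
        rng = np.random.default_rng(3)
        pos = rng.uniform(100, 400, (60, 2))
        s1, f1 = compute_gaze_steps(synthetic_trace(pos), geometry)
        s2, f2 = compute_gaze_steps(synthetic_trace(pos + [55.5, -20.0]), geometry)
        assert np.allclose(s1["length_px"], s2["length_px"])
        pd.testing.assert_frame_equal(f1, f2)

    def test_fewer_than_two_samples(self, geometry):
        steps, flips = compute_gaze_steps(
            synthetic_trace(np.array([[1.0, 2.0]])), geometry
        )
        assert len(steps) == 0
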