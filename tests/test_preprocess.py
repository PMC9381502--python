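"""Gap filling, filtering, stance detection, normalization, gait events,
GRF landmarks and the residual QC rule."""

import statistics

import numpy as np
import pytest

from ankleaxis.preprocess import (
    GRFLandmarks,
    LandmarksUndefinedError,
    NoContactError,
    PreprocessError,
    TrialNormalized,
    TrialRaw,
    detect_next_heelstrike,
    detect_stance,
    fill_gaps,
    gait_speed,
    grf_landmarks,
    lowpass_filter,
    reference_clouds,
    residual_qc,
    time_normalize,
)
from ankleaxis.geometry import Pose
from ankleaxis.synthetic import WalkConfig, gen_walking_trial

from conftest import fit_single


class TestFillGaps:
    def test_no_gaps_is_identity(self):
        traj = np.random.default_rng(0).normal(size=(50, 3))
        assert np.array_equal(fill_gaps(traj), traj)

    def test_linear_ramp_filled_exactly(self):
        traj = np.linspace(0, 49, 50)[:, None] * np.array([1.0, 2.0, -0.5])
        gapped = traj.copy()
        gapped[10:13] = np.nan
        filled = fill_gaps(gapped)
        assert np.allclose(filled, traj, atol=1e-12)

    def test_gap_longer_than_limit_left_missing(self):
        traj = np.linspace(0, 49, 50)[:, None] * np.ones(3)
        gapped = traj.copy()
        gapped[10:21] = np.nan  # 11 frames
        filled = fill_gaps(gapped, max_gap_frames=10)
        assert np.isnan(filled[10:21]).all()
        gapped = traj.copy()
        gapped[10:20] = np.nan  # exactly 10: filled
        assert not np.isnan(fill_gaps(gapped, max_gap_frames=10)).any()

    def test_boundary_gap_warns_and_stays(self):
        traj = np.ones((20, 3))
        traj[:3] = np.nan
        with pytest.warns(UserWarning, match="boundary"):
            filled = fill_gaps(traj)
        assert np.isnan(filled[:3]).all()


class TestLowpass:
    def test_constant_unchanged(self):
        sig = np.full((200, 3), 7.5)
        assert np.allclose(lowpass_filter(sig, 240.0), sig, atol=1e-9)

    def test_passband_and_stopband(self):
        t = np.arange(4800) / 240.0
        low = np.sin(2 * np.pi * 1.0 * t)
        high = np.sin(2 * np.pi * 100.0 * t)
        out_low = lowpass_filter(low[:, None], 240.0)[:, 0]
        out_high = lowpass_filter(high[:, None], 240.0)[:, 0]
        mid = slice(1200, 3600)  # avoid edge transients
        assert np.max(np.abs(out_low[mid])) == pytest.approx(1.0, rel=0.01)
        assert np.max(np.abs(out_high[mid])) < 0.01

    def test_nan_rejected(self):
        sig = np.ones((100, 3))
        sig[5, 0] = np.nan
        with pytest.raises(PreprocessError):
            lowpass_filter(sig, 240.0)


class TestDetectStance:
    def test_supra_threshold_block(self):
        grf = np.zeros(1000)
        grf[100:701] = 50.0
        assert detect_stance(grf) == (100, 700)

    def test_threshold_is_inclusive_boundary(self):
        grf = np.full(100, 9.9)
        with pytest.raises(NoContactError):
            detect_stance(grf)
        grf[50] = 10.0
        assert detect_stance(grf) == (50, 50)

    def test_generated_grf_duration_within_one_sample(self):
        cfg = WalkConfig(seed=0)
        trial, _, truth = gen_walking_trial(cfg)
        start, end = detect_stance(trial.grf_z)
        duration = (end - start) / cfg.grf_rate_hz
        assert abs(duration - cfg.stance_duration_s) <= 1.0 / cfg.grf_rate_hz


def _static_trial(n_frames=101, rate=100.0):
    tri = np.array([[0.0, 0, 0], [40, 0, 0], [10, 35, 5]])
    arr = np.repeat(tri[None], n_frames, axis=0)
    grf = np.full(n_frames, 800.0)
    return TrialRaw(
        markers={"tibia": (("a", "b", "c"), arr), "talus": (("a", "b", "c"), arr + 5)},
        marker_rate_hz=rate,
        grf_z=grf,
        grf_rate_hz=rate,
        body_weight_N=800.0,
    )


class TestTimeNormalize:
    def test_output_has_101_samples(self):
        trial = _static_trial()
        ref = reference_clouds(trial)
        out = time_normalize(trial, (0, 100), ref)
        assert len(out.poses_tibia) == 101
        assert len(out.poses_talus) == 101
        assert out.grf_bw.shape == (101,)

    def test_stance_of_101_frames_resamples_identically(self):
        # matched rates and a 101-frame stance: resampling is the identity,
        # poses are exactly the identity and GRF is exactly 1 BW
        trial = _static_trial()
        out = time_normalize(trial, (0, 100), reference_clouds(trial))
        assert np.array_equal(out.grf_bw, np.ones(101))
        for pose in out.poses_talus:
            assert np.allclose(pose.R, np.eye(3), atol=1e-12)
        assert out.residual_max["tibia"] < 1e-12

    def test_noise_free_commensurate_trial_residual_zero(self, hinge_fitted):
        results, _ = hinge_fitted
        res = results.trials[0].residual_max
        assert res["tibia"] < 1e-9 and res["talus"] < 1e-9

    def test_gap_inside_stance_invalidates_trial(self):
        trial = _static_trial()
        trial.markers["talus"][1][50, 1, :] = np.nan
        with pytest.raises(PreprocessError):
            time_normalize(trial, (0, 100), reference_clouds(trial))

    def test_landmarks_invariant_to_body_weight_rescaling(self):
        trial, _, _ = gen_walking_trial(WalkConfig(seed=4))
        ref_trial, _, _ = gen_walking_trial(WalkConfig(seed=4))
        ref_trial.grf_z = ref_trial.grf_z * 2.0
        ref_trial.body_weight_N = trial.body_weight_N * 2.0
        stance_a = detect_stance(trial.grf_z)
        stance_b = detect_stance(ref_trial.grf_z)
        ref = reference_clouds(trial)
        a = time_normalize(trial, stance_a, ref)
        b = time_normalize(ref_trial, stance_b, ref)
        assert np.allclose(a.grf_bw, b.grf_bw, atol=1e-12)


class TestGaitEvents:
    def test_speed_closed_form(self):
        arr = np.zeros((11, 1, 3))
        arr[10, 0, 0] = 1400.0  # 1.4 m over 10 frames
        assert gait_speed(arr, 0, 10, 0.1) == pytest.approx(1.4)

    def test_speed_averages_markers(self):
        arr = np.zeros((2, 2, 3))
        arr[1, 0, 0] = 1300.0
        arr[1, 1, 0] = 1500.0
        assert gait_speed(arr, 0, 1, 1.0) == pytest.approx(1.4)

    def test_speed_requires_markers_present(self):
        arr = np.zeros((2, 1, 3))
        arr[1] = np.nan
        with pytest.raises(PreprocessError):
            gait_speed(arr, 0, 1, 1.0)

    def test_synthetic_speed_recovered(self, default_noiseless):
        results, truth = default_noiseless
        assert results.trials[0].gait_speed == pytest.approx(
            truth.gait_speed_mps, abs=0.01
        )

    def test_heelstrike_detection_accuracy_and_determinism(self):
        cfg = WalkConfig(seed=9)
        trial, _, truth = gen_walking_trial(cfg)
        cal = trial.markers["calcaneus"][1]
        start = int(truth.stance_end_s * cfg.marker_rate_hz) + 2
        frame = detect_next_heelstrike(cal, search_start=start)
        assert abs(frame - truth.heelstrike2_frame) <= 5
        assert detect_next_heelstrike(cal, search_start=start) == frame

    def test_rising_foot_has_no_heelstrike(self):
        arr = np.zeros((100, 2, 3))
        arr[:, :, 2] = np.linspace(0, 500, 100)[:, None]
        with pytest.raises(PreprocessError):
            detect_next_heelstrike(arr)


class TestGRFLandmarks:
    def test_synthetic_landmarks_recovered(self, default_noiseless):
        results, truth = default_noiseless
        lm = grf_landmarks(results.trials[0].grf_bw)
        fz2, fz3, fz4 = truth.grf_landmarks_bw
        assert lm.fz2 == pytest.approx(fz2, abs=1e-3)
        assert lm.fz3 == pytest.approx(fz3, abs=1e-3)
        assert lm.fz4 == pytest.approx(fz4, abs=1e-3)
        assert (lm.fz2_pct, lm.fz3_pct, lm.fz4_pct) == truth.grf_landmark_pcts

    def test_printed_participant_means_unload_54_percent(self):
        # Fz2 = 1.39 BW, Fz3 = 0.64 BW: mid-stance unloading rounds to 54%
        lm = GRFLandmarks(1.39, 0.64, 1.19, 25, 50, 75)
        assert round(lm.relative_unloading_pct) == 54

    def test_monotone_grf_rejected(self):
        with pytest.raises(LandmarksUndefinedError):
            grf_landmarks(np.linspace(0, 1.5, 101))
        with pytest.raises(LandmarksUndefinedError):
            grf_landmarks(np.ones(101))


def _normalized_with_residuals(res_tibia, res_talus, name=""):
    poses = [Pose.identity() for _ in range(101)]
    return TrialNormalized(
        poses_tibia=poses,
        poses_talus=poses,
        grf_bw=np.zeros(101),
        gait_speed=None,
        stance_duration=0.6,
        residual_max={"tibia": res_tibia, "talus": res_talus},
        trial=name,
    )


class TestResidualQC:
    def test_equal_residuals_keep_everything(self):
        trials = [_normalized_with_residuals(0.5, 0.5) for _ in range(6)]
        included, excluded = residual_qc(trials)
        assert len(included) == 6 and not excluded

    def test_single_outlier_excluded(self):
        trials = [_normalized_with_residuals(0.5, 0.5, f"t{i}") for i in range(9)]
        trials.append(_normalized_with_residuals(5.0, 0.5, "bad"))
        included, excluded = residual_qc(trials)
        assert [t.trial for t in excluded] == ["bad"]
        assert len(included) == 9

    def test_boundary_is_strictly_greater(self):
        # others' maxima: [0.4, 0.5, 0.6, 0.7] -> Q3 + 1.5 IQR computable
        others = [0.4, 0.5, 0.6, 0.7]
        q1, q2, q3 = statistics.quantiles(others, n=4, method="inclusive")
        fence = q3 + 1.5 * (q3 - q1)
        base = [_normalized_with_residuals(v, 0.1, f"o{v}") for v in others]
        at = base + [_normalized_with_residuals(fence, 0.1, "at")]
        _, excluded = residual_qc(at)
        assert not excluded  # exactly at the fence: retained
        above = base + [_normalized_with_residuals(fence + 1e-9, 0.1, "above")]
        _, excluded = residual_qc(above)
        assert [t.trial for t in excluded] == ["above"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_quantile_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.2, 1.0, size=8)
        vals[rng.integers(8)] *= rng.uniform(1.0, 8.0)
        trials = [
            _normalized_with_residuals(v, rng.uniform(0.2, 0.4), f"t{i}")
            for i, v in enumerate(vals)
        ]
        _, excluded = residual_qc(trials)
        expected = set()
        for i, trial in enumerate(trials):
            for bone in ("tibia", "talus"):
                others = [
                    t.residual_max[bone] for j, t in enumerate(trials) if j != i
                ]
                q1, _, q3 = statistics.quantiles(others, n=4, method="inclusive")
                if trial.residual_max[bone] > q3 + 1.5 * (q3 - q1):
                    expected.add(trial.trial)
        assert {t.trial for t in excluded} == expected

    def test_too_few_trials_skips_with_warning(self):
        with pytest.warns(UserWarning):
            included, excluded = residual_qc([_normalized_with_residuals(1, 1)])
        assert len(included) == 1 and not excluded


class TestPipelineDeterminism:
    def test_identical_raw_trial_gives_bit_identical_normalized(self):
        cfg = WalkConfig(seed=7, marker_noise_mm=0.2)
        out = []
        for _ in range(2):
            trial, standing, _ = gen_walking_trial(cfg)
            results = fit_single(trial, standing)
            out.append(results.trials[0])
        a, b = out
        assert np.array_equal(a.grf_bw, b.grf_bw)
        for pa, pb in zip(a.poses_talus, b.poses_talus):
            assert np.array_equal(pa.R, pb.R) and np.array_equal(pa.t, pb.t)

    def test_residual_grows_with_marker_noise(self):
        worst = []
        for sigma in (0.0, 0.1, 0.5):
            res = []
            for seed in range(3):
                trial, standing, _ = gen_walking_trial(
                    WalkConfig(seed=seed, marker_noise_mm=sigma)
                )
                results = fit_single(trial, standing, lowpass_cutoff_hz=None)
                res.append(max(results.trials[0].residual_max.values()))
            worst.append(np.mean(res))
        assert worst[0] < worst[1] < worst[2]
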