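"""Moving-window FHA analysis: window scheme, rotation gate, period means,
ROM and the quasi-static-style flexion-pair comparison."""

import numpy as np
import pytest

from ankleaxis import fha
from ankleaxis.geometry import (
    GeometryError,
    PlanarAngles,
    axis_orientation,
)
from ankleaxis.preprocess import TrialNormalized
from ankleaxis.synthetic import WalkConfig, gen_walking_trial

from conftest import fit_single, single_trial_windows


def _reverse_trial(trial: TrialNormalized) -> TrialNormalized:
    return TrialNormalized(
        poses_tibia=trial.poses_tibia[::-1],
        poses_talus=trial.poses_talus[::-1],
        grf_bw=trial.grf_bw[::-1].copy(),
        gait_speed=trial.gait_speed,
        stance_duration=trial.stance_duration,
        residual_max=trial.residual_max,
    )


def _window(mid, axis=(0.0, 1.0, 0.0), theta=4.0, valid=True):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    return fha.WindowFHA(
        mid_percent=mid,
        valid=valid,
        theta=theta,
        d_mm=0.0,
        axis=axis if valid else None,
        orientation=axis_orientation(axis) if valid else None,
        planar_increment=PlanarAngles(theta, 0.0, 0.0),
    )


class TestMovingWindow:
    def test_window_grid_midpoints(self, hinge_fitted):
        results, _ = hinge_fitted
        windows = single_trial_windows(results)
        assert [w.mid_percent for w in windows] == list(range(5, 96))
        assert len(windows) == 91

    def test_noiseless_hinge_recovers_axis_exactly(self, hinge_fitted):
        results, _ = hinge_fitted
        valid = [w for w in single_trial_windows(results) if w.valid]
        assert len(valid) > 20
        for w in valid:
            assert w.orientation.inclination == pytest.approx(10.0, abs=1e-6)
            assert w.orientation.deviation == pytest.approx(85.0, abs=1e-6)

    def test_windows_spanning_flexion_reversal_are_gated(self):
        cfg = WalkConfig(
            seed=3,
            axis_schedule=((0.0, 0.0, 90.0), (100.0, 0.0, 90.0)),
            flexion_keyframes=((0.0, 0.0), (50.0, 12.0), (97.0, 0.5), (100.0, 0.5)),
        )
        trial, standing, _ = gen_walking_trial(cfg)
        results = fit_single(trial, standing, lowpass_cutoff_hz=None)
        windows = {w.mid_percent: w for w in single_trial_windows(results)}
        for mid in (49, 50, 51):  # symmetric about the reversal: theta ~ 0
            assert not windows[mid].valid
        assert windows[25].valid and windows[70].valid

    def test_gate_monotonicity(self):
        trial, standing, _ = gen_walking_trial(WalkConfig(seed=5, marker_noise_mm=0.3))
        results = fit_single(trial, standing)
        counts = []
        for gate in (1.0, 2.0, 3.0, 5.0):
            windows = fha.moving_window_fha(results.trials[0], gate_deg=gate)
            counts.append(sum(w.valid for w in windows))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_time_mirrored_trial_gives_same_axes(self, hinge_fitted):
        results, _ = hinge_fitted
        trial = results.trials[0]
        fwd = fha.moving_window_fha(trial)
        rev = fha.moving_window_fha(_reverse_trial(trial))
        for wf, wr in zip(fwd, rev[::-1]):
            assert wf.valid == wr.valid
            assert wf.theta == pytest.approx(wr.theta, abs=1e-9)
            if wf.valid:
                assert np.allclose(wf.axis, wr.axis, atol=1e-9)


class TestTrialPeriodMean:
    def test_constant_axis_mean_is_that_axis(self):
        axis = np.array([0.1, 0.9, 0.2])
        windows = [_window(m, axis) for m in range(15, 26)]
        mean = fha.trial_period_mean(windows, fha.DF_PERIOD)
        expected = axis_orientation(axis / np.linalg.norm(axis))
        assert mean.inclination == pytest.approx(expected.inclination, abs=1e-12)
        assert mean.deviation == pytest.approx(expected.deviation, abs=1e-12)

    def test_opposite_inclinations_average_to_zero(self):
        up = (0.0, np.cos(np.radians(10)), np.sin(np.radians(10)))
        dn = (0.0, np.cos(np.radians(10)), -np.sin(np.radians(10)))
        windows = [_window(15, up), _window(16, dn)]
        mean = fha.trial_period_mean(windows, fha.DF_PERIOD)
        assert mean.inclination == pytest.approx(0.0, abs=1e-12)
        assert mean.deviation == pytest.approx(90.0, abs=1e-12)

    def test_no_valid_windows_is_an_error(self):
        windows = [_window(m, valid=False) for m in range(15, 26)]
        with pytest.raises(GeometryError):
            fha.trial_period_mean(windows, fha.DF_PERIOD)

    def test_constant_axis_df_equals_pf(self, hinge_fitted):
        results, _ = hinge_fitted
        windows = single_trial_windows(results)
        df = fha.trial_period_mean(windows, fha.DF_PERIOD)
        pf = fha.trial_period_mean(windows, fha.PF_PERIOD)
        assert df.inclination == pytest.approx(pf.inclination, abs=1e-6)
        assert df.deviation == pytest.approx(pf.deviation, abs=1e-6)


def _sorted_percentile(values, q):
    """Independent linear-interpolation percentile (sort + index arithmetic)."""
    v = sorted(values)
    pos = q / 100.0 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


class TestSummarizePeriod:
    def test_constant_axis_collapses_statistics(self, hinge_fitted):
        results, _ = hinge_fitted
        summary = fha.summarize_period(results.trial_windows, fha.DF_PERIOD)
        for q in ("inclination", "deviation"):
            s = summary.stats.loc[q]
            assert s["grand_mean"] == pytest.approx(s["min"], abs=1e-6)
            assert s["grand_mean"] == pytest.approx(s["max"], abs=1e-6)

    def test_at_most_11_windows_per_trial_in_period(self):
        for seed in range(3):
            trial, standing, _ = gen_walking_trial(
                WalkConfig(seed=seed, marker_noise_mm=0.2)
            )
            results = fit_single(trial, standing)
            summary = fha.summarize_period(results.trial_windows, fha.DF_PERIOD)
            assert (summary.trial_means["n_valid"] <= 11).all()

    def test_percentiles_match_sort_based_oracle(self):
        trial, standing, _ = gen_walking_trial(WalkConfig(seed=8, marker_noise_mm=0.3))
        results = fit_single(trial, standing)
        summary = fha.summarize_period(results.trial_windows, fha.PF_PERIOD)
        pooled = summary.windows
        for q in ("theta", "inclination", "pf", "d_mm"):
            vals = pooled[q].to_numpy()
            assert summary.stats.loc[q, "p5"] == pytest.approx(
                _sorted_percentile(vals, 5), abs=1e-12
            )
            assert summary.stats.loc[q, "p95"] == pytest.approx(
                _sorted_percentile(vals, 95), abs=1e-12
            )

    def test_empty_pool_is_an_error(self):
        windows = {"t": [_window(m, valid=False) for m in range(5, 96)]}
        with pytest.raises(GeometryError):
            fha.summarize_period(windows, fha.DF_PERIOD)


class TestRomSummary:
    def test_identity_poses_have_zero_rom(self):
        from ankleaxis.geometry import Pose

        trial = TrialNormalized(
            poses_tibia=[Pose.identity()] * 101,
            poses_talus=[Pose.identity()] * 101,
            grf_bw=np.zeros(101),
            gait_speed=None,
            stance_duration=0.6,
            residual_max={"tibia": 0, "talus": 0},
        )
        sag, fro, tra, _ = fha.rom_summary(trial)
        assert sag == fro == tra == 0.0

    def test_pure_flexion_config_rom(self):
        cfg = WalkConfig(
            seed=2,
            axis_schedule=((0.0, 0.0, 90.0), (100.0, 0.0, 90.0)),
            flexion_keyframes=((0.0, 0.0), (40.0, -7.0), (97.0, 8.0), (100.0, 8.0)),
        )
        trial, standing, _ = gen_walking_trial(cfg)
        results = fit_single(trial, standing, lowpass_cutoff_hz=None)
        sag, fro, tra, _ = fha.rom_summary(results.trials[0])
        assert sag == pytest.approx(15.0, abs=0.01)
        assert fro < 0.01 and tra < 0.01

    def test_early_stance_plantarflexion_sign(self, default_noiseless):
        # default flexion rises to +2 deg (plantarflexed) early in stance
        results, _ = default_noiseless
        _, _, _, series = fha.rom_summary(results.trials[0])
        assert series.loc[series["percent"] == 5, "pf"].iloc[0] > 0


class TestFlexionPairs:
    def test_hinge_pairs_recover_axis_inclination(self):
        cfg = WalkConfig(
            seed=6,
            axis_schedule=((0.0, 10.0, 85.0), (100.0, 10.0, 85.0)),
        )
        trial, standing, _ = gen_walking_trial(cfg)
        results = fit_single(trial, standing, lowpass_cutoff_hz=None)
        pairs = fha.flexion_pair_fha(results.trials[0])
        directions = {p.direction for p in pairs}
        assert "DF" in directions and "PF" in directions
        for p in pairs:
            assert p.inclination == pytest.approx(10.0, abs=0.5)
            lo, hi = (10, 30) if max(p.percent_a, p.percent_b) <= 30 else (80, 100)
            assert lo <= p.percent_a <= hi and lo <= p.percent_b <= hi
            assert abs(p.percent_b - p.percent_a) <= 20

    def test_flexion_never_reaching_magnitude_yields_empty(self):
        cfg = WalkConfig(
            seed=2,
            axis_schedule=((0.0, 0.0, 90.0), (100.0, 0.0, 90.0)),
            flexion_keyframes=((0.0, 0.0), (50.0, -3.0), (97.0, 3.0), (100.0, 3.0)),
        )
        trial, standing, _ = gen_walking_trial(cfg)
        results = fit_single(trial, standing, lowpass_cutoff_hz=None)
        assert fha.flexion_pair_fha(results.trials[0]) == []

    def test_separation_rule_rejects_distant_crossings(self, default_noiseless):
        results, _ = default_noiseless
        trial = results.trials[0]
        wide = fha.flexion_pair_fha(trial, max_separation_pct=20)
        narrow = fha.flexion_pair_fha(trial, max_separation_pct=5)
        assert len(narrow) < len(wide)
        for p in narrow:
            assert abs(p.percent_b - p.percent_a) <= 5

    def test_headline_ordering_on_scheduled_axis(self):
        # DF-period inclination scheduled at -10 deg, PF-period at +12 deg:
        # per-trial DF mean must fall below the PF mean at moderate noise
        hits = 0
        for seed in range(20):
            trial, standing, _ = gen_walking_trial(
                WalkConfig(seed=seed, marker_noise_mm=0.2)
            )
            results = fit_single(trial, standing)
            windows = single_trial_windows(results)
            df = fha.trial_period_mean(windows, fha.DF_PERIOD)
            pf = fha.trial_period_mean(windows, fha.PF_PERIOD)
            hits += df.inclination < pf.inclination
        assert hits == 20
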