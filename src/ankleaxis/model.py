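"""Model / Results interface over the analysis pipeline.

:class:`AnkleAxisModel` is built from raw walking trials plus a standing
reference; ``fit()`` runs preprocessing, residual quality control, the
moving-window finite-helical-axis (FHA) analysis and the period summaries,
returning an :class:`AnkleAxisResults` with tidy tables and a printable
``summary()``. :class:`TrochleaMorphologyModel` does the same for the
morphology-based axis estimate from a talus mesh.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fha as _fha
from . import morphology as _morph
from . import preprocess as _pre
from .geometry import GeometryError
from .io import read_mesh, read_trial

__all__ = [
    "AnkleAxisModel",
    "AnkleAxisResults",
    "TrochleaMorphologyModel",
    "TrochleaMorphologyResults",
]


class AnkleAxisModel:
    """Ankle joint axis orientation during stance, from bone-pin markers.

    Parameters
    ----------
    trials
        Raw walking trials (marker + vertical GRF streams).
    reference
        Standing trial defining the 0-degree reference configuration; the
        reference pose of each bone is the mean marker cloud over the trial.
    window_pct, step_pct, gate_deg
        Moving FHA window size and step (% stance) and the minimum rotation
        (deg) for a window orientation to be considered reliable.
    lowpass_cutoff_hz
        Butterworth (zero-phase, 4th order) marker filter cutoff; ``None``
        disables filtering.
    contact_threshold_N, max_gap_frames
        Ground-contact threshold for stance detection and the longest marker
        gap that is still interpolated.
    qc
        Apply the per-participant residual outlier rule (Q3 + 1.5 IQR of the
        other trials' maxima) to exclude trials.
    """

    def __init__(
        self,
        trials: list[_pre.TrialRaw],
        reference: _pre.TrialRaw,
        *,
        window_pct: int = 10,
        step_pct: int = 1,
        gate_deg: float = 2.0,
        lowpass_cutoff_hz: float | None = 10.0,
        filter_order: int = 4,
        contact_threshold_N: float = 10.0,
        max_gap_frames: int = 10,
        qc: bool = True,
    ) -> None:
        if not trials:
            raise ValueError("at least one trial is required")
        self.trials_raw = list(trials)
        self.reference_trial = reference
        self.window_pct = window_pct
        self.step_pct = step_pct
        self.gate_deg = gate_deg
        self.lowpass_cutoff_hz = lowpass_cutoff_hz
        self.filter_order = filter_order
        self.contact_threshold_N = contact_threshold_N
        self.max_gap_frames = max_gap_frames
        self.qc = qc

    @classmethod
    def from_directory(
        cls, trials_dir: str | Path, reference: str | Path, **kwargs
    ) -> "AnkleAxisModel":
        """Build from a directory of trial subdirectories plus a reference."""
        trials_dir = Path(trials_dir)
        trial_paths = sorted(
            d for d in trials_dir.iterdir() if (d / "markers.tsv").exists()
        )
        if not trial_paths:
            raise FileNotFoundError(f"no trials found under {trials_dir}")
        trials = [read_trial(p) for p in trial_paths]
        ref = read_trial(Path(reference))
        return cls(trials, ref, **kwargs)

    # ------------------------------------------------------------------

    def _preprocess_trial(
        self, trial: _pre.TrialRaw, reference: dict
    ) -> _pre.TrialNormalized:
        filled = {}
        for bone, (labels, arr) in trial.markers.items():
            arr = _pre.fill_gaps(arr, max_gap_frames=self.max_gap_frames)
            if self.lowpass_cutoff_hz is not None:
                arr = self._filter_valid_block(arr, trial.marker_rate_hz)
            filled[bone] = (labels, arr)
        work = _pre.TrialRaw(
            markers=filled,
            marker_rate_hz=trial.marker_rate_hz,
            grf_z=trial.grf_z,
            grf_rate_hz=trial.grf_rate_hz,
            body_weight_N=trial.body_weight_N,
            participant=trial.participant,
            trial=trial.trial,
        )
        stance = _pre.detect_stance(work.grf_z, threshold_N=self.contact_threshold_N)
        speed = self._gait_speed(work, stance)
        return _pre.time_normalize(work, stance, reference, gait_speed_mps=speed)

    def _filter_valid_block(self, arr: np.ndarray, rate: float) -> np.ndarray:
        """Zero-phase filter the contiguous gap-free block of a trajectory."""
        finite = np.all(np.isfinite(arr.reshape(arr.shape[0], -1)), axis=1)
        if finite.all():
            return _pre.lowpass_filter(
                arr, rate, cutoff_hz=self.lowpass_cutoff_hz, order=self.filter_order
            )
        idx = np.flatnonzero(finite)
        if len(idx) == 0:
            return arr
        lo, hi = idx[0], idx[-1] + 1
        if not finite[lo:hi].all():
            # interior gaps survived gap filling: leave them for stance checks
            return arr
        out = arr.copy()
        out[lo:hi] = _pre.lowpass_filter(
            arr[lo:hi], rate, cutoff_hz=self.lowpass_cutoff_hz, order=self.filter_order
        )
        return out

    def _gait_speed(
        self, trial: _pre.TrialRaw, stance: tuple[int, int]
    ) -> float | None:
        if "calcaneus" not in trial.markers:
            return None
        cal = trial.markers["calcaneus"][1]
        rate = trial.marker_rate_hz
        hs1 = int(round(stance[0] / trial.grf_rate_hz * rate))
        stance_end = int(round(stance[1] / trial.grf_rate_hz * rate))
        try:
            hs2 = _pre.detect_next_heelstrike(cal, search_start=stance_end + 2)
            return _pre.gait_speed(cal, hs1, hs2, 1.0 / rate)
        except _pre.PreprocessError:
            return None

    def fit(self) -> "AnkleAxisResults":
        """Run the full analysis and return the results object."""
        reference = _pre.reference_clouds(self.reference_trial)
        normalized = [self._preprocess_trial(t, reference) for t in self.trials_raw]
        if self.qc:
            included, excluded = _pre.residual_qc(normalized)
        else:
            included, excluded = normalized, []
        if not included:
            raise _pre.TrialInvalidError("all trials excluded by residual QC")

        trial_windows: dict[str, list[_fha.WindowFHA]] = {}
        window_frames = []
        rom_rows = []
        landmark_rows = []
        pair_rows = []
        for i, trial in enumerate(included):
            tid = trial.trial or f"trial{i}"
            windows = _fha.moving_window_fha(
                trial,
                window_pct=self.window_pct,
                step_pct=self.step_pct,
                gate_deg=self.gate_deg,
            )
            trial_windows[tid] = windows
            window_frames.append(_fha.windows_to_frame(windows, tid))
            sag, frontal, transverse, _series = _fha.rom_summary(trial)
            row = {
                "trial": tid,
                "participant": trial.participant,
                "gait_speed_mps": trial.gait_speed,
                "stance_duration_s": trial.stance_duration,
                "sagittal_rom": sag,
                "frontal_rom": frontal,
                "transverse_rom": transverse,
                "residual_max_tibia": trial.residual_max.get("tibia"),
                "residual_max_talus": trial.residual_max.get("talus"),
            }
            try:
                lm = _pre.grf_landmarks(trial.grf_bw)
                landmark_rows.append(
                    {
                        "trial": tid,
                        "fz2_bw": lm.fz2,
                        "fz3_bw": lm.fz3,
                        "fz4_bw": lm.fz4,
                        "fz2_pct": lm.fz2_pct,
                        "fz3_pct": lm.fz3_pct,
                        "fz4_pct": lm.fz4_pct,
                        "relative_unloading_pct": lm.relative_unloading_pct,
                    }
                )
            except _pre.LandmarksUndefinedError:
                pass
            rom_rows.append(row)
            for pair in _fha.flexion_pair_fha(trial):
                pair_rows.append(
                    {
                        "trial": tid,
                        "direction": pair.direction,
                        "anchor": pair.anchor,
                        "percent_a": pair.percent_a,
                        "percent_b": pair.percent_b,
                        "inclination": pair.inclination,
                        "deviation": pair.deviation,
                        "theta": pair.theta,
                    }
                )

        summaries = {}
        for name, period in (("DF", _fha.DF_PERIOD), ("PF", _fha.PF_PERIOD)):
            try:
                summaries[name] = _fha.summarize_period(trial_windows, period)
            except GeometryError:
                summaries[name] = None

        window_table = (
            pd.concat(window_frames, ignore_index=True)
            if window_frames
            else pd.DataFrame()
        )
        pair_cols = [
            "trial", "direction", "anchor", "percent_a", "percent_b",
            "inclination", "deviation", "theta",
        ]
        return AnkleAxisResults(
            model=self,
            trials=included,
            excluded=excluded,
            trial_windows=trial_windows,
            window_table=window_table,
            trial_summary=pd.DataFrame(rom_rows),
            landmark_table=pd.DataFrame(landmark_rows),
            flexion_pair_table=pd.DataFrame(pair_rows, columns=pair_cols),
            summaries=summaries,
        )


@dataclass
class AnkleAxisResults:
    """Fitted FHA analysis: tidy tables plus period summaries.

    ``summaries`` maps "DF"/"PF" to a :class:`~ankleaxis.fha.PeriodSummary`
    (or None when no valid window fell into a period).
    """

    model: AnkleAxisModel
    trials: list[_pre.TrialNormalized]
    excluded: list[_pre.TrialNormalized]
    trial_windows: dict[str, list[_fha.WindowFHA]]
    window_table: pd.DataFrame
    trial_summary: pd.DataFrame
    landmark_table: pd.DataFrame
    flexion_pair_table: pd.DataFrame
    summaries: dict[str, _fha.PeriodSummary | None]
    morphology_table: pd.DataFrame | None = None

    def period_table(self) -> pd.DataFrame:
        """Long-format period statistics (one row per period x quantity)."""
        rows = []
        for name, summ in self.summaries.items():
            if summ is None:
                continue
            rows.append(
                {"period": name, "quantity": "n_valid", "grand_mean": summ.n_valid}
            )
            for quantity, stats in summ.stats.iterrows():
                rows.append(
                    {"period": name, "quantity": quantity, **stats.to_dict()}
                )
        cols = ["period", "quantity", "grand_mean", "min", "p5", "p95", "max"]
        return pd.DataFrame(rows, columns=cols)

    def trial_period_means(self, period: str) -> pd.DataFrame:
        summ = self.summaries.get(period)
        if summ is None:
            return pd.DataFrame(columns=["trial", "n_valid", "inclination", "deviation"])
        return summ.trial_means

    def summary(self) -> str:
        """Printable overview of walking characteristics and axis statistics."""
        lines = [
            "Ankle joint axis analysis (moving-window finite helical axes)",
            "=" * 62,
            f"trials included: {len(self.trials)}   excluded by residual QC: "
            f"{len(self.excluded)}",
            f"window {self.model.window_pct}% stance, step {self.model.step_pct}%,"
            f" rotation gate {self.model.gate_deg} deg",
            "",
            "Walking characteristics (means over trials)",
            "-" * 62,
        ]
        ts = self.trial_summary
        if len(ts):
            speed = ts["gait_speed_mps"].dropna()
            if len(speed):
                lines.append(f"gait speed        : {speed.mean():6.2f} m/s")
            lines.append(
                f"stance duration   : {ts['stance_duration_s'].mean():6.3f} s"
            )
            lines.append(
                "ROM sagittal/frontal/transverse: "
                f"{ts['sagittal_rom'].mean():.1f} / {ts['frontal_rom'].mean():.1f} /"
                f" {ts['transverse_rom'].mean():.1f} deg"
            )
        if len(self.landmark_table):
            lt = self.landmark_table
            lines.append(
                f"GRF Fz2/Fz3/Fz4   : {lt['fz2_bw'].mean():.2f} / "
                f"{lt['fz3_bw'].mean():.2f} / {lt['fz4_bw'].mean():.2f} BW "
                f"(mid-stance unloading {lt['relative_unloading_pct'].mean():.0f}%)"
            )
        for name, label in (("DF", "Dorsiflexion 15-25%"), ("PF", "Plantarflexion 85-95%")):
            summ = self.summaries.get(name)
            lines += ["", f"{label} stance", "-" * 62]
            if summ is None:
                lines.append("no valid windows")
                continue
            lines.append(f"valid FHAs: {summ.n_valid}")
            for q in ("inclination", "deviation", "theta", "d_mm", "pf"):
                s = summ.stats.loc[q]
                lines.append(
                    f"{q:<12}: mean {s['grand_mean']:7.2f}  "
                    f"[min {s['min']:7.2f}, p5 {s['p5']:7.2f}, "
                    f"p95 {s['p95']:7.2f}, max {s['max']:7.2f}]"
                )
        return "\n".join(lines)


class TrochleaMorphologyModel:
    """Morphology-based ankle axis estimate from a talus surface mesh.

    The mesh must already be expressed in the standing-reference lab frame.
    Seed points (three per side) define the nearly sagittal section planes;
    trim limits stand in for the manual choice of where the trochlea ends.
    """

    def __init__(
        self,
        mesh: _morph.TalusMesh,
        lateral_points: np.ndarray,
        medial_points: np.ndarray,
        *,
        slab_mm: float = 2.0,
        trim_lateral: tuple[float, float] | None = None,
        trim_medial: tuple[float, float] | None = None,
    ) -> None:
        self.mesh = mesh
        self.lateral_points = np.asarray(lateral_points, dtype=float)
        self.medial_points = np.asarray(medial_points, dtype=float)
        self.slab_mm = slab_mm
        self.trim_lateral = trim_lateral
        self.trim_medial = trim_medial

    @classmethod
    def from_file(
        cls, mesh_path: str | Path, lateral_points, medial_points, **kwargs
    ) -> "TrochleaMorphologyModel":
        return cls(read_mesh(mesh_path), lateral_points, medial_points, **kwargs)

    def fit(self) -> "TrochleaMorphologyResults":
        axes = _morph.estimate_axes(
            self.mesh,
            self.lateral_points,
            self.medial_points,
            slab_mm=self.slab_mm,
            trim_lateral=self.trim_lateral,
            trim_medial=self.trim_medial,
        )
        return TrochleaMorphologyResults(model=self, axes=axes)


@dataclass
class TrochleaMorphologyResults:
    """Fitted morphology axes with circle-fit diagnostics."""

    model: TrochleaMorphologyModel
    axes: _morph.MorphAxes

    def table(self) -> pd.DataFrame:
        rows = []
        for key, orient in (
            ("DF", self.axes.df_orientation),
            ("PF", self.axes.pf_orientation),
        ):
            rows.append(
                {
                    "axis": key,
                    "inclination": orient.inclination,
                    "deviation": orient.deviation,
                }
            )
        for name, fit in self.axes.fits.items():
            rows.append(
                {
                    "axis": f"circle_{name}",
                    "center_a_mm": fit.center[0],
                    "center_c_mm": fit.center[1],
                    "radius_mm": fit.radius,
                    "rms_mm": fit.rms,
                    "n_points": fit.n_points,
                }
            )
        return pd.DataFrame(rows)

    def repeatability(
        self, n_repeats: int = 5, jitter_mm: float = 1.0, seed: int = 0
    ) -> pd.DataFrame:
        """Spread of the axis estimate under jittered seed-point selection."""
        m = self.model
        return _morph.jitter_repeatability(
            m.mesh,
            m.lateral_points,
            m.medial_points,
            n_repeats=n_repeats,
            jitter_mm=jitter_mm,
            seed=seed,
            slab_mm=m.slab_mm,
            trim_lateral=m.trim_lateral,
            trim_medial=m.trim_medial,
        )

    def summary(self) -> str:
        a = self.axes
        lines = [
            "Morphology-based ankle axes (trochlea circle fits)",
            "=" * 52,
            f"DF axis (anterior centres) : inclination {a.df_orientation.inclination:7.2f} deg,"
            f" deviation {a.df_orientation.deviation:7.2f} deg",
            f"PF axis (posterior centres): inclination {a.pf_orientation.inclination:7.2f} deg,"
            f" deviation {a.pf_orientation.deviation:7.2f} deg",
            "",
            "circle fits (centre in-plane, mm):",
        ]
        for name, fit in a.fits.items():
            lines.append(
                f"  {name:<9} r = {fit.radius:6.2f}  rms = {fit.rms:8.4f} "
                f"(n = {fit.n_points})"
            )
        return "\n".join(lines)
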