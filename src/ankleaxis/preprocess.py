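"""Raw-trial preprocessing: gap filling, filtering, stance detection,
time normalization to 101 stance samples, gait events and GRF landmarks,
and the per-participant marker-residual quality-control rule.

A raw trial carries per-bone marker trajectories (frames x markers x 3, mm)
sampled at the camera rate and a vertical ground-reaction-force series (N)
sampled at the force-plate rate; both streams share the time origin t = 0
at their first frame. Missing marker samples are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt, find_peaks

from .geometry import MarkerCloud, Pose, fit_rigid_transform

__all__ = [
    "PreprocessError",
    "NoContactError",
    "LandmarksUndefinedError",
    "TrialInvalidError",
    "TrialRaw",
    "TrialNormalized",
    "GRFLandmarks",
    "fill_gaps",
    "lowpass_filter",
    "detect_stance",
    "time_normalize",
    "gait_speed",
    "detect_next_heelstrike",
    "grf_landmarks",
    "residual_qc",
    "reference_clouds",
]

N_STANCE_SAMPLES = 101  # 0..100 % stance


class PreprocessError(ValueError):
    """Invalid preprocessing input."""


class NoContactError(PreprocessError):
    """No supra-threshold ground contact in the GRF series."""


class LandmarksUndefinedError(PreprocessError):
    """GRF series lacks the double-hump structure (two maxima, one minimum)."""


class TrialInvalidError(PreprocessError):
    """Trial cannot be normalized (e.g. unfillable marker gaps in stance)."""


@dataclass
class TrialRaw:
    """Raw marker + GRF streams of one trial.

    markers maps bone name -> (labels, array of shape (frames, n_markers, 3)
    in mm, NaN for gaps). grf_z is the vertical GRF in N.
    """

    markers: dict[str, tuple[tuple[str, ...], np.ndarray]]
    marker_rate_hz: float
    grf_z: np.ndarray
    grf_rate_hz: float
    body_weight_N: float
    participant: str = ""
    trial: str = ""

    def __post_init__(self) -> None:
        if self.marker_rate_hz <= 0 or self.grf_rate_hz <= 0:
            raise PreprocessError("sampling rates must be positive")
        if self.body_weight_N <= 0:
            raise PreprocessError("body weight must be positive")
        self.grf_z = np.asarray(self.grf_z, dtype=float)

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values()))[1].shape[0]

    def marker_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.marker_rate_hz

    def grf_times(self) -> np.ndarray:
        return np.arange(len(self.grf_z)) / self.grf_rate_hz


@dataclass
class TrialNormalized:
    """Stance phase of one trial resampled to 101 instants (0..100 %)."""

    poses_tibia: list[Pose]
    poses_talus: list[Pose]
    grf_bw: np.ndarray  # 101 values, body-weight multiples
    gait_speed: float | None  # m/s
    stance_duration: float  # s
    residual_max: dict[str, float]  # per bone, mm
    participant: str = ""
    trial: str = ""

    def __post_init__(self) -> None:
        if len(self.poses_tibia) != N_STANCE_SAMPLES:
            raise PreprocessError("normalized trial must hold 101 tibia poses")
        if len(self.poses_talus) != N_STANCE_SAMPLES:
            raise PreprocessError("normalized trial must hold 101 talus poses")
        self.grf_bw = np.asarray(self.grf_bw, dtype=float)
        if self.grf_bw.shape != (N_STANCE_SAMPLES,):
            raise PreprocessError("normalized GRF must hold 101 samples")
        if np.any(self.grf_bw < -1e-9):
            raise PreprocessError("normalized GRF must be non-negative")


@dataclass(frozen=True)
class GRFLandmarks:
    """Stacoff-style vertical GRF landmarks in body weights.

    Fz2 = first (weight-acceptance) maximum, Fz3 = mid-stance minimum,
    Fz4 = second (push-off) maximum; locations in % stance.
    """

    fz2: float
    fz3: float
    fz4: float
    fz2_pct: int
    fz3_pct: int
    fz4_pct: int

    @property
    def relative_unloading_pct(self) -> float:
        """Mid-stance unloading relative to the first peak: 100*(Fz2-Fz3)/Fz2."""
        return 100.0 * (self.fz2 - self.fz3) / self.fz2


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True in a boolean mask as (start, stop) slices."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(trajectory: np.ndarray, max_gap_frames: int = 10) -> np.ndarray:
    """Fill NaN gaps up to *max_gap_frames* with shape-preserving cubics.

    Monotone piecewise-cubic (PCHIP) interpolation per coordinate; gaps at
    the sequence boundary or longer than the limit are left missing (a
    warning is issued for boundary gaps).
    """
    traj = np.array(trajectory, dtype=float)
    flat = traj.reshape(traj.shape[0], -1)
    for c in range(flat.shape[1]):
        col = flat[:, c]
        missing = np.isnan(col)
        if not missing.any():
            continue
        valid_idx = np.flatnonzero(~missing)
        if len(valid_idx) < 2:
            warnings.warn("too few valid samples to fill gaps", stacklevel=2)
            continue
        interp = PchipInterpolator(valid_idx, col[valid_idx])
        for start, stop in _nan_runs(missing):
            if start == 0 or stop == len(col):
                warnings.warn("gap at sequence boundary left unfilled", stacklevel=2)
                continue
            if stop - start > max_gap_frames:
                continue
            col[start:stop] = interp(np.arange(start, stop))
        flat[:, c] = col
    return flat.reshape(traj.shape)


def lowpass_filter(
    trajectory: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 10.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass per coordinate."""
    traj = np.asarray(trajectory, dtype=float)
    if np.isnan(traj).any():
        raise PreprocessError("trajectory still contains missing samples")
    if sample_rate_hz <= 2 * cutoff_hz:
        raise PreprocessError("sampling rate must exceed twice the cutoff")
    b, a = butter(order, cutoff_hz, fs=sample_rate_hz)
    flat = traj.reshape(traj.shape[0], -1)
    out = filtfilt(b, a, flat, axis=0)
    return out.reshape(traj.shape)


def detect_stance(grf_z: np.ndarray, threshold_N: float = 10.0) -> tuple[int, int]:
    """First and last frame of the longest episode with GRF >= threshold."""
    grf = np.asarray(grf_z, dtype=float)
    above = grf >= threshold_N
    if not above.any():
        raise NoContactError(f"no GRF samples reach the {threshold_N} N threshold")
    runs = _nan_runs(above)
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    return start, stop - 1


def reference_clouds(
    standing: TrialRaw,
) -> dict[str, MarkerCloud]:
    """Per-bone reference clouds: mean marker positions over a standing trial.

    Bones carrying fewer than three markers (event markers such as the
    calcaneal pair) are skipped; they cannot define a pose.
    """
    ref = {}
    for bone, (labels, arr) in standing.markers.items():
        if arr.shape[1] < 3:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_pos = np.nanmean(arr, axis=0)
        if np.isnan(mean_pos).any():
            raise TrialInvalidError(f"standing trial has all-gap markers for {bone}")
        ref[bone] = MarkerCloud(labels, mean_pos)
    return ref


def _resample_linear(
    times: np.ndarray, values: np.ndarray, new_times: np.ndarray
) -> np.ndarray:
    """Linear resampling of a (frames, ...) array onto new time stamps."""
    flat = values.reshape(values.shape[0], -1)
    out = np.empty((len(new_times), flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(new_times, times, flat[:, c])
    return out.reshape((len(new_times),) + values.shape[1:])


def time_normalize(
    trial: TrialRaw,
    stance: tuple[int, int],
    reference: dict[str, MarkerCloud],
    gait_speed_mps: float | None = None,
    pose_bones: tuple[str, ...] = ("tibia", "talus"),
) -> TrialNormalized:
    """Resample the stance phase to 101 instants and fit per-instant poses.

    Marker trajectories are interpolated (linearly) onto 101 equally spaced
    instants spanning the detected stance, the GRF is interpolated onto the
    same instants and scaled by body weight, and per-instant bone poses are
    fitted against the standing reference with the SVD rigid-transform
    solver. The largest per-bone fit residual over stance is recorded for
    the QC rule.
    """
    start, end = stance
    t0 = start / trial.grf_rate_hz
    t1 = end / trial.grf_rate_hz
    if not 0 <= start < end:
        raise PreprocessError("invalid stance indices")
    instants = np.linspace(t0, t1, N_STANCE_SAMPLES)

    grf_norm = _resample_linear(trial.grf_times(), trial.grf_z, instants)
    grf_bw = np.clip(grf_norm / trial.body_weight_N, 0.0, None)

    poses: dict[str, list[Pose]] = {}
    residual_max: dict[str, float] = {}
    mtimes = trial.marker_times()
    for bone in pose_bones:
        labels, arr = trial.markers[bone]
        stance_mask = (mtimes >= t0 - 2.0 / trial.marker_rate_hz) & (
            mtimes <= t1 + 2.0 / trial.marker_rate_hz
        )
        if np.isnan(arr[stance_mask]).any():
            raise TrialInvalidError(
                f"unfillable marker gaps inside stance for bone {bone!r}"
            )
        resampled = _resample_linear(mtimes, arr, instants)
        ref = reference[bone]
        bone_poses = []
        worst = 0.0
        for k in range(N_STANCE_SAMPLES):
            pose, rms = fit_rigid_transform(ref, MarkerCloud(ref.labels, resampled[k]))
            bone_poses.append(pose)
            worst = max(worst, rms)
        poses[bone] = bone_poses
        residual_max[bone] = worst

    return TrialNormalized(
        poses_tibia=poses["tibia"],
        poses_talus=poses["talus"],
        grf_bw=grf_bw,
        gait_speed=gait_speed_mps,
        stance_duration=t1 - t0,
        residual_max=residual_max,
        participant=trial.participant,
        trial=trial.trial,
    )


def gait_speed(
    calcaneal_markers: np.ndarray,
    heelstrike_1: int,
    heelstrike_2: int,
    dt: float,
) -> float:
    """Mean calcaneal-marker displacement between heel strikes over time (m/s).

    *calcaneal_markers* is (frames, n_markers, 3) in mm; *dt* is the frame
    interval in seconds.
    """
    arr = np.asarray(calcaneal_markers, dtype=float)
    p1 = arr[heelstrike_1]
    p2 = arr[heelstrike_2]
    if np.isnan(p1).any() or np.isnan(p2).any():
        raise PreprocessError("calcaneal marker missing at a heel-strike instant")
    dist_mm = np.linalg.norm(p2 - p1, axis=1).mean()
    elapsed = (heelstrike_2 - heelstrike_1) * dt
    if elapsed <= 0:
        raise PreprocessError("heel strikes must be ordered in time")
    return float(dist_mm / 1000.0 / elapsed)


def detect_next_heelstrike(
    foot_markers: np.ndarray,
    search_start: int = 0,
) -> int:
    """Kinematic foot-contact event: most negative local minimum of the
    vertical velocity of the foot-marker centroid at or after *search_start*.
    """
    arr = np.asarray(foot_markers, dtype=float)
    centroid_z = np.nanmean(arr[:, :, 2], axis=1)
    if np.isnan(centroid_z).any():
        raise PreprocessError("foot markers contain gaps in the search range")
    vz = np.gradient(centroid_z)
    # local minima of vertical velocity
    peaks, _ = find_peaks(-vz)
    peaks = peaks[(peaks >= search_start) & (vz[peaks] < 0)]
    if len(peaks) == 0:
        raise PreprocessError("no qualifying vertical-velocity minimum found")
    return int(peaks[np.argmin(vz[peaks])])


def grf_landmarks(grf_bw: np.ndarray) -> GRFLandmarks:
    """Extract Fz2 (first max), Fz3 (mid-stance min) and Fz4 (second max).

    Requires the double-hump walking GRF shape: two interior local maxima
    separated by an interior local minimum, all in body weights on the
    101-sample normalized series.
    """
    grf = np.asarray(grf_bw, dtype=float)
    maxima, _ = find_peaks(grf)
    if len(maxima) < 2:
        raise LandmarksUndefinedError("GRF lacks two local maxima")
    i2, i4 = int(maxima[0]), int(maxima[-1])
    between = grf[i2 : i4 + 1]
    i3 = i2 + int(np.argmin(between))
    if i3 in (i2, i4):
        raise LandmarksUndefinedError("no interior minimum between GRF maxima")
    return GRFLandmarks(
        fz2=float(grf[i2]),
        fz3=float(grf[i3]),
        fz4=float(grf[i4]),
        fz2_pct=i2,
        fz3_pct=i3,
        fz4_pct=i4,
    )


def residual_qc(
    trials: list[TrialNormalized],
    bones: tuple[str, ...] = ("tibia", "talus"),
) -> tuple[list[TrialNormalized], list[TrialNormalized]]:
    """Exclude trials with outlying marker-fit residuals.

    For each trial and each bone, the trial's maximum fit residual is
    compared against Q3 + 1.5*IQR of the corresponding maxima of the
    participant's OTHER trials (linear-interpolation quantiles). A trial is
    excluded when strictly greater for either bone. With fewer than two
    trials the rule is skipped with a warning.
    """
    if len(trials) < 2:
        warnings.warn("fewer than 2 trials: residual QC skipped", stacklevel=2)
        return list(trials), []
    included, excluded = [], []
    for i, trial in enumerate(trials):
        bad = False
        for bone in bones:
            others = np.array(
                [t.residual_max[bone] for j, t in enumerate(trials) if j != i]
            )
            q1, q3 = np.percentile(others, [25, 75])
            fence = q3 + 1.5 * (q3 - q1)
            if trial.residual_max[bone] > fence:
                bad = True
                break
        (excluded if bad else included).append(trial)
    return included, excluded
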