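"""Moving-window finite-helical-axis analysis of the normalized stance phase.

The joint pose at each stance instant is the talus pose expressed in the
tibia frame (both technical frames coincide with the lab frame in relaxed
standing, so the standing configuration is the identity). A finite helical
axis (FHA) is computed between joint poses 10 % of stance apart and assigned
to the window midpoint; only windows with more than 2 degrees of rotation
are considered reliable enough to report an orientation.

Dorsiflexion is summarised over the 15-25 % stance window midpoints and
plantarflexion over 85-95 % (closed intervals, at most 11 windows per trial
at the default 1 % step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    AxisOrientation,
    GeometryError,
    PlanarAngles,
    Pose,
    axis_orientation,
    canonicalize_axis,
    helical_parameters,
    planar_components,
    relative_pose,
)
from .preprocess import N_STANCE_SAMPLES, TrialNormalized

__all__ = [
    "DF_PERIOD",
    "PF_PERIOD",
    "WindowFHA",
    "PeriodSummary",
    "FlexionPair",
    "joint_poses",
    "moving_window_fha",
    "trial_period_mean",
    "summarize_period",
    "rom_summary",
    "flexion_pair_fha",
    "windows_to_frame",
]

DF_PERIOD = (15, 25)  # % stance, closed interval on window midpoints
PF_PERIOD = (85, 95)

PERIOD_QUANTITIES = ("pf", "inv", "add", "d_mm", "theta", "inclination", "deviation")


@dataclass(frozen=True)
class WindowFHA:
    """FHA of one moving window, assigned to the window midpoint (% stance)."""

    mid_percent: int
    valid: bool
    theta: float
    d_mm: float
    axis: np.ndarray | None  # canonicalized unit vector, None if invalid
    orientation: AxisOrientation | None
    planar_increment: PlanarAngles


@dataclass
class PeriodSummary:
    """Pooled window statistics over one flexion period across trials."""

    period: tuple[int, int]
    n_valid: int
    stats: pd.DataFrame  # rows = quantities, cols = grand_mean/min/p5/p95/max
    trial_means: pd.DataFrame  # per-trial mean orientation (boxplot input)
    windows: pd.DataFrame  # all valid windows in period (swarm input)


@dataclass(frozen=True)
class FlexionPair:
    """One quasi-static-style 0 <-> 5 degree flexion comparison."""

    direction: str  # "DF" or "PF"
    anchor: str  # "start-at-0" or "end-at-0"
    percent_a: int
    percent_b: int
    inclination: float
    deviation: float
    theta: float


def joint_poses(trial: TrialNormalized) -> list[Pose]:
    """Talus pose relative to the tibia at each stance instant."""
    return [
        tib.inverse().compose(tal)
        for tib, tal in zip(trial.poses_tibia, trial.poses_talus)
    ]


def moving_window_fha(
    trial: TrialNormalized,
    window_pct: int = 10,
    step_pct: int = 1,
    gate_deg: float = 2.0,
    min_theta_deg: float = 0.1,
) -> list[WindowFHA]:
    """FHAs between joint poses *window_pct* apart, stepped by *step_pct*.

    Each window's relative transform is decomposed into its screw parameters
    and planar increments; the window is valid when its rotation exceeds
    *gate_deg*. Midpoints run from window_pct/2 to 100 - window_pct/2.
    """
    if not 0 < window_pct < N_STANCE_SAMPLES:
        raise ValueError("window_pct must be in (0, 100]")
    J = joint_poses(trial)
    windows: list[WindowFHA] = []
    for s in range(0, N_STANCE_SAMPLES - window_pct, step_pct):
        rel = relative_pose(J[s], J[s + window_pct])
        hel = helical_parameters(rel, min_theta_deg=min_theta_deg)
        planar = planar_components(rel)
        valid = hel.defined and hel.theta > gate_deg
        axis = orient = None
        if valid:
            axis = canonicalize_axis(hel.u)
            orient = axis_orientation(axis)
        windows.append(
            WindowFHA(
                mid_percent=s + window_pct // 2,
                valid=valid,
                theta=hel.theta,
                d_mm=hel.d if hel.defined else 0.0,
                axis=axis,
                orientation=orient,
                planar_increment=planar,
            )
        )
    return windows


def _period_windows(
    windows: list[WindowFHA], period: tuple[int, int]
) -> list[WindowFHA]:
    lo, hi = period
    return [w for w in windows if w.valid and lo <= w.mid_percent <= hi]


def trial_period_mean(
    windows: list[WindowFHA], period: tuple[int, int]
) -> AxisOrientation:
    """Mean axis orientation of one trial's valid windows in a period.

    The mean is the normalized vector sum of the canonicalized window axes
    (avoids angle wrap-around), reported as inclination/deviation.
    """
    sel = _period_windows(windows, period)
    if not sel:
        raise GeometryError(f"no valid windows with midpoint in {period}")
    vec = np.sum([w.axis for w in sel], axis=0)
    norm = np.linalg.norm(vec)
    if norm < 1e-6:
        raise GeometryError("degenerate mean: window axes cancel out")
    return axis_orientation(vec / norm)


def windows_to_frame(
    windows: list[WindowFHA], trial_id: str = ""
) -> pd.DataFrame:
    """Tidy per-window table (one row per window, valid or not)."""
    rows = []
    for w in windows:
        rows.append(
            {
                "trial": trial_id,
                "mid_percent": w.mid_percent,
                "valid": w.valid,
                "theta": w.theta,
                "d_mm": w.d_mm,
                "pf": w.planar_increment.pf,
                "inv": w.planar_increment.inv,
                "add": w.planar_increment.add,
                "inclination": w.orientation.inclination if w.valid else np.nan,
                "deviation": w.orientation.deviation if w.valid else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_period(
    trial_windows: dict[str, list[WindowFHA]],
    period: tuple[int, int],
) -> PeriodSummary:
    """Pool valid windows of all trials within a period.

    Reports the grand mean and min / 5th / 95th / max percentiles (linear
    interpolation) of the per-window planar increments, axis translation,
    rotation and orientation angles, plus per-trial mean orientations.
    """
    pooled = []
    trial_rows = []
    for trial_id, windows in trial_windows.items():
        sel = _period_windows(windows, period)
        if not sel:
            continue
        df = windows_to_frame(sel, trial_id)
        pooled.append(df)
        mean = trial_period_mean(windows, period)
        trial_rows.append(
            {
                "trial": trial_id,
                "n_valid": len(sel),
                "inclination": mean.inclination,
                "deviation": mean.deviation,
            }
        )
    if not pooled:
        raise GeometryError(f"no trial has valid windows in period {period}")
    pool = pd.concat(pooled, ignore_index=True)
    stats = {}
    for q in PERIOD_QUANTITIES:
        vals = pool[q].to_numpy()
        stats[q] = {
            "grand_mean": float(np.mean(vals)),
            "min": float(np.min(vals)),
            "p5": float(np.percentile(vals, 5)),
            "p95": float(np.percentile(vals, 95)),
            "max": float(np.max(vals)),
        }
    return PeriodSummary(
        period=period,
        n_valid=len(pool),
        stats=pd.DataFrame(stats).T,
        trial_means=pd.DataFrame(trial_rows),
        windows=pool,
    )


def rom_summary(
    trial: TrialNormalized,
) -> tuple[float, float, float, pd.DataFrame]:
    """Planar joint-angle series over stance and per-plane ranges of motion.

    Angles are attitude-vector components of the joint pose relative to
    relaxed standing (0 degrees); ROM = max - min per plane over 0-100 %.
    Returns (sagittal_rom, frontal_rom, transverse_rom, series) where the
    series has columns percent, pf, inv, add.
    """
    J = joint_poses(trial)
    planar = np.array([planar_components(p).as_array() for p in J])
    series = pd.DataFrame(
        {
            "percent": np.arange(N_STANCE_SAMPLES),
            "pf": planar[:, 0],
            "inv": planar[:, 1],
            "add": planar[:, 2],
        }
    )
    roms = planar.max(axis=0) - planar.min(axis=0)
    return float(roms[0]), float(roms[1]), float(roms[2]), series


def _nearest_crossings(
    series: np.ndarray, level: float, interval: tuple[int, int]
) -> list[int]:
    """Nearest-sample indices where *series* crosses *level* inside interval."""
    lo, hi = interval
    out = []
    resid = series - level
    for i in range(lo, hi):
        a, b = resid[i], resid[i + 1]
        if a == 0.0:
            out.append(i)
        elif a * b < 0.0:
            # crossing between i and i+1: pick the nearer sample (in interval)
            frac = abs(a) / (abs(a) + abs(b))
            out.append(i if frac < 0.5 else min(i + 1, hi))
    if abs(resid[hi]) == 0.0:
        out.append(hi)
    return sorted(set(out))


def flexion_pair_fha(
    trial: TrialNormalized,
    magnitude_deg: float = 5.0,
    max_separation_pct: int = 20,
    intervals: tuple[tuple[int, int], ...] = ((10, 30), (80, 100)),
    min_theta_deg: float = 0.1,
) -> list[FlexionPair]:
    """FHAs between 0 degree and +-*magnitude_deg* ankle flexion.

    Stance percents where the sagittal angle crosses 0 and +-magnitude are
    located at the nearest normalized sample; ordered pairs are formed when
    both percents fall inside one allowed interval and are at most
    *max_separation_pct* apart. DF pairs use -magnitude (dorsiflexion),
    PF pairs +magnitude. The anchor records whether the movement starts or
    ends at the 0 degree (relaxed standing) configuration.
    """
    J = joint_poses(trial)
    _, _, _, series = rom_summary(trial)
    pf = series["pf"].to_numpy()
    pairs: list[FlexionPair] = []
    for direction, level in (("DF", -magnitude_deg), ("PF", magnitude_deg)):
        for interval in intervals:
            zeros = _nearest_crossings(pf, 0.0, interval)
            flexed = _nearest_crossings(pf, level, interval)
            for s0 in zeros:
                for sm in flexed:
                    if s0 == sm or abs(s0 - sm) > max_separation_pct:
                        continue
                    a, b = (s0, sm) if s0 < sm else (sm, s0)
                    rel = relative_pose(J[a], J[b])
                    hel = helical_parameters(rel, min_theta_deg=min_theta_deg)
                    if not hel.defined:
                        continue
                    orient = axis_orientation(canonicalize_axis(hel.u))
                    pairs.append(
                        FlexionPair(
                            direction=direction,
                            anchor="start-at-0" if s0 < sm else "end-at-0",
                            percent_a=a,
                            percent_b=b,
                            inclination=orient.inclination,
                            deviation=orient.deviation,
                            theta=hel.theta,
                        )
                    )
    return pairs
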