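"""Synthetic walking trials and trochlea meshes with known ground truth.

The walking generator emulates the structure of a bone-pin gait acquisition:
rigid tibia/talus marker triads moving under a prescribed, possibly
time-varying ankle screw axis; calcaneal markers for gait-speed and
heel-strike detection; and a double-hump vertical ground reaction force
with a mid-stance minimum. The trochlea generator lofts a surface between a
single-arc lateral profile and a two-arc medial profile, the classic
morphological model of the talar dome, and returns the exact axis that the
morphology pipeline should recover.

Default parameter values are chosen to be representative of barefoot
walking of healthy adults: gait speed 1.45 m/s, stance duration 0.64 s,
GRF peaks 1.24 / 0.68 / 1.15 body weights, sagittal ankle excursion from
-7 deg (dorsiflexion) to +8 deg (plantarflexion) and smaller frontal /
transverse excursions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .geometry import (
    ANTERIOR,
    MEDIAL,
    VERTICAL,
    AxisOrientation,
    _axis_from_rotation,
    axis_orientation,
)
from .morphology import TalusMesh
from .preprocess import TrialRaw

__all__ = [
    "ConfigError",
    "WalkConfig",
    "WalkGroundTruth",
    "gen_walking_trial",
    "TrochleaConfig",
    "TrochleaGroundTruth",
    "gen_trochlea_mesh",
]


class ConfigError(ValueError):
    """Infeasible generator configuration."""


def _triad(edge_mm: float, center: np.ndarray) -> np.ndarray:
    """Equilateral marker triad of the given edge length around *center*."""
    h = edge_mm / np.sqrt(3.0)
    local = np.array(
        [
            [h, 0.0, 0.0],
            [-h / 2.0, h * np.sqrt(3.0) / 2.0, 0.0],
            [-h / 2.0, -h * np.sqrt(3.0) / 2.0, 0.0],
        ]
    )
    # tilt the triad plane so markers are non-coplanar with the bone axes
    tilt = np.radians(30.0)
    Rx = np.array(
        [
            [1, 0, 0],
            [0, np.cos(tilt), -np.sin(tilt)],
            [0, np.sin(tilt), np.cos(tilt)],
        ]
    )
    return local @ Rx.T + np.asarray(center, dtype=float)


@dataclass
class WalkConfig:
    """Ground-truth parameters of one synthetic walking trial.

    Flexion keyframes map stance percent to sagittal joint angle (deg,
    plantarflexion positive); the axis schedule maps stance percent to the
    (inclination, deviation) of the instantaneous rotation axis. Secondary
    amplitudes add frontal/transverse excursion on top of the cross-talk
    already implied by the scheduled axis.
    """

    seed: int = 0
    stance_duration_s: float = 0.64
    marker_rate_hz: float = 240.0
    grf_rate_hz: float = 960.0
    body_weight_N: float = 735.8  # 75 kg
    gait_speed_mps: float = 1.45
    stride_time_s: float = 1.1
    flexion_keyframes: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (5.0, 2.0),
        (35.0, -7.0),
        (75.0, -6.0),
        (97.0, 8.0),
        (100.0, 8.0),
    )
    # (percent, inclination deg, deviation deg) of the instantaneous axis
    axis_schedule: tuple[tuple[float, float, float], ...] = (
        (0.0, -10.0, 80.0),
        (20.0, -10.0, 80.0),
        (90.0, 12.0, 85.0),
        (100.0, 12.0, 85.0),
    )
    inv_rom_deg: float = 0.0
    add_rom_deg: float = 0.0
    triad_edge_mm: float = 50.0
    marker_noise_mm: float = 0.0
    grf_peaks_bw: tuple[float, float, float] = (1.24, 0.68, 1.15)
    grf_peak_pcts: tuple[float, float, float] = (25.0, 50.0, 75.0)
    pre_roll_s: float = 0.25
    standing_duration_s: float = 0.5

    def __post_init__(self) -> None:
        if self.marker_rate_hz <= 0 or self.grf_rate_hz <= 0:
            raise ConfigError("sampling rates must be positive")
        if self.marker_noise_mm < 0:
            raise ConfigError("marker noise sigma must be >= 0")
        pcts = [p for p, _ in self.flexion_keyframes]
        if not all(b > a for a, b in zip(pcts, pcts[1:])):
            raise ConfigError("flexion keyframe percents must strictly increase")
        if pcts[0] < 0 or pcts[-1] > 100:
            raise ConfigError("flexion keyframe percents must lie in [0, 100]")
        s_pcts = [p for p, _, _ in self.axis_schedule]
        if not all(b > a for a, b in zip(s_pcts, s_pcts[1:])):
            raise ConfigError("axis schedule percents must strictly increase")
        if self.stride_time_s <= self.stance_duration_s:
            raise ConfigError("stride time must exceed stance duration")


@dataclass
class WalkGroundTruth:
    """Exact quantities of the generated trial, by construction."""

    axis_inclination: np.ndarray  # scheduled inclination at midpoints 5..95
    axis_deviation: np.ndarray
    midpoints: np.ndarray
    planar_pf: np.ndarray  # exact joint angles at 0..100 % stance
    planar_inv: np.ndarray
    planar_add: np.ndarray
    grf_landmarks_bw: tuple[float, float, float]
    grf_landmark_pcts: tuple[float, float, float]
    gait_speed_mps: float
    stance_start_s: float
    stance_end_s: float
    heelstrike2_frame: int


def _axis_from_orientation(incl_deg: float, dev_deg: float) -> np.ndarray:
    """Unit axis with the given inclination/deviation (canonical hemisphere)."""
    i, v = np.radians(incl_deg), np.radians(dev_deg)
    u = np.zeros(3)
    u[ANTERIOR] = np.cos(i) * np.cos(v)
    u[MEDIAL] = np.cos(i) * np.sin(v)
    u[VERTICAL] = np.sin(i)
    return u


def _rotvec_to_matrix(omega_deg: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector given in degrees."""
    w = np.radians(np.asarray(omega_deg, dtype=float))
    th = np.linalg.norm(w)
    if th < 1e-15:
        return np.eye(3)
    u = w / th
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _secondary_profiles(cfg: WalkConfig, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smooth inversion/adduction excursions added on top of the axis schedule."""
    inv = cfg.inv_rom_deg * np.sin(np.pi * p / 100.0)
    add = 0.5 * cfg.add_rom_deg * np.sin(2.0 * np.pi * p / 100.0)
    return inv, add


def _integrate_rotations(cfg: WalkConfig, percents: np.ndarray) -> list[np.ndarray]:
    """Joint rotation matrices at the given (sorted, in [0, 100]) percents.

    The rotation is built incrementally: each step rotates about the
    scheduled axis at the step midpoint by the amount that brings the
    sagittal attitude component onto the flexion keyframe spline (so the
    planar flexion angle tracks the keyframes exactly, without compounding
    composition error), plus the secondary inversion/adduction increments.
    Because every increment is taken exactly about the scheduled axis, the
    screw axis of any short window of the motion matches the schedule at
    the window midpoint (exactly so for a constant axis).
    """
    kf_p = np.array([q for q, _ in cfg.flexion_keyframes])
    kf_f = np.array([f for _, f in cfg.flexion_keyframes])
    flex = PchipInterpolator(kf_p, kf_f)
    s_p = np.array([q for q, _, _ in cfg.axis_schedule])
    s_i = np.array([i for _, i, _ in cfg.axis_schedule])
    s_d = np.array([d for _, _, d in cfg.axis_schedule])

    def axis_at(p: float) -> np.ndarray:
        u = _axis_from_orientation(
            float(np.interp(p, s_p, s_i)), float(np.interp(p, s_p, s_d))
        )
        if abs(u[MEDIAL]) < 0.2:
            raise ConfigError("scheduled axis too far from medio-lateral for flexion")
        return u

    inv_prof, add_prof = _secondary_profiles(cfg, np.asarray(percents, dtype=float))

    R = np.eye(3)
    out: list[np.ndarray] = []
    p_prev = 0.0
    inv_prev = add_prev = 0.0
    for k, p in enumerate(np.asarray(percents, dtype=float)):
        if p > p_prev:
            u = axis_at(0.5 * (p_prev + p))
            u_cur, th_cur = _axis_from_rotation(R)
            pf_cur = np.degrees(th_cur) * u_cur[MEDIAL]
            dtheta = (float(flex(np.clip(p, kf_p[0], kf_p[-1]))) - pf_cur) / u[MEDIAL]
            w = dtheta * u
            w[ANTERIOR] += inv_prof[k] - inv_prev
            w[VERTICAL] += add_prof[k] - add_prev
            R = _rotvec_to_matrix(w) @ R
        out.append(R)
        p_prev = p
        inv_prev, add_prev = inv_prof[k], add_prof[k]
    return out


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _grf_curve(cfg: WalkConfig, percent: np.ndarray) -> np.ndarray:
    """Double-hump GRF (body weights) through the landmark points."""
    fz2, fz3, fz4 = cfg.grf_peaks_bw
    p2, p3, p4 = cfg.grf_peak_pcts
    if not 2.0 < p2 < p3 < p4 < 98.0:
        raise ConfigError("GRF landmark percents must satisfy 2 < p2 < p3 < p4 < 98")
    if not (fz2 > fz3 and fz4 > fz3 and fz3 > 0):
        raise ConfigError("GRF peaks must bracket a positive mid-stance minimum")
    # Small nonzero boundary value: the whole stance is supra-threshold so
    # contact detection recovers the configured interval to one sample.
    knots_p = np.array([0.0, 2.0, p2, p3, p4, 98.0, 100.0])
    knots_f = np.array([0.02, 0.35, fz2, fz3, fz4, 0.35, 0.02])
    curve = PchipInterpolator(knots_p, knots_f)(np.clip(percent, 0.0, 100.0))
    curve[(percent < 0.0) | (percent > 100.0)] = 0.0
    return np.clip(curve, 0.0, None)


def gen_walking_trial(
    config: WalkConfig,
) -> tuple[TrialRaw, TrialRaw, WalkGroundTruth]:
    """Generate one walking trial, a standing reference trial and its truth.

    Deterministic given ``config.seed``. The talus rotates relative to the
    tibia so that the sagittal joint angle tracks the flexion keyframes
    exactly and the instantaneous rotation axis follows the axis schedule;
    the tibia translates forward at gait speed; marker triads are rigidly
    attached and perturbed with i.i.d. Gaussian noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    t0 = cfg.pre_roll_s
    t1 = t0 + cfg.stance_duration_s
    t_hs2 = t0 + cfg.stride_time_s
    t_end = t_hs2 + 0.25

    n_frames = int(np.ceil(t_end * cfg.marker_rate_hz)) + 1
    times = np.arange(n_frames) / cfg.marker_rate_hz
    percent = (times - t0) / cfg.stance_duration_s * 100.0

    # Joint rotation: integrated on the union of the (clipped) marker-frame
    # percents and the integer percent grid, then mapped back to frames.
    # Frames outside stance hold the boundary configurations.
    clipped = np.clip(percent, 0.0, 100.0)
    grid = np.unique(np.concatenate([[0.0], clipped, np.arange(101.0)]))
    R_grid = _integrate_rotations(cfg, grid)
    lookup = {p: R for p, R in zip(grid, R_grid)}
    rotations = np.array([lookup[p] for p in clipped])
    R_int = [lookup[p] for p in np.arange(101.0)]

    tib_base = _triad(cfg.triad_edge_mm, center=np.array([0.0, 0.0, 400.0]))
    tal_base = _triad(cfg.triad_edge_mm, center=np.array([20.0, 0.0, 80.0]))
    cal_base = np.array([[-60.0, -10.0, 30.0], [-60.0, 10.0, 30.0]])

    speed_mm = cfg.gait_speed_mps * 1000.0
    shift = np.zeros((n_frames, 3))
    shift[:, ANTERIOR] = speed_mm * times

    tib = tib_base[None, :, :] + shift[:, None, :]
    tal = np.einsum("fij,mj->fmi", rotations, tal_base) + shift[:, None, :]

    # Calcaneus: planted through stance, advances one stride during swing,
    # landing (vertical-velocity minimum) at t_hs2.
    stride_mm = speed_mm * cfg.stride_time_s
    s = (times - t1) / (t_hs2 - t1)
    cal_dx = stride_mm * _smoothstep(s)
    cal_dz = 60.0 * np.sin(np.pi * np.clip(s, 0.0, 1.0))
    cal = np.repeat(cal_base[None, :, :], n_frames, axis=0)
    cal[:, :, ANTERIOR] += cal_dx[:, None]
    cal[:, :, VERTICAL] += cal_dz[:, None]

    n_grf = int(np.ceil(t_end * cfg.grf_rate_hz)) + 1
    grf_t = np.arange(n_grf) / cfg.grf_rate_hz
    grf_pct = (grf_t - t0) / cfg.stance_duration_s * 100.0
    grf = cfg.body_weight_N * _grf_curve(cfg, grf_pct)

    def noisy(arr: np.ndarray) -> np.ndarray:
        if cfg.marker_noise_mm == 0.0:
            return arr
        return arr + rng.normal(0.0, cfg.marker_noise_mm, size=arr.shape)

    labels3 = ("m1", "m2", "m3")
    trial = TrialRaw(
        markers={
            "tibia": (labels3, noisy(tib)),
            "talus": (labels3, noisy(tal)),
            "calcaneus": (("c1", "c2"), noisy(cal)),
        },
        marker_rate_hz=cfg.marker_rate_hz,
        grf_z=grf,
        grf_rate_hz=cfg.grf_rate_hz,
        body_weight_N=cfg.body_weight_N,
        participant="synthetic",
        trial=f"seed{cfg.seed}",
    )

    n_stand = int(np.ceil(cfg.standing_duration_s * cfg.marker_rate_hz)) + 1
    standing = TrialRaw(
        markers={
            "tibia": (labels3, noisy(np.repeat(tib_base[None], n_stand, axis=0))),
            "talus": (labels3, noisy(np.repeat(tal_base[None], n_stand, axis=0))),
            "calcaneus": (
                ("c1", "c2"),
                noisy(np.repeat(cal_base[None], n_stand, axis=0)),
            ),
        },
        marker_rate_hz=cfg.marker_rate_hz,
        grf_z=np.full(
            int(np.ceil(cfg.standing_duration_s * cfg.grf_rate_hz)) + 1,
            cfg.body_weight_N,
        ),
        grf_rate_hz=cfg.grf_rate_hz,
        body_weight_N=cfg.body_weight_N,
        participant="synthetic",
        trial="standing",
    )

    mids = np.arange(5, 96)
    s_p = np.array([q for q, _, _ in cfg.axis_schedule])
    s_i = np.array([i for _, i, _ in cfg.axis_schedule])
    s_d = np.array([d for _, _, d in cfg.axis_schedule])
    omega_grid = []
    for R in R_int:
        u, th = _axis_from_rotation(R)
        omega_grid.append(np.degrees(th) * u)
    omega_grid = np.array(omega_grid)
    truth = WalkGroundTruth(
        axis_inclination=np.interp(mids, s_p, s_i),
        axis_deviation=np.interp(mids, s_p, s_d),
        midpoints=mids,
        planar_pf=omega_grid[:, MEDIAL],
        planar_inv=omega_grid[:, ANTERIOR],
        planar_add=omega_grid[:, VERTICAL],
        grf_landmarks_bw=cfg.grf_peaks_bw,
        grf_landmark_pcts=cfg.grf_peak_pcts,
        gait_speed_mps=cfg.gait_speed_mps,
        stance_start_s=t0,
        stance_end_s=t1,
        heelstrike2_frame=int(round(t_hs2 * cfg.marker_rate_hz)),
    )
    return trial, standing, truth


# ---------------------------------------------------------------------------
# Trochlea mesh generation
# ---------------------------------------------------------------------------


@dataclass
class TrochleaConfig:
    """Two-arc medial / single-arc lateral trochlea surface parameters.

    2D profile coordinates are (anterior, cranial) mm in the sagittal plane;
    the lateral circle is centred at the origin. The medial anterior and
    posterior circle centres are given as offsets from the lateral centre;
    the two medial circles must intersect so their upper intersection forms
    the cranial junction where the profile is split.
    """

    r_lateral: float = 22.0
    r_medial_ant: float = 15.0
    r_medial_post: float = 24.0
    medial_ant_offset: tuple[float, float] = (0.0, 5.0)
    medial_post_offset: tuple[float, float] = (0.0, -4.0)
    width_mm: float = 30.0
    arc_start_deg: float = 25.0  # from the +anterior direction, per centre
    arc_end_deg: float = 155.0
    vertex_spacing_mm: float = 0.6  # CT-segmentation-like sampling density
    jitter_mm: float = 0.0
    seed: int = 0
    blend_margin: float = 0.2  # fraction of width kept as pure profile

    def __post_init__(self) -> None:
        if min(self.r_lateral, self.r_medial_ant, self.r_medial_post) <= 0:
            raise ConfigError("radii must be positive")
        if self.width_mm <= 0:
            raise ConfigError("width must be positive")
        if not 0 < self.arc_start_deg < 90 < self.arc_end_deg < 180:
            raise ConfigError("arc span must straddle the cranial apex (90 deg)")


@dataclass
class TrochleaGroundTruth:
    """Exact axes of the generated trochlea plus pipeline inputs."""

    df_axis: np.ndarray
    pf_axis: np.ndarray
    df_orientation: AxisOrientation
    pf_orientation: AxisOrientation
    centers3d: dict[str, np.ndarray]
    lateral_seed_points: np.ndarray  # 3 points on the lateral face profile
    medial_seed_points: np.ndarray


def _circle_junction(
    c1: np.ndarray, r1: float, c2: np.ndarray, r2: float
) -> np.ndarray:
    """Most cranial common point of two circles (tangency handled)."""
    d = np.linalg.norm(c2 - c1)
    if d < 1e-12:
        raise ConfigError("medial circle centres coincide")
    if d > r1 + r2 + 1e-9 or d < abs(r1 - r2) - 1e-9:
        raise ConfigError("medial arcs do not meet at a cranial junction")
    a = (d**2 + r1**2 - r2**2) / (2.0 * d)
    h2 = r1**2 - a**2
    h = np.sqrt(max(h2, 0.0))
    base = c1 + a * (c2 - c1) / d
    perp = np.array([-(c2 - c1)[1], (c2 - c1)[0]]) / d
    p_up = base + h * perp
    p_dn = base - h * perp
    return p_up if p_up[1] >= p_dn[1] else p_dn


def _arc(center: np.ndarray, radius: float, ang_from: float, ang_to: float, n: int):
    ang = np.linspace(np.radians(ang_from), np.radians(ang_to), n)
    return center + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def gen_trochlea_mesh(
    config: TrochleaConfig,
) -> tuple[TalusMesh, TrochleaGroundTruth]:
    """Loft a trochlea surface between the lateral and medial profiles.

    The lateral profile is one circular arc; the medial profile is two arcs
    joined at their upper intersection (the cranial junction). The surface
    blends between the two profiles across the width, holding each profile
    pure near its face so that sagittal sections near the faces are exactly
    circular. Returns the mesh and the exact morphology axes (the line
    through the anterior centres for dorsiflexion, through the posterior
    centres for plantarflexion).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    c_lat = np.zeros(2)
    c_ma = np.asarray(cfg.medial_ant_offset, dtype=float)
    c_mp = np.asarray(cfg.medial_post_offset, dtype=float)

    junction = _circle_junction(c_ma, cfg.r_medial_ant, c_mp, cfg.r_medial_post)
    ang_j_ant = np.degrees(np.arctan2(*(junction - c_ma)[::-1]))
    ang_j_post = np.degrees(np.arctan2(*(junction - c_mp)[::-1]))
    if not cfg.arc_start_deg < ang_j_ant <= 90.0 + 1e-9:
        raise ConfigError("junction is not the crest of the medial anterior arc")
    if not 90.0 - 1e-9 <= ang_j_post < cfg.arc_end_deg:
        raise ConfigError("junction is not the crest of the medial posterior arc")

    # Dense polylines, then uniform arc-length resampling at the configured
    # vertex spacing. Both profiles share the point count (loft
    # correspondence), so their sampling densities are nearly identical.
    dense = 4000
    med_ant = _arc(c_ma, cfg.r_medial_ant, cfg.arc_start_deg, ang_j_ant, dense // 2)
    med_post = _arc(c_mp, cfg.r_medial_post, ang_j_post, cfg.arc_end_deg, dense // 2)
    medial_dense = np.vstack([med_ant, med_post[1:]])
    lateral_dense = _arc(c_lat, cfg.r_lateral, cfg.arc_start_deg, cfg.arc_end_deg,
                         dense)

    def arclen(poly: np.ndarray) -> np.ndarray:
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def resample(poly: np.ndarray, n: int) -> np.ndarray:
        s = arclen(poly)
        si = np.linspace(0.0, s[-1], n)
        return np.column_stack(
            [np.interp(si, s, poly[:, 0]), np.interp(si, s, poly[:, 1])]
        )

    mean_len = 0.5 * (arclen(medial_dense)[-1] + arclen(lateral_dense)[-1])
    n_prof = max(int(round(mean_len / cfg.vertex_spacing_mm)), 20)
    medial = resample(medial_dense, n_prof)
    lateral = resample(lateral_dense, n_prof)

    w = cfg.width_mm
    n_stations = max(int(round(w / cfg.vertex_spacing_mm)) + 1, 5)
    stations = np.linspace(-w / 2.0, w / 2.0, n_stations)
    frac = stations / w + 0.5  # 0 at lateral face, 1 at medial face
    q = _smoothstep((frac - cfg.blend_margin) / (1.0 - 2.0 * cfg.blend_margin))

    verts = []
    for y, qj in zip(stations, q):
        prof = (1.0 - qj) * lateral + qj * medial
        row = np.column_stack([prof[:, 0], np.full(len(prof), y), prof[:, 1]])
        verts.append(row)
    verts = np.concatenate(verts, axis=0)
    if cfg.jitter_mm > 0:
        verts = verts + rng.normal(0.0, cfg.jitter_mm, size=verts.shape)

    m = len(medial)
    faces = []
    for j in range(n_stations - 1):
        for i in range(m - 1):
            a = j * m + i
            b = a + 1
            c = a + m
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    mesh = TalusMesh(vertices=verts, faces=np.array(faces, dtype=int))

    centers3d = {
        "lat_ant": np.array([c_lat[0], -w / 2.0, c_lat[1]]),
        "lat_post": np.array([c_lat[0], -w / 2.0, c_lat[1]]),
        "med_ant": np.array([c_ma[0], w / 2.0, c_ma[1]]),
        "med_post": np.array([c_mp[0], w / 2.0, c_mp[1]]),
    }

    def axis(part: str) -> np.ndarray:
        vec = centers3d[f"med_{part}"] - centers3d[f"lat_{part}"]
        return vec / np.linalg.norm(vec)

    df_axis, pf_axis = axis("ant"), axis("post")

    def face_points(profile2d: np.ndarray, y: float) -> np.ndarray:
        # near the arc ends plus the crest: a well-conditioned (non-thin)
        # triangle, as an operator would pick for a plane that cuts the
        # profile appropriately
        n = len(profile2d)
        pts = profile2d[[int(0.05 * n), n // 2, int(0.95 * n)]]
        return np.column_stack([pts[:, 0], np.full(3, y), pts[:, 1]])

    truth = TrochleaGroundTruth(
        df_axis=df_axis,
        pf_axis=pf_axis,
        df_orientation=axis_orientation(df_axis),
        pf_orientation=axis_orientation(pf_axis),
        centers3d=centers3d,
        lateral_seed_points=face_points(lateral, -w / 2.0),
        medial_seed_points=face_points(medial, w / 2.0),
    )
    return mesh, truth
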