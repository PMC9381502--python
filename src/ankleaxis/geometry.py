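"""Rigid-body pose estimation and screw-axis (finite helical axis) mathematics.

Frame convention used throughout the package (right foot, right-handed):

* ``x`` — anterior (walking direction),
* ``y`` — medial,
* ``z`` — vertical (up).

With this frame the components of the attitude vector (rotation angle times
unit rotation axis) map directly onto clinically signed planar angles:

* rotation about ``+x`` (anterior)  → inversion positive,
* rotation about ``+y`` (medial)    → plantarflexion positive,
* rotation about ``+z`` (vertical)  → adduction positive.

Left-foot data must be mirrored onto this convention before entering the
pipeline. Angles are degrees at every public surface; radians are internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "DeviationUndefinedError",
    "MarkerCloud",
    "Pose",
    "HelicalAxis",
    "AxisOrientation",
    "PlanarAngles",
    "fit_rigid_transform",
    "relative_pose",
    "helical_parameters",
    "planar_components",
    "canonicalize_axis",
    "axis_orientation",
]

# Index of each anatomical direction in the lab frame.
ANTERIOR, MEDIAL, VERTICAL = 0, 1, 2

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid geometric input."""


class DegenerateGeometryError(GeometryError):
    """Marker set too small, coincident or collinear for pose estimation."""


class DeviationUndefinedError(GeometryError):
    """Axis is (numerically) vertical: its transverse projection vanishes."""


@dataclass(frozen=True)
class MarkerCloud:
    """A labelled set of 3D marker positions (mm), N >= 3 for pose fitting."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError(f"positions must be (N, 3), got {pos.shape}")
        if len(self.labels) != pos.shape[0]:
            raise GeometryError("number of labels must match number of positions")
        if pos.shape[0] < 3:
            raise DegenerateGeometryError("a marker cloud needs at least 3 markers")
        if not np.all(np.isfinite(pos)):
            raise GeometryError("marker positions must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass(frozen=True)
class Pose:
    """Rigid transform ``x -> R x + t`` (rotation matrix + translation, mm)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise GeometryError("R must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("R is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("R is a reflection (det < 0)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.R.T + self.t

    def inverse(self) -> "Pose":
        return Pose(self.R.T, -self.R.T @ self.t)

    def compose(self, other: "Pose") -> "Pose":
        """Return ``self ∘ other`` (apply *other* first)."""
        return Pose(self.R @ other.R, self.R @ other.t + self.t)


@dataclass(frozen=True)
class HelicalAxis:
    """Screw decomposition of a rigid motion.

    ``u`` is the unit axis direction, ``theta`` the (non-negative) rotation
    about it in degrees, ``d`` the signed translation along it in mm and
    ``origin`` the axis point closest to the frame origin. ``defined`` is
    False when theta falls below the caller's resolvable threshold, in which
    case the direction is not meaningful.
    """

    u: np.ndarray | None
    theta: float
    d: float
    origin: np.ndarray | None
    defined: bool


@dataclass(frozen=True)
class AxisOrientation:
    """Orientation of a (canonicalized) axis relative to anatomical planes.

    inclination: signed angle (deg) to the transverse plane; positive means
    the medial end of the axis points upward ("medially upwards").
    deviation: angle (deg, [0, 180]) between the transverse-plane projection
    of the axis and the anterior direction; 90 = purely medio-lateral.
    """

    inclination: float
    deviation: float


@dataclass(frozen=True)
class PlanarAngles:
    """Attitude-vector components on the tibia frame (deg).

    pf: plantarflexion positive (dorsiflexion negative);
    inv: inversion positive; add: adduction positive.
    """

    pf: float
    inv: float
    add: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pf, self.inv, self.add])


def _check_cloud_for_fit(cloud: MarkerCloud) -> None:
    if cloud.n_markers < 3:
        raise DegenerateGeometryError("pose estimation requires >= 3 markers")
    centered = cloud.positions - cloud.centroid()
    # Coincident markers
    from scipy.spatial.distance import pdist

    if np.min(pdist(cloud.positions)) < 1e-9:
        raise DegenerateGeometryError("coincident markers")
    # Collinearity: rank of the centered cloud must be >= 2
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("markers are collinear")


def fit_rigid_transform(
    reference: MarkerCloud, current: MarkerCloud
) -> tuple[Pose, float]:
    """Least-squares rigid transform mapping *reference* onto *current*.

    SVD solution of the orthogonal Procrustes problem on centered marker
    coordinates, with the reflection corrected so that ``det(R) = +1``.
    Returns the pose and the RMS of the per-marker fit residuals (mm).
    """
    if reference.labels != current.labels:
        raise GeometryError(
            f"marker labels differ: {reference.labels} vs {current.labels}"
        )
    _check_cloud_for_fit(reference)
    _check_cloud_for_fit(current)

    p = reference.positions
    q = current.positions
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    H = (p - pc).T @ (q - qc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.linalg.det(Vt.T @ U.T)])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    residuals = q - (p @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return Pose(R, t), rms


def relative_pose(pose_a: Pose, pose_b: Pose) -> Pose:
    """Transform taking the body's configuration at *a* to that at *b*.

    Both poses are relative to the same reference; the result is expressed
    in the reference frame: ``T_rel = T_b ∘ T_a⁻¹``.
    """
    return pose_b.compose(pose_a.inverse())


def _axis_from_rotation(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit rotation axis and angle (rad) via the Spoor–Veldpaus extraction.

    The angle comes from both the antisymmetric (sine) and symmetric
    (cosine) parts via atan2, which is well conditioned on (0, 180). The
    axis direction comes from the antisymmetric part whenever the sine is
    resolvable; only in the immediate vicinity of 180 deg, where it
    vanishes, does the symmetric part take over.
    """
    v = 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_t = np.linalg.norm(v)
    cos_t = 0.5 * (np.trace(R) - 1.0)
    theta = float(np.arctan2(sin_t, cos_t))
    if theta < 1e-12:
        return np.zeros(3), 0.0
    if sin_t > 1e-5:
        u = v / sin_t
    else:
        # Symmetric part: u uᵀ = (S - cos I) / (1 - cos)
        diag = np.clip((np.diag(R) - cos_t) / (1.0 - cos_t), 0.0, None)
        u = np.sqrt(diag)
        # Fix relative signs from the largest component using the symmetric
        # off-diagonals, then the overall sign from the antisymmetric part.
        k = int(np.argmax(u))
        for j in range(3):
            if j != k and u[j] > 0.0:
                s_off = 0.5 * (R[k, j] + R[j, k]) / (1.0 - cos_t)
                if s_off < 0.0:
                    u[j] = -u[j]
        if sin_t > 1e-12 and np.dot(u, v) < 0.0:
            u = -u
        u = u / np.linalg.norm(u)
    return u, theta


def helical_parameters(pose: Pose, min_theta_deg: float = 0.1) -> HelicalAxis:
    """Finite-helical-axis (screw) decomposition of a rigid transform.

    Returns direction ``u``, rotation ``theta`` (deg, in [0, 180]), signed
    translation along the axis ``d = t·u`` (mm) and the axis point closest
    to the frame origin. When theta falls below *min_theta_deg* the motion
    is treated as unresolvable rotation: ``defined=False``.
    """
    u, theta_rad = _axis_from_rotation(pose.R)
    theta = float(np.degrees(theta_rad))
    if theta < min_theta_deg:
        return HelicalAxis(u=None, theta=theta, d=0.0, origin=None, defined=False)
    d = float(np.dot(pose.t, u))
    # Point on the axis: least-norm solution of (I - R) s = t - d u,
    # which is the axis point perpendicular to the frame origin.
    rhs = pose.t - d * u
    s, *_ = np.linalg.lstsq(np.eye(3) - pose.R, rhs, rcond=None)
    return HelicalAxis(u=u, theta=theta, d=d, origin=s, defined=True)


def planar_components(pose: Pose) -> PlanarAngles:
    """Attitude-vector (theta times axis) decomposition on the tibia frame.

    Components are mapped to clinically signed planar angles per the frame
    convention: plantarflexion (+about medial axis), inversion (+about
    anterior axis), adduction (+about vertical axis), all in degrees.
    """
    u, theta_rad = _axis_from_rotation(pose.R)
    attitude = np.degrees(theta_rad) * u
    return PlanarAngles(
        pf=float(attitude[MEDIAL]),
        inv=float(attitude[ANTERIOR]),
        add=float(attitude[VERTICAL]),
    )


def canonicalize_axis(u: np.ndarray) -> np.ndarray:
    """Flip the sign of *u* so its medial component is >= 0.

    Tie-breaks: zero medial component → vertical component > 0; both zero →
    anterior component > 0. FHA directions are sign-ambiguous; orientations
    are only reported for canonicalized axes.
    """
    u = np.asarray(u, dtype=float)
    for idx in (MEDIAL, VERTICAL, ANTERIOR):
        c = u[idx]
        if abs(c) > _ORTHO_TOL:
            return u if c > 0 else -u
    raise GeometryError("zero axis vector cannot be canonicalized")


def axis_orientation(u: np.ndarray) -> AxisOrientation:
    """Inclination and deviation of a unit axis after canonicalization.

    Inclination is the signed angle to the transverse plane (positive =
    medial end up). Deviation is the angle in [0, 180] between the
    transverse-plane projection and the anterior direction (90 = purely
    medio-lateral). Raises :class:`DeviationUndefinedError` for a vertical
    axis.
    """
    u = np.asarray(u, dtype=float)
    norm = np.linalg.norm(u)
    if abs(norm - 1.0) > 1e-6:
        raise GeometryError(f"axis must be a unit vector, |u| = {norm:.6g}")
    u = canonicalize_axis(u / norm)
    inclination = float(np.degrees(np.arcsin(np.clip(u[VERTICAL], -1.0, 1.0))))
    proj = np.hypot(u[ANTERIOR], u[MEDIAL])
    if proj < _ORTHO_TOL:
        raise DeviationUndefinedError("vertical axis: deviation undefined")
    deviation = float(np.degrees(np.arctan2(u[MEDIAL], u[ANTERIOR])))
    return AxisOrientation(inclination=inclination, deviation=deviation)


def screw_pose(
    u: np.ndarray, theta_deg: float, point: np.ndarray | None = None, d: float = 0.0
) -> Pose:
    """Build the rigid transform of a screw motion (test/generator utility).

    Rotation of *theta_deg* about the axis through *point* with direction
    *u*, plus translation *d* along the axis.
    """
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    th = np.radians(theta_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    p = np.zeros(3) if point is None else np.asarray(point, dtype=float)
    t = p - R @ p + d * u
    return Pose(R, t)
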