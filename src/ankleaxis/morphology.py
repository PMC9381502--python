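"""Ankle-axis estimation from talar morphology.

The trochlea tali is sectioned by two nearly sagittal planes (one through
the lateral, one through the medial profile). Mesh vertices within a slab
around each plane are projected onto it, trimmed to the trochlear extent
and reduced to the upper envelope so the section traces the articular dome.
Each profile is split at its most cranial point into an anterior and a
posterior part, and a circle is fitted to each part with Taubin's algebraic
method. The line connecting the two ANTERIOR circle centres estimates the
ankle axis in dorsiflexion, the line connecting the POSTERIOR centres the
axis in plantarflexion.

The mesh is expected in the standing-reference lab frame of
:mod:`ankleaxis.geometry` (x anterior, y medial, z up), in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    ANTERIOR,
    MEDIAL,
    VERTICAL,
    AxisOrientation,
    axis_orientation,
    canonicalize_axis,
)

__all__ = [
    "MorphologyError",
    "CircleFitError",
    "IllConditionedAxisError",
    "TalusMesh",
    "ProfilePlane",
    "ProfileSection",
    "CircleFit",
    "MorphAxes",
    "section_profile",
    "taubin_fit",
    "morphology_axes",
    "estimate_axes",
]


class MorphologyError(ValueError):
    """Invalid morphology input."""


class CircleFitError(MorphologyError):
    """Too few or collinear points for a circle fit."""


class IllConditionedAxisError(MorphologyError):
    """Circle centres too close together to define an axis direction."""


@dataclass(frozen=True)
class TalusMesh:
    """Triangulated talus surface in the standing-reference frame (mm)."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 100:
            raise MorphologyError("mesh needs >= 100 vertices of shape (V, 3)")
        if not np.all(np.isfinite(v)):
            raise MorphologyError("mesh vertices must be finite")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass(frozen=True)
class ProfilePlane:
    """Sectioning plane with an in-plane (anterior-ish, cranial-ish) basis."""

    origin: np.ndarray
    normal: np.ndarray  # unit, within 45 deg of the medio-lateral axis
    e_anterior: np.ndarray  # in-plane, unit, anterior-ish
    e_cranial: np.ndarray  # in-plane, unit, cranial-ish

    def project(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points, dtype=float) - self.origin
        return np.column_stack([rel @ self.e_anterior, rel @ self.e_cranial])

    def lift(self, point2d: np.ndarray) -> np.ndarray:
        a, c = point2d
        return self.origin + a * self.e_anterior + c * self.e_cranial


@dataclass(frozen=True)
class ProfileSection:
    """2D trochlear profile points (anterior, cranial) in one plane."""

    points: np.ndarray  # (M, 2)
    plane: ProfilePlane
    trim: tuple[float, float]


@dataclass(frozen=True)
class CircleFit:
    """Taubin circle fit: 2D centre and radius (mm) with RMS residual."""

    center: np.ndarray  # (2,)
    radius: float
    rms: float
    n_points: int


@dataclass(frozen=True)
class MorphAxes:
    """Morphology-based dorsiflexion and plantarflexion axis estimates."""

    df_axis: np.ndarray  # canonicalized unit vector
    pf_axis: np.ndarray
    df_orientation: AxisOrientation
    pf_orientation: AxisOrientation
    centers3d: dict[str, np.ndarray]  # lat_ant, lat_post, med_ant, med_post
    fits: dict[str, CircleFit]


def _plane_from_points(three_points: np.ndarray) -> ProfilePlane:
    pts = np.asarray(three_points, dtype=float)
    if pts.shape != (3, 3):
        raise MorphologyError("exactly three 3D seed points required")
    n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    norm = np.linalg.norm(n)
    span = max(np.linalg.norm(pts[1] - pts[0]), np.linalg.norm(pts[2] - pts[0]))
    if norm < 1e-9 * max(span**2, 1.0):
        raise MorphologyError("seed points are collinear")
    n = n / norm
    if n[MEDIAL] < 0:
        n = -n
    # nearly sagittal: normal within 45 deg of the medio-lateral direction
    if n[MEDIAL] < np.cos(np.radians(45.0)):
        raise MorphologyError("section plane is not nearly sagittal")
    x_hat = np.zeros(3)
    x_hat[ANTERIOR] = 1.0
    e_a = x_hat - np.dot(x_hat, n) * n
    e_a = e_a / np.linalg.norm(e_a)
    e_c = np.cross(n, e_a)
    if e_c[VERTICAL] < 0:
        e_c = -e_c
    return ProfilePlane(origin=pts.mean(axis=0), normal=n, e_anterior=e_a, e_cranial=e_c)


def section_profile(
    mesh: TalusMesh,
    three_points: np.ndarray,
    slab_mm: float = 2.0,
    trim: tuple[float, float] | None = None,
    envelope_bin_mm: float = 0.5,
) -> ProfileSection:
    """Slice the trochlea with a nearly sagittal plane through 3 seed points.

    Vertices within *slab_mm* of the plane are projected onto it; the 2D
    profile is trimmed to *trim* = (posterior_limit, anterior_limit) along
    the anterior axis (plane-relative mm; standing in for the manual choice
    of where the trochlea ends) and reduced to the upper envelope (most
    cranial point per 0.5 mm anterior bin) so it traces the dome.
    """
    plane = _plane_from_points(three_points)
    dist = (mesh.vertices - plane.origin) @ plane.normal
    mask = np.abs(dist) < slab_mm
    if not mask.any():
        raise MorphologyError(f"no vertices within {slab_mm} mm of the plane")
    pts2d = plane.project(mesh.vertices[mask])
    if trim is not None:
        lo, hi = trim
        keep = (pts2d[:, 0] >= lo) & (pts2d[:, 0] <= hi)
        pts2d = pts2d[keep]
        if len(pts2d) == 0:
            raise MorphologyError("trim limits exclude all section points")
    else:
        lo, hi = float(pts2d[:, 0].min()), float(pts2d[:, 0].max())
    # upper envelope: most cranial point per anterior-coordinate bin
    bins = np.floor((pts2d[:, 0] - lo) / envelope_bin_mm).astype(int)
    envelope = []
    for b in np.unique(bins):
        sub = pts2d[bins == b]
        envelope.append(sub[np.argmax(sub[:, 1])])
    pts2d = np.array(envelope)
    if len(pts2d) < 6:
        raise MorphologyError("too few profile points after envelope extraction")
    return ProfileSection(points=pts2d, plane=plane, trim=(lo, hi))


def taubin_fit(points2d: np.ndarray) -> CircleFit:
    """Taubin's algebraic circle fit (normalized algebraic distance).

    Solves the smallest-singular-vector problem of the gradient-normalized
    algebraic circle equation; near-unbiased for partial arcs. Raises
    :class:`CircleFitError` on fewer than 3 points or collinear input.
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CircleFitError("circle fit requires >= 3 2D points")
    mean = pts.mean(axis=0)
    x = pts[:, 0] - mean[0]
    y = pts[:, 1] - mean[1]
    z = x**2 + y**2
    zm = z.mean()
    if zm < 1e-12:
        raise CircleFitError("points are coincident")
    z0 = (z - zm) / (2.0 * np.sqrt(zm))
    A = np.column_stack([z0, x, y])
    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    a0, b, c = Vt[-1]
    a = a0 / (2.0 * np.sqrt(zm))
    d = -zm * a
    scale = np.hypot(np.max(np.abs(x)), np.max(np.abs(y)))
    if abs(a) < 1e-12 / max(scale, 1.0):
        raise CircleFitError("points are (numerically) collinear")
    center = -np.array([b, c]) / (2.0 * a) + mean
    radius = float(np.sqrt(b**2 + c**2 - 4.0 * a * d) / (2.0 * abs(a)))
    dists = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return CircleFit(center=center, radius=radius, rms=rms, n_points=len(pts))


def _split_at_crest(section: ProfileSection) -> tuple[np.ndarray, np.ndarray]:
    """Split a profile at its most cranial point (included in both parts)."""
    pts = section.points
    k = int(np.argmax(pts[:, 1]))
    a_split = pts[k, 0]
    anterior = pts[pts[:, 0] >= a_split]
    posterior = pts[pts[:, 0] <= a_split]
    if len(anterior) < 3 or len(posterior) < 3:
        raise MorphologyError(
            "profile cannot be split into anterior/posterior parts of >= 3 points"
        )
    return anterior, posterior


def morphology_axes(
    lateral: ProfileSection, medial: ProfileSection, min_center_sep_mm: float = 5.0
) -> MorphAxes:
    """DF and PF axis estimates from medial and lateral trochlea profiles.

    Each profile is split at its most cranial point; Taubin circles are
    fitted to the anterior and posterior parts; the 2D centres are lifted
    back to 3D through their planes. The dorsiflexion axis connects the two
    anterior centres, the plantarflexion axis the two posterior centres.
    """
    fits: dict[str, CircleFit] = {}
    centers: dict[str, np.ndarray] = {}
    for name, section in (("lat", lateral), ("med", medial)):
        ant, post = _split_at_crest(section)
        for part, pts in (("ant", ant), ("post", post)):
            fit = taubin_fit(pts)
            fits[f"{name}_{part}"] = fit
            centers[f"{name}_{part}"] = section.plane.lift(fit.center)

    axes = {}
    orients = {}
    for key, part in (("df", "ant"), ("pf", "post")):
        vec = centers[f"med_{part}"] - centers[f"lat_{part}"]
        if np.linalg.norm(vec) < min_center_sep_mm:
            raise IllConditionedAxisError(
                f"{key} circle centres are closer than {min_center_sep_mm} mm"
            )
        axes[key] = canonicalize_axis(vec / np.linalg.norm(vec))
        orients[key] = axis_orientation(axes[key])

    return MorphAxes(
        df_axis=axes["df"],
        pf_axis=axes["pf"],
        df_orientation=orients["df"],
        pf_orientation=orients["pf"],
        centers3d=centers,
        fits=fits,
    )


def estimate_axes(
    mesh: TalusMesh,
    lateral_points: np.ndarray,
    medial_points: np.ndarray,
    slab_mm: float = 2.0,
    trim_lateral: tuple[float, float] | None = None,
    trim_medial: tuple[float, float] | None = None,
) -> MorphAxes:
    """Full morphology pipeline: section both profiles, fit, connect centres."""
    lat = section_profile(mesh, lateral_points, slab_mm=slab_mm, trim=trim_lateral)
    med = section_profile(mesh, medial_points, slab_mm=slab_mm, trim=trim_medial)
    return morphology_axes(lat, med)


def jitter_repeatability(
    mesh: TalusMesh,
    lateral_points: np.ndarray,
    medial_points: np.ndarray,
    n_repeats: int = 5,
    jitter_mm: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> "pd.DataFrame":
    """Re-run the axis estimation with jittered seed points.

    Emulates repeated manual point selection: each repetition displaces each
    of the six plane seed points by an independent random vector of length
    at most *jitter_mm* and records the recovered DF/PF orientations.
    """
    import pandas as pd

    def ball_jitter(rng: np.random.Generator, shape) -> np.ndarray:
        v = rng.normal(size=shape)
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        radius = jitter_mm * rng.uniform(0.0, 1.0, size=shape[:-1] + (1,)) ** (1 / 3)
        return v * radius

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        jl = lateral_points + ball_jitter(rng, (3, 3))
        jm = medial_points + ball_jitter(rng, (3, 3))
        axes = estimate_axes(mesh, jl, jm, **kwargs)
        rows.append(
            {
                "repeat": rep,
                "df_inclination": axes.df_orientation.inclination,
                "df_deviation": axes.df_orientation.deviation,
                "pf_inclination": axes.pf_orientation.inclination,
                "pf_deviation": axes.pf_orientation.deviation,
            }
        )
    return pd.DataFrame(rows)
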