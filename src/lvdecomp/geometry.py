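"""Planar polygon primitives for short-axis contour analysis.

Short-axis LV contours are closed planar polygons in millimetres. The swept-area
decomposition superimposes the end-diastolic (ED) and end-systolic (ES)
epicardial contours of a slice about a common center, resamples both onto a
shared uniform angular grid, and integrates the signed radial area change
within angular sectors (septal vs lateral, delimited by the RV insertion
points).

Conventions: angles in radians, counter-clockwise, 0 along +x of the slice
plane; polygons are normalized to counter-clockwise orientation on ingest;
angular windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateContourError,
    GridMismatchError,
    InvalidContourError,
    InvalidLandmarkError,
    NotStarShapedError,
)

TWO_PI = 2.0 * np.pi

__all__ = [
    "PlanarContour",
    "AngularWindow",
    "RadialProfile",
    "polygon_area",
    "polygon_centroid",
    "polar_resample",
    "septal_window",
    "swept_sector_area",
]


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class PlanarContour:
    """Closed polygon in a short-axis plane (mm).

    The last vertex implicitly connects to the first. On construction,
    consecutive duplicate vertices (including a repeated closing vertex) are
    dropped and the orientation is normalized to counter-clockwise.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidContourError(
                f"contour points must have shape (n, 2), got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidContourError("contour contains non-finite coordinates")
        # drop consecutive duplicates, treating the polygon cyclically
        keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
        pts = pts[keep]
        if pts.shape[0] < 3:
            raise InvalidContourError(
                f"contour needs >= 3 distinct points, got {pts.shape[0]}"
            )
        if _signed_area(pts) < 0.0:
            pts = pts[::-1]
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def translated(self, dx: float, dy: float) -> "PlanarContour":
        return PlanarContour(self.points + np.array([dx, dy]))

    def scaled(self, k: float, about: tuple[float, float] = (0.0, 0.0)) -> "PlanarContour":
        c = np.asarray(about, dtype=float)
        return PlanarContour(c + k * (self.points - c))


def polygon_area(contour: PlanarContour) -> float:
    """Shoelace area in mm² (strictly positive after orientation normalization)."""
    area = _signed_area(contour.points)
    if area <= 0.0:
        raise DegenerateContourError("contour encloses zero area")
    return area


def polygon_centroid(contour: PlanarContour) -> tuple[float, float]:
    """Area-weighted centroid of the polygon, in mm."""
    pts = contour.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a <= 0.0:
        raise DegenerateContourError("centroid undefined for zero-area contour")
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return (cx, cy)


@dataclass(frozen=True)
class AngularWindow:
    """Half-open angular sector ``[start, end)``, counter-clockwise, radians.

    The septal and lateral windows of a slice partition the full circle:
    ``window.complement()`` is the other sector.
    """

    start: float
    end: float
    label: str = "septal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", float(np.mod(self.start, TWO_PI)))
        object.__setattr__(self, "end", float(np.mod(self.end, TWO_PI)))
        if self.length <= 0.0 or self.length >= TWO_PI:
            raise InvalidLandmarkError(
                f"angular window length must lie in (0, 2*pi), got {self.length}"
            )

    @property
    def length(self) -> float:
        return float(np.mod(self.end - self.start, TWO_PI))

    def contains(self, angles: np.ndarray) -> np.ndarray:
        """Boolean mask of angles inside the half-open window."""
        return np.mod(np.asarray(angles) - self.start, TWO_PI) < self.length

    def complement(self, label: str | None = None) -> "AngularWindow":
        if label is None:
            label = "lateral" if self.label == "septal" else "septal"
        return AngularWindow(self.end, self.start, label)


@dataclass
class RadialProfile:
    """Distances from a fixed center to a star-shaped contour on a uniform
    angular grid in ``[0, 2*pi)``."""

    center: np.ndarray
    angles: np.ndarray
    radii: np.ndarray

    @property
    def n_theta(self) -> int:
        return self.angles.shape[0]

    def to_polygon(self) -> PlanarContour:
        pts = self.center + self.radii[:, None] * np.stack(
            [np.cos(self.angles), np.sin(self.angles)], axis=1
        )
        return PlanarContour(pts)


def polar_resample(
    contour: PlanarContour, center: tuple[float, float], n_theta: int = 720
) -> RadialProfile:
    """Resample a star-shaped contour onto ``n_theta`` uniform angles about
    ``center``.

    The radius at each grid angle is the exact intersection of the ray with the
    polygon boundary (not an interpolation of vertex radii). Star-shapedness is
    verified: the vertex angles about the center must be strictly monotone
    counter-clockwise; otherwise some ray crosses the boundary 0 or >= 2 times.
    """
    c = np.asarray(center, dtype=float)
    pts = contour.points
    v = pts - c
    r_vert = np.hypot(v[:, 0], v[:, 1])
    if np.any(r_vert <= 1e-9):
        raise NotStarShapedError("polar center lies on the contour boundary")
    ang = np.mod(np.arctan2(v[:, 1], v[:, 0]), TWO_PI)
    k0 = int(np.argmin(ang))
    ang_r = np.roll(ang, -k0)
    pts_r = np.roll(pts, -k0, axis=0)
    gaps = np.diff(np.concatenate([ang_r, ang_r[:1] + TWO_PI]))
    if np.any(gaps <= 0.0):
        bad = int(np.argmax(gaps <= 0.0))
        raise NotStarShapedError(
            "contour is not star-shaped about "
            f"({c[0]:.3f}, {c[1]:.3f}): ray near angle {ang_r[bad]:.4f} rad "
            "crosses the boundary more than once"
        )
    ang_ext = np.concatenate([ang_r, [ang_r[0] + TWO_PI]])
    q = np.concatenate([pts_r, pts_r[:1]], axis=0) - c

    theta = np.arange(n_theta) * (TWO_PI / n_theta)
    th = theta.copy()
    th[th < ang_r[0]] += TWO_PI
    idx = np.clip(np.searchsorted(ang_ext, th, side="right") - 1, 0, len(ang_r) - 1)
    q1 = q[idx]
    e = q[idx + 1] - q1
    u = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    denom = u[:, 0] * e[:, 1] - u[:, 1] * e[:, 0]
    num = q1[:, 0] * e[:, 1] - q1[:, 1] * e[:, 0]
    radii = num / denom
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0.0):
        raise NotStarShapedError(
            "ray-boundary intersection failed; contour degenerate about center"
        )
    return RadialProfile(center=c, angles=theta, radii=radii)


def septal_window(
    insertion_anterior: tuple[float, float],
    insertion_inferior: tuple[float, float],
    center: tuple[float, float],
) -> AngularWindow:
    """Angular sector between the RV insertion points that faces the RV side.

    Of the two arcs delimited by the insertion angles, the septum is the one
    containing the direction from the LV center toward the insertion-point
    midpoint (which lies on the RV side). The complementary arc is the lateral
    wall.
    """
    a = np.asarray(insertion_anterior, dtype=float)
    i = np.asarray(insertion_inferior, dtype=float)
    c = np.asarray(center, dtype=float)
    if np.allclose(a, c) or np.allclose(i, c) or np.allclose(a, i):
        raise InvalidLandmarkError("insertion points and center must be distinct")
    ang_a = float(np.mod(np.arctan2(*(a - c)[::-1]), TWO_PI))
    ang_i = float(np.mod(np.arctan2(*(i - c)[::-1]), TWO_PI))
    if np.isclose(np.mod(ang_a - ang_i, TWO_PI), 0.0, atol=1e-9):
        raise InvalidLandmarkError("insertion points lie at the same angle")
    mid = 0.5 * (a + i) - c
    if np.hypot(*mid) <= 1e-9:
        raise InvalidLandmarkError(
            "insertion points are antipodal; septal side is ambiguous"
        )
    ang_mid = np.mod(np.arctan2(mid[1], mid[0]), TWO_PI)
    window = AngularWindow(ang_i, ang_a, "septal")
    if not window.contains(np.array([ang_mid]))[0]:
        window = AngularWindow(ang_a, ang_i, "septal")
    return window


def swept_sector_area(
    profile_ed: RadialProfile, profile_es: RadialProfile, window: AngularWindow
) -> float:
    """Signed area (mm²) swept between two superimposed contours in a sector.

    Computed as ``sum over grid angles in window of 0.5*(r_ED^2 - r_ES^2)*dtheta``.
    Positive when the ES contour lies inside the ED contour (inward radial
    motion contributing to stroke volume), negative when ES lies outside ED
    (dyskinetic outward motion).
    """
    if profile_ed.n_theta != profile_es.n_theta:
        raise GridMismatchError(
            f"profiles have different n_theta: {profile_ed.n_theta} vs {profile_es.n_theta}"
        )
    if not np.allclose(profile_ed.center, profile_es.center, atol=1e-9):
        raise GridMismatchError("profiles do not share a polar center")
    if not np.allclose(profile_ed.angles, profile_es.angles, atol=1e-12):
        raise GridMismatchError("profiles do not share the angular grid")
    dtheta = TWO_PI / profile_ed.n_theta
    mask = window.contains(profile_ed.angles)
    return float(
        0.5 * np.sum(profile_ed.radii[mask] ** 2 - profile_es.radii[mask] ** 2) * dtheta
    )
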