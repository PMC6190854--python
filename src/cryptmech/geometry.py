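"""Idealized gland geometry and planar contour shape descriptors.

A gastric gland together with its pit is modelled as an "L"-shaped tube: a
vertical cylindrical pit (axis perpendicular to the mucosal surface) joined at
a right angle to a horizontal cylindrical gland body (axis parallel to the
surface).  Every cross-section of either segment is a circle — the shape that
maximizes enclosed area at fixed perimeter — which is why a resting crypt
opening looks round.  As the opening deforms, two scalar descriptors track the
departure from circularity:

* the isoperimetric ratio ``4*pi*A / P**2`` (1 for a circle, -> 0 for a
  degenerate line), and
* the aspect ratio of the principal-axis extents (1 for a circle, large for
  elongated openings).

Contours are planar, ordered counter-clockwise, and closed implicitly
(last vertex connects back to the first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Contour",
    "LTubeGeometry",
    "isoperimetric_ratio",
    "build_l_tube",
    "shape_metrics",
]


class ContourError(ValueError):
    """Raised for open, degenerate or otherwise invalid contours."""


@dataclass(frozen=True)
class Contour:
    """A closed planar polygonal contour.

    Parameters
    ----------
    points
        ``(n, 2)`` array of vertices in order.  Coordinates are in
        dimensionless length units (cell diameters).
    closed
        Whether the contour is closed (last vertex joins the first).  Only
        closed contours support area-based metrics.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError("contour points must be an (n, 2) array")
        if self.closed and len(pts) < 3:
            raise ContourError("a closed contour needs at least 3 points")
        # drop an explicitly repeated closing vertex
        if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) > 1:
            dup = np.all(pts == np.roll(pts, -1, axis=0), axis=1)
            if self.closed and dup.any():
                raise ContourError("consecutive duplicate points in contour")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        """Shoelace signed area; positive for counter-clockwise order."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def perimeter(self) -> float:
        d = np.roll(self.points, -1, axis=0) - self.points
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed region."""
        p, q = self.points, np.roll(self.points, -1, axis=0)
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        a = 0.5 * np.sum(cross)
        if a == 0.0:
            raise ContourError("zero-area contour has no area centroid")
        c = np.sum((p + q) * cross[:, None], axis=0) / (6.0 * a)
        return c


@dataclass(frozen=True)
class LTubeGeometry:
    """Dimensions of the L-shaped pit + gland tube.

    The pit is a vertical cylinder of radius ``pit_radius`` and length
    ``pit_depth``; the gland body is a horizontal cylinder of radius
    ``gland_radius`` and length ``gland_length`` joined at the pit bottom at a
    right angle.  ``n_circumference`` points sample each circular
    cross-section and ``n_axial`` sections sample the full axis.
    """

    pit_radius: float
    gland_radius: float
    pit_depth: float
    gland_length: float
    n_circumference: int = 48
    n_axial: int = 30

    def __post_init__(self) -> None:
        for name in ("pit_radius", "gland_radius", "pit_depth", "gland_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_circumference < 3 or self.n_axial < 3:
            raise ValueError("sampling counts must be >= 3")


def isoperimetric_ratio(contour: Contour) -> float:
    """Circularity ``4*pi*A / P**2`` of a closed contour.

    Equals 1 only for a circle (up to polygonal discretization) and is
    bounded above by 1 for every simple closed curve — the isoperimetric
    inequality.  Elongated openings score close to 0.

    Raises
    ------
    ContourError
        If the contour is open or has zero area or perimeter.
    """
    if not contour.closed:
        raise ContourError("isoperimetric ratio requires a closed contour")
    area = contour.area
    perim = contour.perimeter
    if area == 0.0 or perim == 0.0:
        raise ContourError("degenerate (zero-area) contour")
    return 4.0 * math.pi * area / perim**2


def _circle(center: np.ndarray, radius: float, n: int) -> Contour:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    pts = np.column_stack([np.cos(t), np.sin(t)]) * radius + center
    return Contour(pts)


@dataclass(frozen=True)
class LTubeSample:
    """Sampled L-tube: circular sections positioned along the bent axis."""

    axis_points: np.ndarray          # (n_axial, 3) section centers
    sections: list = field(default_factory=list)  # per-section Contour (local plane)
    section_radii: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def turn_angle(self) -> float:
        """Angle between pit axis and gland axis (radians)."""
        return math.pi / 2.0


def build_l_tube(geom: LTubeGeometry) -> LTubeSample:
    """Sample the L-shaped tube as circular cross-sections along its axis.

    The pit segment runs from the mucosal surface at the origin straight down
    (-y) for ``pit_depth``; the gland segment continues horizontally (+x) for
    ``gland_length``.  Sections are allocated to the two segments in
    proportion to their lengths (each segment gets at least one), and each is
    a circle of that segment's radius lying in the plane normal to the local
    axis.
    """
    total = geom.pit_depth + geom.gland_length
    n_pit = max(1, min(geom.n_axial - 1, round(geom.n_axial * geom.pit_depth / total)))
    n_gland = geom.n_axial - n_pit

    centers = []
    radii = []
    for i in range(n_pit):
        s = geom.pit_depth * i / max(n_pit - 1, 1) if n_pit > 1 else 0.0
        centers.append([0.0, -s, 0.0])
        radii.append(geom.pit_radius)
    for j in range(1, n_gland + 1):
        s = geom.gland_length * j / n_gland
        centers.append([s, -geom.pit_depth, 0.0])
        radii.append(geom.gland_radius)

    sections = [_circle(np.zeros(2), r, geom.n_circumference) for r in radii]
    return LTubeSample(
        axis_points=np.asarray(centers),
        sections=sections,
        section_radii=np.asarray(radii),
    )


def shape_metrics(contour: Contour) -> dict:
    """Shape descriptors of a closed contour.

    Returns a dict with:

    ``isoperimetric_ratio``
        ``4*pi*A/P**2`` as in :func:`isoperimetric_ratio`.
    ``aspect_ratio``
        Ratio (>= 1) of the vertex extents along the two principal axes of
        the vertex second-moment tensor.  Axes are tie-broken toward x so the
        result is deterministic under symmetry.
    ``max_width``
        Extent along the major principal axis.
    ``asymmetry``
        Normalized offset of the area centroid from the midpoint of the
        major-axis extent — 0 for mirror-symmetric shapes such as circles and
        ellipses, positive for teardrop-like contours.
    """
    if not contour.closed:
        raise ContourError("shape metrics require a closed contour")
    iso = isoperimetric_ratio(contour)

    pts = contour.points - contour.points.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)          # ascending eigenvalues
    major, minor = evecs[:, 1], evecs[:, 0]
    if abs(evals[1] - evals[0]) < 1e-12 * max(evals[1], 1.0):
        # isotropic: tie-break to the coordinate axes
        major, minor = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    proj_major = pts @ major
    proj_minor = pts @ minor
    ext_major = float(proj_major.max() - proj_major.min())
    ext_minor = float(proj_minor.max() - proj_minor.min())
    if ext_major == 0.0 or ext_minor == 0.0:
        raise ContourError("degenerate contour: zero extent")
    if ext_major < ext_minor:
        ext_major, ext_minor = ext_minor, ext_major
        proj_major = proj_minor
        major = minor

    centroid = contour.centroid - contour.points.mean(axis=0)
    mid = 0.5 * (proj_major.max() + proj_major.min())
    asym = abs(float(centroid @ major) - mid) / ext_major

    return {
        "isoperimetric_ratio": iso,
        "aspect_ratio": ext_major / ext_minor,
        "max_width": ext_major,
        "asymmetry": asym,
    }
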