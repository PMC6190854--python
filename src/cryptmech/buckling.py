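"""Beam mechanics of the epithelial sheet: strain, bending moment, Euler load.

A segment of the columnar epithelium under the axial pull from continuous
regeneration behaves as a thin elastic beam.  A small bend strains material
at height ``y`` from the neutral surface by ``y/R`` (``R`` the radius of
curvature); integrating Hooke's law over the cross-section gives the bending
moment ``tau = E*I/R`` with ``I`` the second moment of area about the
centroidal (neutral) axis.  Balancing that moment against the axial load's
moment arm yields the pinned-pinned mode shape ``y = K sin(pi x / Lc)`` and
the critical (Euler) load

    F_crit = pi**2 * E * I / Lc**2

above which the sheet buckles.  In the crypt model this threshold is not a
rupture load: reaching it triggers EMT, which flattens the deflection and
keeps the axial force at the threshold's vicinity.

The discrete-chain routine provides an independent route to the same
critical load: the smallest axial force at which the linearized transverse
stiffness of an n-segment pinned chain loses positive-definiteness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "ElasticParams",
    "BeamState",
    "bending_strain",
    "moment_of_inertia",
    "bending_moment",
    "bending_moment_integral",
    "euler_critical_force",
    "mode_shape",
    "discrete_chain_critical_load",
    "critical_load_from_profile",
]

#: validity limit of the small-slope curvature approximation d2y/dx2 ~ 1/R
SMALL_SLOPE_LIMIT = 0.2


@dataclass
class ElasticParams:
    """Elastic constants of the epithelial sheet.

    ``E`` Young's modulus (force/area), ``I`` second moment of area
    (length^4), ``Lc`` the end-to-end connecting length of the buckled
    segment (the sine wavelength; twice the cell-segment length ``l``),
    ``K_mode`` the sine amplitude.  All dimensionless model units.
    """

    E: float = 1.0
    I: float = 1.0 / 12.0
    Lc: float = 2.0
    K_mode: float = 0.01

    def __post_init__(self) -> None:
        if self.E <= 0 or self.I <= 0 or self.Lc <= 0:
            raise ValueError("E, I and Lc must be positive")

    @property
    def l(self) -> float:
        """Cell-segment length; the wavelength Lc spans two segments."""
        return self.Lc / 2.0

    @property
    def F_crit(self) -> float:
        return euler_critical_force(self.E, self.I, self.Lc)


@dataclass
class BeamState:
    """A sampled transverse deflection profile under axial load."""

    x_p: np.ndarray
    y_p: np.ndarray
    F_C_xz: float = 0.0

    def __post_init__(self) -> None:
        self.x_p = np.asarray(self.x_p, dtype=float)
        self.y_p = np.asarray(self.y_p, dtype=float)
        if self.x_p.shape != self.y_p.shape:
            raise ValueError("x_p and y_p must have the same shape")

    @property
    def max_slope(self) -> float:
        return float(np.max(np.abs(np.gradient(self.y_p, self.x_p))))


def bending_strain(y: float, R: float) -> float:
    """Longitudinal strain ``y/R`` at height y above the neutral surface.

    Positive strain means stretch (material below the neutral surface of a
    downward bend), negative means compression; ``y = 0`` is unstrained by
    definition of the neutral surface.
    """
    if R == 0:
        raise ValueError("radius of curvature must be non-zero")
    return y / R


def moment_of_inertia(
    width,
    y_min: float,
    y_max: float,
    *,
    about: float | str = "centroid",
    rtol: float = 1e-8,
) -> float:
    """Second moment of area ``I = integral(y^2 dA)`` of a height profile.

    The section is described by its width ``w(y)`` over ``[y_min, y_max]``
    (a callable, or a scalar for a rectangle).  Quadrature is the midpoint
    rule on a regular grid, refined (with Richardson extrapolation) until the
    relative change is below ``rtol``.

    Parameters
    ----------
    about
        ``"centroid"`` (default) measures y from the area centroid — the
        neutral axis of a small bend; a float measures from that fixed axis
        instead.  The centroidal value is minimal (parallel-axis theorem).
    """
    if y_max <= y_min:
        raise ValueError("y_max must exceed y_min")
    if callable(width):
        wfun = width
    else:
        w0 = float(width)
        if w0 <= 0:
            raise ValueError("width must be positive")
        wfun = lambda y: w0  # noqa: E731

    def quad(f, n: int) -> float:
        y = y_min + (np.arange(n) + 0.5) * (y_max - y_min) / n
        w = np.array([wfun(v) for v in y], dtype=float)
        return float(np.sum(f(y) * w)) * (y_max - y_min) / n

    def refine(f) -> float:
        n = 64
        prev = quad(f, n)
        for _ in range(18):
            n *= 2
            cur = quad(f, n)
            # midpoint rule is O(h^2): Richardson step
            extrap = cur + (cur - prev) / 3.0
            if abs(cur - prev) <= rtol * max(abs(extrap), 1e-300):
                return extrap
            prev = cur
        return extrap

    area = refine(lambda y: np.ones_like(y))
    if area <= 0:
        raise ValueError("section must have positive area")
    if about == "centroid":
        axis = refine(lambda y: y) / area
    else:
        axis = float(about)
    return refine(lambda y: (y - axis) ** 2)


def bending_moment(E: float, I: float, R: float) -> float:
    """Bending moment ``tau = E*I/R`` of a uniformly curved section."""
    if R == 0:
        raise ValueError("radius of curvature must be non-zero")
    if E <= 0 or I <= 0:
        raise ValueError("E and I must be positive")
    return E * I / R


def bending_moment_integral(
    E: float,
    R: float,
    width,
    y_min: float,
    y_max: float,
    *,
    rtol: float = 1e-8,
) -> float:
    """Bending moment from the stress integral ``(E/R) integral(y^2 dA)``.

    Independent route to :func:`bending_moment`; the two agree to quadrature
    tolerance on any section (the integral IS ``E*I/R``).
    """
    if R == 0:
        raise ValueError("radius of curvature must be non-zero")
    I = moment_of_inertia(width, y_min, y_max, rtol=rtol)
    return E * I / R


def euler_critical_force(E: float, I: float, Lc: float) -> float:
    """Critical axial load ``pi^2 E I / Lc^2`` of the pinned-pinned sheet.

    Independent of the deflection amplitude for small bending; below it the
    epithelium cannot buckle (and hence cannot break), above it EMT fires.
    """
    if E <= 0 or I <= 0 or Lc <= 0:
        raise ValueError("E, I and Lc must be positive")
    return math.pi**2 * E * I / Lc**2


def mode_shape(K_mode: float, Lc: float, x_p):
    """First buckling mode ``y = K sin(pi x / Lc)`` on ``[0, Lc]``.

    Satisfies the pinned-end conditions and the small-bend moment balance
    ``y'' = -(pi/Lc)^2 y`` exactly; peak deflection ``K_mode`` at mid-span.
    """
    if Lc <= 0:
        raise ValueError("Lc must be positive")
    x = np.asarray(x_p, dtype=float)
    if np.any(x < -1e-12) or np.any(x > Lc + 1e-12):
        raise ValueError("x_p must lie in [0, Lc]")
    y = K_mode * np.sin(math.pi * x / Lc)
    return float(y) if np.isscalar(x_p) else y


def discrete_chain_critical_load(
    n_segments: int, E: float, I: float, Lc: float
) -> float:
    """Buckling load of an n-segment pinned chain with bending stiffness E*I.

    Builds the linearized transverse bending stiffness and geometric
    stiffness of the chain and returns the smallest axial load at which
    ``K_bend - F * K_geo`` loses positive-definiteness (the smallest
    generalized eigenvalue).  Converges to :func:`euler_critical_force`
    as ``n_segments`` grows, with O(1/n^2) error.
    """
    if n_segments < 3:
        raise ValueError("need at least 3 segments")
    if E <= 0 or I <= 0 or Lc <= 0:
        raise ValueError("E, I and Lc must be positive")
    a = Lc / n_segments
    m = n_segments - 1  # interior nodes; ends pinned at zero
    # second-difference operator (interior), pinned BCs
    C = (
        np.diag(np.full(m, -2.0))
        + np.diag(np.ones(m - 1), 1)
        + np.diag(np.ones(m - 1), -1)
    )
    # bending energy 1/2 (EI/a^3) |C y|^2  ->  K_bend = (EI/a^3) C^T C;
    # EI is factored out of the solve so the result is exactly linear in it
    K_bend_unit = (1.0 / a**3) * (C.T @ C)
    # axial shortening 1/(2a) |D y|^2 with D the n x (n-1) difference map
    D = np.zeros((n_segments, m))
    for i in range(n_segments):
        if i - 1 >= 0:
            D[i, i - 1] = -1.0
        if i < m:
            D[i, i] = 1.0
    K_geo = (1.0 / a) * (D.T @ D)
    evals = scipy.linalg.eigh(K_bend_unit, K_geo, eigvals_only=True)
    return E * I * float(evals[0])


def critical_load_from_profile(x: np.ndarray, y: np.ndarray, E: float, I: float) -> float:
    """Critical load detected from a sampled buckled profile.

    Energy-balance (Rayleigh) estimate: bending energy stored in the profile
    divided by the axial end-shortening it produces, both evaluated with the
    exact arc-length geometry.  For the sine mode this recovers the Euler
    load, independent of amplitude in the small-bending regime; a warning is
    issued when the profile leaves that regime (max slope above
    ``SMALL_SLOPE_LIMIT``, where equating curvature with y'' degrades).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 profile samples")
    dy = np.gradient(y, x)
    d2y = np.gradient(dy, x)
    if np.max(np.abs(dy)) > SMALL_SLOPE_LIMIT:
        warnings.warn(
            "profile slope exceeds the small-bending validity limit; the "
            "curvature approximation 1/R = y'' degrades",
            stacklevel=2,
        )
    kappa = d2y / (1.0 + dy**2) ** 1.5
    ds = np.sqrt(1.0 + dy**2)
    bend = 0.5 * E * I * np.trapezoid(kappa**2 * ds, x)
    shorten = np.trapezoid(ds - 1.0, x)
    if shorten <= 0:
        raise ValueError("profile produces no end-shortening")
    return float(bend / shorten)
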