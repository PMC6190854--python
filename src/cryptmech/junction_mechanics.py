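"""Force balance at the crypt rim and quasi-static spring-network relaxation.

The marginal crypt epithelium (MCE) — the ring of cells bordering the crypt
opening — is modelled as point cells joined by linear springs standing for
E-cadherin adhesion, the only internal force of the idealized epithelium.
Cell division in the column beneath the focal rim cell ``C_e`` exerts a pull
on it; its rim neighbours ``C_R`` and ``C_L`` resist through their junctions.

Projecting onto the mucosal plane (the paper-thin "xz" plane of the opening),
equilibrium of ``C_e`` requires

    F_C = F_R * cos(theta1) + F_L * cos(theta2)

where ``theta1, theta2`` are the angles the neighbour junctions make with the
pull axis.  When all three magnitudes are equal the junctions open at
``theta1 + theta2 = 120`` degrees — the hexagonal-packing angle.  As the pull
grows the junction chain behind ``C_R`` straightens: the bond angle
``theta3`` at ``C_R`` tends to ``pi`` and the tensions along the chain
equalize, which is what turns a round opening into a droplet and finally an
approximately straight line.

Relaxation is an overdamped quasi-static scheme: damped fixed-point
iteration on the net nodal forces with backtracking on the total elastic
energy, run until every cell's net force falls below a tolerance.  Cells may
be anchored to the substrate (basement membrane) by weak springs so that a
net applied force has a finite equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Role",
    "Cell",
    "Junction",
    "ForceState",
    "RingEquilibrium",
    "ConvergenceError",
    "x_balance_residual",
    "y_balance_residual",
    "solve_symmetric_angles",
    "straightening_angle",
    "relax_ring",
    "total_energy",
    "make_ring",
]


class Role(str, Enum):
    MCE = "MCE"
    EPITHELIAL = "epithelial"
    STEM = "stem"


@dataclass
class Cell:
    """A point epithelial cell."""

    id: int
    position: np.ndarray
    radius: float = 0.5
    column_index: int = 0
    role: Role = Role.MCE

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cell radius must be positive")
        self.position = np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class Junction:
    """Elastic bond between two cells (E-cadherin adhesion)."""

    cell_a: int
    cell_b: int
    rest_length: float
    stiffness: float

    def __post_init__(self) -> None:
        if self.rest_length <= 0:
            raise ValueError("rest_length must be positive")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.cell_a, self.cell_b))


@dataclass
class ForceState:
    """Resolved in-plane forces and angles at the focal rim cell.

    Magnitudes are of the projections onto the opening plane; angles are in
    radians.  ``theta3`` is the bond angle of the rim chain at the first
    right-hand neighbour, which tends to pi as the chain straightens.
    The lumped volume terms (``V``, ``rho``, ``a``) exist because the
    division force is physically a volume integral of a force density; the
    quasi-static scheme only visits equilibria, so ``a`` is identically 0.
    """

    F_C_xz: float = 0.0
    F_R_xz: float = 0.0
    F_L_xz: float = 0.0
    F_pulling: float = 0.0
    F_R1_xz: float = 0.0
    F_R2_xz: float = 0.0
    theta1: float = math.pi / 2
    theta2: float = math.pi / 2
    theta3: float = math.pi
    theta_R_y: float = math.pi / 2
    theta_L_y: float = math.pi / 2
    theta_C_y: float = math.pi / 2
    F_ext: np.ndarray = field(default_factory=lambda: np.zeros(2))
    F_int: np.ndarray = field(default_factory=lambda: np.zeros(2))
    V: float = 1.0
    rho: float = 1.0
    a: float = 0.0

    @property
    def f_ext(self) -> np.ndarray:
        """Lumped force density: applied force per unit cell volume."""
        return self.F_ext / self.V

    def __post_init__(self) -> None:
        for name in ("F_C_xz", "F_R_xz", "F_L_xz", "F_pulling", "F_R1_xz", "F_R2_xz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.theta1 <= math.pi / 2 + 1e-12):
            raise ValueError("theta1 must lie in [0, pi/2]")
        if not (0.0 <= self.theta2 <= math.pi / 2 + 1e-12):
            raise ValueError("theta2 must lie in [0, pi/2]")
        if not (0.0 <= self.theta3 <= math.pi + 1e-12):
            raise ValueError("theta3 must lie in [0, pi]")


class ConvergenceError(RuntimeError):
    """Relaxation failed to reach the force tolerance within the cap."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"relaxation did not converge: residual {residual:.3e} "
            f"after {iterations} iterations"
        )


def x_balance_residual(state: ForceState) -> float:
    """In-plane balance residual along the pull axis.

    ``F_C - (F_R cos(theta1) + F_L cos(theta2))``; zero at equilibrium.
    """
    return state.F_C_xz - (
        state.F_R_xz * math.cos(state.theta1) + state.F_L_xz * math.cos(state.theta2)
    )


def y_balance_residual(state: ForceState, F_ext_y: float) -> float:
    """Vertical balance residual, each pull projected with its own angle."""
    return F_ext_y - (
        state.F_R_xz * math.cos(state.theta_R_y)
        + state.F_L_xz * math.cos(state.theta_L_y)
        + state.F_C_xz * math.cos(state.theta_C_y)
    )


def solve_symmetric_angles(F_C: float, F_side: float) -> tuple[float, float]:
    """Junction angles for a symmetric rim (equal side tensions).

    Solves ``F_C = 2 F_side cos(theta)`` for ``theta1 = theta2 = theta``.
    At ``F_C = F_side`` the opening sits at the hexagonal 120-degree
    condition; the angles close monotonically as the pull grows.

    Raises
    ------
    ValueError
        If ``F_C > 2 F_side`` — no planar solution exists and the chain must
        recruit additional pulling force / further straightening.
    """
    if F_side <= 0:
        raise ValueError("F_side must be positive")
    if F_C < 0:
        raise ValueError("F_C must be non-negative")
    if F_C > 2.0 * F_side:
        raise ValueError(
            "no solution: F_C exceeds 2*F_side; the junction pair cannot "
            "balance the pull at any angle"
        )
    theta = math.acos(F_C / (2.0 * F_side))
    return theta, theta


def straightening_angle(F_R1: float, F_R2: float) -> float:
    """Bond angle theta3 at the first rim neighbour.

    From ``F_R1 = F_R2 cos(pi - theta3)``: ``theta3 = pi - arccos(F_R1/F_R2)``.
    Equal tensions give a straight chain (``theta3 = pi``).
    """
    if F_R2 <= 0:
        raise ValueError("F_R2 must be positive")
    if F_R1 < 0:
        raise ValueError("F_R1 must be non-negative")
    if F_R1 > F_R2:
        raise ValueError("no solution: F_R1 exceeds F_R2")
    return math.pi - math.acos(F_R1 / F_R2)


# ---------------------------------------------------------------------------
# spring-network relaxation


def total_energy(
    pos: np.ndarray,
    edges: np.ndarray,
    rest: np.ndarray,
    stiff: np.ndarray,
    applied: np.ndarray,
    anchor_pos: np.ndarray | None,
    anchor_stiffness: float,
) -> float:
    """Total potential: spring + anchor energy minus work of applied forces."""
    d = pos[edges[:, 0]] - pos[edges[:, 1]]
    length = np.hypot(d[:, 0], d[:, 1])
    e = 0.5 * np.sum(stiff * (length - rest) ** 2)
    if anchor_stiffness > 0.0 and anchor_pos is not None:
        e += 0.5 * anchor_stiffness * np.sum((pos - anchor_pos) ** 2)
    e -= float(np.sum(applied * pos))
    return float(e)


def _net_forces(
    pos: np.ndarray,
    edges: np.ndarray,
    rest: np.ndarray,
    stiff: np.ndarray,
    applied: np.ndarray,
    anchor_pos: np.ndarray | None,
    anchor_stiffness: float,
) -> np.ndarray:
    d = pos[edges[:, 0]] - pos[edges[:, 1]]
    length = np.hypot(d[:, 0], d[:, 1])
    length = np.where(length == 0.0, 1e-300, length)
    # tension > 0 when stretched: pulls endpoints together
    fpair = (stiff * (length - rest) / length)[:, None] * d
    forces = applied.copy()
    np.subtract.at(forces, edges[:, 0], fpair)
    np.add.at(forces, edges[:, 1], fpair)
    if anchor_stiffness > 0.0 and anchor_pos is not None:
        forces -= anchor_stiffness * (pos - anchor_pos)
    return forces


@dataclass
class RingEquilibrium:
    """Result of :func:`relax_ring`."""

    positions: dict
    force_state: ForceState
    residual: float
    iterations: int
    energy: float
    contour_points: np.ndarray


def _resolve_force_state(
    pos: np.ndarray,
    index: dict,
    cells: list,
    junctions: list,
    applied: np.ndarray,
    focal: int,
) -> ForceState:
    """Measure tensions and angles at the focal cell from a configuration."""
    i_e = index[focal]
    pull = applied[i_e]
    F_C = float(np.hypot(*pull))
    axis = pull / F_C if F_C > 0 else np.array([1.0, 0.0])

    # rim neighbours of the focal cell through MCE junctions
    nbrs = []
    for j in junctions:
        if focal in (j.cell_a, j.cell_b):
            other = j.cell_b if j.cell_a == focal else j.cell_a
            d = pos[index[other]] - pos[i_e]
            ln = float(np.hypot(*d))
            tension = j.stiffness * (ln - j.rest_length)
            nbrs.append((other, max(tension, 0.0), d / ln if ln > 0 else d, j))
    state = ForceState(F_C_xz=F_C, F_ext=pull.astype(float))
    if len(nbrs) < 2:
        return state

    # classify left/right by the sign of the cross product with the pull axis
    def side(v: np.ndarray) -> float:
        return axis[0] * v[1] - axis[1] * v[0]

    nbrs.sort(key=lambda t: side(t[2]))
    right, left = nbrs[0], nbrs[-1]

    def angle_to_axis(v: np.ndarray) -> float:
        # junction restoring force on C_e points toward the neighbour
        c = float(np.clip(-v @ axis, -1.0, 1.0))
        return math.acos(c)

    th1 = angle_to_axis(right[2])
    th2 = angle_to_axis(left[2])
    state.F_R_xz = right[1]
    state.F_L_xz = left[1]
    state.theta1 = min(th1, math.pi / 2)
    state.theta2 = min(th2, math.pi / 2)
    state.F_pulling = max(F_C - (right[1] * math.cos(state.theta1) + left[1] * math.cos(state.theta2)), 0.0)

    # chain straightening at C_R: bond angle between C_R->C_e and C_R->C_s-R
    i_r = index[right[0]]
    chain = []
    for j in junctions:
        if right[0] in (j.cell_a, j.cell_b):
            other = j.cell_b if j.cell_a == right[0] else j.cell_a
            if other == focal:
                continue
            d = pos[index[other]] - pos[i_r]
            ln = float(np.hypot(*d))
            tension = j.stiffness * (ln - j.rest_length)
            chain.append((max(tension, 0.0), d / ln if ln > 0 else d))
    if chain:
        t2, u2 = max(chain, key=lambda t: t[0])
        u1 = pos[i_e] - pos[i_r]
        u1 = u1 / float(np.hypot(*u1))
        state.F_R1_xz = right[1]
        state.F_R2_xz = t2
        cosang = float(np.clip(u1 @ u2, -1.0, 1.0))
        state.theta3 = math.acos(cosang)
    return state


def relax_ring(
    cells: list,
    junctions: list,
    applied: dict | None = None,
    tol: float = 1e-8,
    *,
    anchor_stiffness: float = 0.0,
    fixed: set | frozenset = frozenset(),
    max_iter: int = 100_000,
    focal: int | None = None,
    initial_positions: np.ndarray | None = None,
) -> RingEquilibrium:
    """Relax a spring network of cells to mechanical equilibrium.

    Overdamped quasi-static relaxation: damped fixed-point iteration on the
    net nodal forces, with the step length chosen by backtracking so the
    total elastic energy never increases.  Stops when every free cell's net
    force magnitude is below ``tol``.

    Parameters
    ----------
    cells, junctions
        The network.  The junction graph must be connected.
    applied
        Map ``cell id -> 2-vector`` of externally applied force (the pull
        from the dividing column).  Missing ids get zero force.
    tol
        Force-residual tolerance (dimensionless force units).
    anchor_stiffness
        Stiffness of substrate anchor springs tying each cell to its initial
        position.  Required (> 0) whenever the applied forces do not sum to
        zero and no cell is fixed, otherwise no equilibrium exists.
    fixed
        Ids of cells clamped at their initial positions.
    focal
        Id of the focal rim cell for force resolution; defaults to the cell
        with the largest applied force.
    initial_positions
        Warm-start positions, shape ``(n, 2)`` in cell order.

    Raises
    ------
    ConvergenceError
        If the residual is still above ``tol`` after ``max_iter`` iterations.
    ValueError
        If the configuration admits no equilibrium (unbalanced force, no
        anchors, nothing fixed).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    index = {c.id: k for k, c in enumerate(cells)}
    n = len(cells)
    if initial_positions is not None:
        pos = np.array(initial_positions, dtype=float)
    else:
        pos = np.array([c.position for c in cells], dtype=float)
    anchor_pos = np.array([c.position for c in cells], dtype=float)

    edges = np.array([[index[j.cell_a], index[j.cell_b]] for j in junctions], dtype=int)
    rest = np.array([j.rest_length for j in junctions])
    stiff = np.array([j.stiffness for j in junctions])

    app = np.zeros((n, 2))
    applied = applied or {}
    for cid, f in applied.items():
        app[index[cid]] = np.asarray(f, dtype=float)

    free = np.ones(n, dtype=bool)
    for cid in fixed:
        free[index[cid]] = False

    if anchor_stiffness == 0.0 and not fixed:
        if float(np.hypot(*app.sum(axis=0))) > 1e-12:
            raise ValueError(
                "net applied force is non-zero but no anchors or fixed cells "
                "provide a reaction; no equilibrium exists"
            )

    # Gershgorin bound on the stiffness matrix: per-node sum of incident
    # spring stiffness plus the anchor; steps below ~1/bound are stable.
    node_k = np.full(n, anchor_stiffness)
    for (ia, ib), k in zip(edges, stiff):
        node_k[ia] += k
        node_k[ib] += k
    kmax = float(node_k.max()) if n else 1.0
    dt0 = 0.9 / max(kmax, 1e-12)
    dt = dt0

    energy = total_energy(pos, edges, rest, stiff, app, anchor_pos, anchor_stiffness)
    # the energy safeguard cannot resolve changes below rounding of E itself
    e_floor = 64.0 * np.finfo(float).eps * max(abs(energy), 1.0)
    residual = math.inf
    it = 0
    while it < max_iter:
        forces = _net_forces(pos, edges, rest, stiff, app, anchor_pos, anchor_stiffness)
        forces[~free] = 0.0
        residual = float(np.max(np.hypot(forces[:, 0], forces[:, 1]))) if n else 0.0
        if residual < tol:
            break
        accepted = False
        for _ in range(40):
            trial = pos + dt * forces
            e_trial = total_energy(trial, edges, rest, stiff, app, anchor_pos, anchor_stiffness)
            if e_trial <= energy + e_floor:
                pos, energy = trial, e_trial
                dt = min(dt * 1.1, dt0)
                accepted = True
                break
            dt *= 0.5
        if not accepted:
            # energy flat to rounding near the minimum: the damped step at
            # the stability bound is safe, take it and restore the step size
            dt = dt0
            pos = pos + dt * forces
            energy = total_energy(pos, edges, rest, stiff, app, anchor_pos, anchor_stiffness)
        e_floor = 64.0 * np.finfo(float).eps * max(abs(energy), 1.0)
        it += 1
    else:
        raise ConvergenceError(residual, it)

    if focal is None:
        focal = cells[int(np.argmax(np.hypot(app[:, 0], app[:, 1])))].id
    state = _resolve_force_state(pos, index, cells, junctions, app, focal)
    return RingEquilibrium(
        positions={c.id: pos[index[c.id]].copy() for c in cells},
        force_state=state,
        residual=residual,
        iterations=it,
        energy=energy,
        contour_points=pos.copy(),
    )


def make_ring(
    n: int,
    radius: float = 1.0,
    stiffness: float = 1.0,
    *,
    rest_length: float | None = None,
) -> tuple[list, list]:
    """Regular ring of MCE cells with nearest-neighbour junctions.

    Rest lengths default to the ring chord so the unloaded ring is at
    equilibrium.  Cell 0 sits on the +x axis; ids run counter-clockwise.
    """
    if n < 3:
        raise ValueError("a ring needs at least 3 cells")
    if radius <= 0:
        raise ValueError("radius must be positive")
    chord = 2.0 * radius * math.sin(math.pi / n)
    if rest_length is None:
        rest_length = chord
    cells = []
    for i in range(n):
        t = 2.0 * math.pi * i / n
        cells.append(
            Cell(
                id=i,
                position=np.array([radius * math.cos(t), radius * math.sin(t)]),
                radius=chord / 2.0,
                column_index=i,
                role=Role.MCE,
            )
        )
    junctions = [
        Junction(cell_a=i, cell_b=(i + 1) % n, rest_length=rest_length, stiffness=stiffness)
        for i in range(n)
    ]
    return cells, junctions
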