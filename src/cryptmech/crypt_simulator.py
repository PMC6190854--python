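"""Orchestration of the crypt-opening trajectory.

Each simulation step is one stem-cell division in the column beneath the
focal rim cell ``C_e``:

1. the division increments the axial pull ``F_C_xz`` by a fixed amount;
2. the rim ring is relaxed to quasi-static equilibrium under the total
   drive — the current elastic pull plus the accumulated viscoelastic creep
   ``S_x`` expressed as an equivalent permanent pull ``K_spring * S_x``;
3. the hysteresis ledger records the stretch/recovery pair ``(S_n, S0_n)``;
4. the buckling threshold is checked, and if the elastic pull exceeds the
   Euler load, EMT fires: the deflection is flattened and the pull drops
   back to the threshold, so the elastic force stays in the Euler-force
   vicinity while the creep — and hence the opening shape — keeps evolving.

Deformation attenuates with depth below the rim (Saint-Venant), modelled as
an exponential decay of the accumulated displacement over the stacked
cross-sections of the pit, optionally augmented by cells added near the
stem-cell replication zone.

The emergent trajectory of the opening contour is the transition the model
exists to produce: round -> (oval) -> droplet -> approximately straight
line, the fundic-to-pyloric crypt-opening sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .buckling import euler_critical_force
from .geometry import Contour, shape_metrics
from .junction_mechanics import make_ring, relax_ring
from .viscoelastic import DisplacementLedger

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SimState",
    "EMTEvent",
    "CrossSectionState",
    "ClassifierThresholds",
    "SimulationResult",
    "LABEL_ORDER",
    "step",
    "emt_feedback",
    "depth_profile",
    "classify_opening",
    "run",
]

#: shape classes in the order the opening traverses them
LABEL_ORDER = ("round", "oval", "droplet", "linear", "groove")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (dimensionless model units).

    Defaults describe a 24-cell rim ring of unit radius with unit junction
    stiffness, a beam with a unit-square cell cross-section (``I = 1/12``)
    whose buckled segment spans two cell lengths (``Lc = 2``), moderate
    cytoplasmic viscosity (``F_v = 0.5``), and a per-division force
    increment of 5% of the Euler load.
    """

    n_divisions: int = 200
    delta_F_per_division: float | None = None  # default 0.05 * F_crit
    ring_size: int = 24
    ring_radius: float = 1.0
    K_spring: float = 1.0
    F_v: float = 0.5
    E: float = 1.0
    I: float = 1.0 / 12.0
    Lc: float = 2.0
    junction_stiffness: float = 1.0
    anchor_stiffness: float = 0.1
    n_cross_sections: int = 5
    attenuation_lambda: float = 0.5
    emt_tolerance_band: float = 0.05
    emt_enabled: bool = True
    seed: int = 0
    A_L_schedule: tuple = ()
    relax_tol: float = 1e-7
    y_p_base: float = 0.01

    def __post_init__(self) -> None:
        if self.n_divisions < 0:
            raise SimConfigError("n_divisions must be non-negative")
        if self.ring_size < 3:
            raise SimConfigError("ring_size must be at least 3")
        for name in (
            "ring_radius", "K_spring", "E", "I", "Lc",
            "junction_stiffness", "relax_tol", "attenuation_lambda",
        ):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.F_v < 0 or self.anchor_stiffness < 0:
            raise SimConfigError("F_v and anchor_stiffness must be non-negative")
        if not (0.0 < self.emt_tolerance_band < 1.0):
            raise SimConfigError("emt_tolerance_band must lie in (0, 1)")
        if self.delta_F_per_division is not None and self.delta_F_per_division <= 0:
            raise SimConfigError("delta_F_per_division must be positive")
        if self.n_cross_sections < 1:
            raise SimConfigError("n_cross_sections must be at least 1")
        if len(self.A_L_schedule) not in (0, self.n_cross_sections):
            raise SimConfigError(
                "A_L_schedule must be empty or have one entry per cross-section"
            )
        if any(a < 0 for a in self.A_L_schedule):
            raise SimConfigError("A_L_schedule entries must be non-negative")

    @property
    def F_crit(self) -> float:
        return euler_critical_force(self.E, self.I, self.Lc)

    @property
    def delta_F(self) -> float:
        if self.delta_F_per_division is not None:
            return self.delta_F_per_division
        return 0.05 * self.F_crit


@dataclass(frozen=True)
class EMTEvent:
    """One EMT firing: force capped back to the Euler-load vicinity."""

    step_index: int
    cell_id: int
    force_at_trigger: float
    y_p_before: float
    y_p_after: float

    def __post_init__(self) -> None:
        if self.y_p_before < self.y_p_after:
            raise ValueError("EMT must not increase the deflection")


@dataclass
class CrossSectionState:
    """Accumulated displacement of one pit cross-section at depth index m."""

    m: int
    S_x_m: float
    D_L: float
    contour: Contour | None = None


@dataclass
class SimState:
    """Mutable simulation state threaded through :func:`step`."""

    config: SimConfig
    step_index: int = 0
    F_C_xz: float = 0.0
    y_p: float = 0.0
    ledger: DisplacementLedger = field(default_factory=DisplacementLedger)
    emt_events: list = field(default_factory=list)
    cells: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    positions: np.ndarray | None = None
    contour: Contour | None = None
    residual: float = 0.0
    force_state: object = None

    @classmethod
    def initial(cls, config: SimConfig) -> "SimState":
        cells, junctions = make_ring(
            config.ring_size, config.ring_radius, config.junction_stiffness
        )
        state = cls(config=config, cells=cells, junctions=junctions)
        state.ledger = DisplacementLedger(K_spring=config.K_spring, F_v=config.F_v)
        state.contour = Contour(np.array([c.position for c in cells]))
        return state

    @property
    def focal_id(self) -> int:
        """The focal rim cell sits on the +x axis (cell 0 of the ring)."""
        return 0


def _relax(state: SimState) -> None:
    """Relax the rim under the current total drive and update the contour."""
    cfg = state.config
    drive = state.F_C_xz + cfg.K_spring * state.ledger.S_x
    eq = relax_ring(
        state.cells,
        state.junctions,
        applied={state.focal_id: np.array([drive, 0.0])},
        tol=cfg.relax_tol,
        anchor_stiffness=cfg.anchor_stiffness,
        focal=state.focal_id,
        initial_positions=state.positions,
    )
    state.positions = eq.contour_points
    state.contour = Contour(eq.contour_points)
    state.residual = eq.residual
    state.force_state = eq.force_state


def emt_feedback(state: SimState, config: SimConfig | None = None) -> list:
    """Fire EMT while the elastic pull exceeds the Euler load.

    Each firing flattens the buckled deflection (``y_p`` drops in proportion
    to the force reduction) and returns the elastic force to the threshold,
    leaving ``F_C_xz <= F_crit * (1 + emt_tolerance_band)``.  Returns the
    events fired (possibly empty).
    """
    cfg = config or state.config
    events = []
    F_crit = cfg.F_crit
    if state.F_C_xz > F_crit:
        y_before = state.y_p
        y_after = y_before * (F_crit / state.F_C_xz)
        ev = EMTEvent(
            step_index=state.step_index,
            cell_id=state.focal_id,
            force_at_trigger=state.F_C_xz,
            y_p_before=y_before,
            y_p_after=y_after,
        )
        state.F_C_xz = F_crit
        state.y_p = y_after
        state.emt_events.append(ev)
        events.append(ev)
    assert state.F_C_xz <= F_crit * (1.0 + cfg.emt_tolerance_band)
    return events


def step(state: SimState, config: SimConfig | None = None) -> SimState:
    """Advance the simulation by one stem-cell division (in place).

    Order of operations: the division increments the elastic pull, the ring
    is relaxed, the hysteresis ledger records the cycle, and the buckling
    check fires EMT if the pull exceeds the Euler load.
    """
    cfg = config or state.config
    state.step_index += 1
    state.F_C_xz += cfg.delta_F
    state.y_p = cfg.y_p_base * state.F_C_xz / cfg.F_crit
    _relax(state)
    state.ledger.record(state.F_C_xz)
    if cfg.emt_enabled:
        emt_feedback(state, cfg)
    return state


def depth_profile(
    S_x: float | DisplacementLedger,
    config: SimConfig,
) -> list:
    """Depth-attenuated displacement of the stacked pit cross-sections.

    The surface section (depth index ``m = 0``) carries the full accumulated
    displacement; deeper sections carry ``S_x * exp(-lambda * m)`` — the
    exponential reading of Saint-Venant decay — plus any added-cell length
    from the ``A_L_schedule``.  The profile must be strictly decreasing in
    ``m``; a schedule that breaks monotonicity is a configuration error.
    ``D_L`` is carried as an opaque strictly-increasing depth sequence.
    """
    if config.attenuation_lambda <= 0:
        raise SimConfigError("attenuation_lambda must be positive")
    s0 = S_x.S_x if isinstance(S_x, DisplacementLedger) else float(S_x)
    lam = config.attenuation_lambda
    A = list(config.A_L_schedule) or [0.0] * config.n_cross_sections
    sections = []
    d_cum = 0.0
    for m in range(config.n_cross_sections):
        d_cum += 1.0 + A[m]
        sections.append(
            CrossSectionState(m=m, S_x_m=s0 * math.exp(-lam * m) + A[m], D_L=d_cum)
        )
    if s0 > 0:
        for prev, cur in zip(sections, sections[1:]):
            if not prev.S_x_m > cur.S_x_m:
                raise SimConfigError(
                    "A_L_schedule breaks depth monotonicity: section "
                    f"{cur.m} displaced at least as much as section {prev.m}"
                )
    return sections


@dataclass(frozen=True)
class ClassifierThresholds:
    """Thresholds of the deterministic opening-shape classifier."""

    round_aspect: float = 1.15
    droplet_aspect: float = 1.4
    linear_aspect: float = 8.0
    droplet_asymmetry: float = 0.02

    def __post_init__(self) -> None:
        if not (1.0 <= self.round_aspect <= self.droplet_aspect <= self.linear_aspect):
            raise ValueError("thresholds must be ordered round <= droplet <= linear")


def classify_opening(
    metrics: dict,
    thresholds: ClassifierThresholds | None = None,
    *,
    n_adjacent_linear: int = 0,
) -> str:
    """Classify an opening contour from its shape metrics.

    Deterministic thresholding on aspect ratio and the teardrop asymmetry
    flag.  A single pit can reach at most "linear"; "groove" is the
    composition label used when at least one adjacent pit's opening is also
    linear, so the linear openings merge into a reticular groove on the
    mucosal surface.
    """
    th = thresholds or ClassifierThresholds()
    aspect = metrics["aspect_ratio"]
    asym = metrics.get("asymmetry", 0.0)
    if aspect >= th.linear_aspect:
        return "groove" if n_adjacent_linear >= 1 else "linear"
    if aspect >= th.droplet_aspect and asym >= th.droplet_asymmetry:
        return "droplet"
    if aspect >= th.round_aspect:
        return "oval"
    return "round"


@dataclass
class SimulationResult:
    """Trajectory of one simulated crypt: per-step records and final state.

    ``records`` is a list of per-step dicts with keys
    ``step, F_C_xz, S_x, label, iso_ratio, aspect_ratio, n_emt_events,
    residual``.
    """

    config: SimConfig
    records: list
    ledger: DisplacementLedger
    emt_events: list
    depth_sections: list
    final_contour: Contour
    checkpoint_contours: dict

    @property
    def final_label(self) -> str:
        return self.records[-1]["label"] if self.records else "round"

    def labels(self) -> list:
        return [r["label"] for r in self.records]

    def to_frame(self):
        """Per-step trajectory as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame.from_records(self.records)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Crypt opening simulation",
            "=" * 55,
            f"divisions            {cfg.n_divisions}",
            f"ring size            {cfg.ring_size}",
            f"Euler load F_crit    {cfg.F_crit:.6g}",
            f"delta F / division   {cfg.delta_F:.6g}",
            f"EMT                  {'on' if cfg.emt_enabled else 'off'}"
            f" (band {cfg.emt_tolerance_band:g})",
            f"viscous force F_v    {cfg.F_v:g}",
            "-" * 55,
        ]
        if self.records:
            last = self.records[-1]
            lines += [
                f"final elastic force  {last['F_C_xz']:.6g}",
                f"accumulated S_x      {last['S_x']:.6g}",
                f"EMT events           {len(self.emt_events)}",
                f"final iso ratio      {last['iso_ratio']:.4f}",
                f"final aspect ratio   {last['aspect_ratio']:.4f}",
                f"final opening class  {last['label']}",
            ]
            seen = []
            for lab in self.labels():
                if lab not in seen:
                    seen.append(lab)
            lines.append("label sequence       " + " -> ".join(seen))
        else:
            lines.append("no divisions: opening stays round")
        return "\n".join(lines)


def run(config: SimConfig, *, checkpoint_every: int | None = None) -> SimulationResult:
    """Run a full division trajectory and return the result object.

    Deterministic for a fixed config (the mechanics core has no stochastic
    component; the seed only governs fixture generation elsewhere).
    """
    state = SimState.initial(config)
    records = []
    checkpoints = {}
    if checkpoint_every is None:
        checkpoint_every = max(1, config.n_divisions // 20)
    for _ in range(config.n_divisions):
        step(state)
        m = shape_metrics(state.contour)
        label = classify_opening(m)
        records.append(
            {
                "step": state.step_index,
                "F_C_xz": state.F_C_xz,
                "S_x": state.ledger.S_x,
                "label": label,
                "iso_ratio": m["isoperimetric_ratio"],
                "aspect_ratio": m["aspect_ratio"],
                "n_emt_events": len(state.emt_events),
                "residual": state.residual,
            }
        )
        if state.step_index % checkpoint_every == 0 or state.step_index == config.n_divisions:
            checkpoints[state.step_index] = state.contour
        logger.info(
            "step=%d F_C_xz=%.8g residual=%.3g label=%s",
            state.step_index, state.F_C_xz, state.residual, label,
        )
    sections = depth_profile(state.ledger, config)
    return SimulationResult(
        config=config,
        records=records,
        ledger=state.ledger,
        emt_events=state.emt_events,
        depth_sections=sections,
        final_contour=state.contour,
        checkpoint_contours=checkpoints,
    )


def config_from_mapping(mapping: dict) -> SimConfig:
    """Build a validated SimConfig from a plain key->value mapping."""
    known = {f.name for f in fields(SimConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise SimConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return SimConfig(**mapping)


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    return replace(config, **kwargs)
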