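"""Division-by-division viscoelastic hysteresis ledger.

Each cell division stretches the focal rim cell by the Hooke displacement
``S_n = F/K``; when the load is removed, cytoplasmic viscosity (friction
between macromolecules and water) dissipates part of the stored work, so the
cell recovers only ``S0_n <= S_n`` along the return path.  The energy
balance per event reads, in magnitudes,

    W_n = F * S_n = (F_v + K * S_n) * S0_n

with ``F_v`` a constant viscous resistance, giving

    S0_n = W_n / (F_v + K * S_n).

The unrecovered remainder ``S_n - S0_n`` is permanent creep; summed over
divisions it is the net rim displacement

    S_x = sum_n (S_n - S0_n),

which is zero for a lossless cell (``F_v = 0``) and strictly increasing in
``n`` otherwise — the shape "memory" that turns repeated stretch-recover
cycles into a permanently elongated crypt opening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DivisionEvent",
    "DisplacementLedger",
    "stretch_displacement",
    "recovery_distance",
    "accumulate",
]


def stretch_displacement(F: float, K_spring: float) -> float:
    """Hooke stretch ``S_n = |F| / K`` of the rim cell under the division pull.

    Magnitude convention: the sign in the restoring-force law only marks
    direction.
    """
    if K_spring <= 0:
        raise ValueError("K_spring must be positive")
    return abs(F) / K_spring


def recovery_distance(F: float, K_spring: float, F_v: float) -> float:
    """Actual recovery distance ``S0_n`` along the return path.

    From the energy balance ``W = F*S = (F_v + K*S) * S0`` with
    ``S = |F|/K``.  Lossless cells (``F_v = 0``) recover fully
    (``S0 = S``); any viscosity leaves ``S0 < S``.
    """
    if K_spring <= 0:
        raise ValueError("K_spring must be positive")
    if F_v < 0:
        raise ValueError("F_v must be non-negative")
    S = stretch_displacement(F, K_spring)
    if S == 0.0:
        return 0.0
    if F_v == 0.0:
        # lossless limit: full recovery, exactly
        return S
    W = abs(F) * S
    # min() guards the S0 <= S invariant against rounding at tiny F_v
    return min(W / (F_v + K_spring * S), S)


@dataclass(frozen=True)
class DivisionEvent:
    """One stretch/recovery cycle of the focal rim cell."""

    index: int
    applied_force: float
    S_n: float
    S0_n: float
    W_n: float
    K_spring: float
    F_v: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("event index starts at 1")
        if not (self.S_n >= self.S0_n >= 0.0):
            raise ValueError("events must satisfy S_n >= S0_n >= 0 (incomplete recovery)")
        if self.W_n < 0:
            raise ValueError("work done must be non-negative")

    @property
    def net(self) -> float:
        """Permanent creep left by this division."""
        return self.S_n - self.S0_n

    @property
    def dissipated(self) -> float:
        """Energy lost to viscosity: stored work minus recovered elastic energy."""
        return self.W_n - 0.5 * self.K_spring * self.S0_n**2


@dataclass
class DisplacementLedger:
    """Ordered record of division events and their accumulated creep."""

    events: list = field(default_factory=list)
    K_spring: float = 1.0
    F_v: float = 0.0

    @property
    def S_x(self) -> float:
        """Accumulated net displacement ``sum(S_n - S0_n)``."""
        return sum(e.net for e in self.events)

    @property
    def cumulative(self) -> list:
        """Running S_x after each event (non-decreasing)."""
        out, s = [], 0.0
        for e in self.events:
            s += e.net
            out.append(s)
        return out

    def record(self, F: float, K_spring: float | None = None, F_v: float | None = None) -> DivisionEvent:
        """Append one division with force ``F``; returns the event."""
        K = self.K_spring if K_spring is None else K_spring
        Fv = self.F_v if F_v is None else F_v
        S = stretch_displacement(F, K)
        S0 = recovery_distance(F, K, Fv)
        ev = DivisionEvent(
            index=len(self.events) + 1,
            applied_force=abs(F),
            S_n=S,
            S0_n=S0,
            W_n=abs(F) * S,
            K_spring=K,
            F_v=Fv,
        )
        self.events.append(ev)
        return ev


def accumulate(events) -> DisplacementLedger:
    """Build a ledger from ``(F, K_spring, F_v)`` triples.

    ``n`` identical lossy events accumulate exactly ``n * (S - S0)``; any
    sequence of lossless events accumulates zero.
    """
    ledger = DisplacementLedger()
    for F, K, Fv in events:
        ledger.record(F, K, Fv)
    return ledger
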