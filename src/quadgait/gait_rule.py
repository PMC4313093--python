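"""The tilt-combination rule of gait generation, independent of any simulation.

During trotting the two legs of each diagonal pair are loaded together.  If
the torso is pitched while a pair is in stance, the two legs carry unequal
load; inhibitory load feedback to the flexor half-centers then delays the
swing onset of the more-loaded leg, splitting the pair in a definite
direction:

* ``TILTED_UP``   (nose up, pitch negative): the hindleg carries more load,
  so the hindleg's swing is delayed -- the foreleg swings first.
* ``TILTED_DOWN`` (nose down, pitch positive): the foreleg's swing is
  delayed -- the hindleg swings first.
* ``LEVEL``: equal loads, the pair stays in phase.

Each pair can be in one of the three tilt states while the origins of the two
pairs remain anti-phase, so exactly nine (3^2) gaits exist.  This module
enumerates that rule table, constructs the swing order of each cell from the
mechanism above, and provides the inverse lookup used to validate simulated
gaits.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .legs import Leg, MIRROR, PAIR1, PAIR2

__all__ = [
    "TiltState",
    "GaitLabel",
    "RuleEntry",
    "predict_gait",
    "enumerate_rule_table",
    "expected_tilts_for_gait",
    "swing_phases",
    "swing_orders_cyclically_equal",
    "mirror_gait",
    "format_swing_order",
]


class TiltState(Enum):
    """Torso posture during a diagonal pair's stance (pitch positive = nose down)."""

    TILTED_DOWN = "tilted_down"
    LEVEL = "level"
    TILTED_UP = "tilted_up"


class GaitLabel(Enum):
    L_WALK = "L-walk"            # lateral sequence walk
    D_WALK = "D-walk"            # diagonal sequence walk
    TROT = "trot"
    R_CANTER = "R-canter"        # right-lead canter
    L_CANTER = "L-canter"        # left-lead canter
    RT_GALLOP = "RT-gallop"      # right-lead transverse gallop
    LT_GALLOP = "LT-gallop"      # left-lead transverse gallop
    UNUSUAL_CANTER_R = "unusual-canter-R"
    UNUSUAL_CANTER_L = "unusual-canter-L"
    UNKNOWN = "unknown"


#: Ordinal phase split between the two legs of a tilted pair, in cycles.
#: 0.125 makes a doubly-split gait (a walk) come out evenly four-beat.
_SPLIT = 0.125

#: Phase of each diagonal pair's origin (swing onset); always anti-phase.
_ORIGIN = {PAIR1: 0.0, PAIR2: 0.5}

#: Label of each (tilt of 1st pair, tilt of 2nd pair) cell.
_LABELS: dict[tuple[TiltState, TiltState], GaitLabel] = {
    (TiltState.TILTED_UP, TiltState.TILTED_UP): GaitLabel.L_WALK,
    (TiltState.TILTED_DOWN, TiltState.TILTED_DOWN): GaitLabel.D_WALK,
    (TiltState.LEVEL, TiltState.LEVEL): GaitLabel.TROT,
    (TiltState.TILTED_UP, TiltState.LEVEL): GaitLabel.R_CANTER,
    (TiltState.LEVEL, TiltState.TILTED_UP): GaitLabel.L_CANTER,
    (TiltState.TILTED_UP, TiltState.TILTED_DOWN): GaitLabel.RT_GALLOP,
    (TiltState.TILTED_DOWN, TiltState.TILTED_UP): GaitLabel.LT_GALLOP,
    (TiltState.TILTED_DOWN, TiltState.LEVEL): GaitLabel.UNUSUAL_CANTER_R,
    (TiltState.LEVEL, TiltState.TILTED_DOWN): GaitLabel.UNUSUAL_CANTER_L,
}
_TILTS = {label: tilts for tilts, label in _LABELS.items()}


@dataclass(frozen=True)
class RuleEntry:
    """One cell of the 3x3 rule table.

    ``swing_order`` is an ordered tuple of groups of legs entering the swing
    phase; a group of two is a diagonal pair staying in phase.  The order is
    cyclic; it is canonicalized to start with the group containing LF.
    """

    tilt_pair1: TiltState
    tilt_pair2: TiltState
    swing_order: tuple[tuple[Leg, ...], ...]
    gait: GaitLabel

    def __post_init__(self) -> None:
        flat = [leg for group in self.swing_order for leg in group]
        if sorted(l.value for l in flat) != ["LF", "LH", "RF", "RH"]:
            raise ValueError("swing_order must contain each leg exactly once")
        for group in self.swing_order:
            if len(group) > 2:
                raise ValueError("in-phase groups have at most two legs")
            if len(group) == 2 and set(group) not in ({*PAIR1}, {*PAIR2}):
                raise ValueError("only diagonal pairs may be in phase")


def swing_phases(tilt_pair1: TiltState, tilt_pair2: TiltState) -> dict[Leg, float]:
    """Nominal swing-onset phase of each leg (cycles, mod 1) for a rule cell.

    Pair origins are fixed anti-phase; within a tilted pair the legs are
    split symmetrically about the origin with the more-loaded leg delayed.
    """
    phases: dict[Leg, float] = {}
    for pair, tilt in (((PAIR1), tilt_pair1), ((PAIR2), tilt_pair2)):
        fore, hind = pair
        origin = _ORIGIN[pair]
        if tilt is TiltState.LEVEL:
            phases[fore] = origin % 1.0
            phases[hind] = origin % 1.0
        elif tilt is TiltState.TILTED_UP:
            phases[fore] = (origin - _SPLIT) % 1.0
            phases[hind] = (origin + _SPLIT) % 1.0
        else:  # TILTED_DOWN: foreleg delayed
            phases[fore] = (origin + _SPLIT) % 1.0
            phases[hind] = (origin - _SPLIT) % 1.0
    return phases


def _order_from_phases(phases: dict[Leg, float]) -> tuple[tuple[Leg, ...], ...]:
    groups: dict[float, list[Leg]] = {}
    for leg, phase in phases.items():
        key = round(phase % 1.0, 9)
        groups.setdefault(key, []).append(leg)
    ordered = [
        tuple(sorted(legs, key=lambda l: l.value))
        for _, legs in sorted(groups.items())
    ]
    # canonical rotation: start with the group containing LF
    start = next(i for i, g in enumerate(ordered) if Leg.LF in g)
    return tuple(ordered[start:] + ordered[:start])


def predict_gait(tilt_pair1: TiltState, tilt_pair2: TiltState) -> RuleEntry:
    """Map the tilt states of the two diagonal pairs to the emergent gait."""
    if not isinstance(tilt_pair1, TiltState) or not isinstance(tilt_pair2, TiltState):
        raise TypeError("arguments must be TiltState members")
    order = _order_from_phases(swing_phases(tilt_pair1, tilt_pair2))
    return RuleEntry(tilt_pair1, tilt_pair2, order, _LABELS[(tilt_pair1, tilt_pair2)])


def enumerate_rule_table() -> tuple[RuleEntry, ...]:
    """All nine cells of the rule table, one per tilt-state combination."""
    return tuple(
        predict_gait(t1, t2) for t1 in TiltState for t2 in TiltState
    )


def expected_tilts_for_gait(gait: GaitLabel) -> tuple[TiltState, TiltState]:
    """Inverse label lookup: the (pair1, pair2) tilts that produce ``gait``."""
    if gait is GaitLabel.UNKNOWN:
        raise ValueError("UNKNOWN has no tilt-state cell")
    return _TILTS[gait]


def swing_orders_cyclically_equal(
    a: tuple[tuple[Leg, ...], ...], b: tuple[tuple[Leg, ...], ...]
) -> bool:
    """True if two swing orders are equal up to cyclic rotation of groups."""
    if len(a) != len(b):
        return False
    norm = lambda order: [frozenset(g) for g in order]
    na, nb = norm(a), norm(b)
    return any(na[i:] + na[:i] == nb for i in range(len(na)))


_MIRROR_LABEL = {
    GaitLabel.R_CANTER: GaitLabel.L_CANTER,
    GaitLabel.L_CANTER: GaitLabel.R_CANTER,
    GaitLabel.RT_GALLOP: GaitLabel.LT_GALLOP,
    GaitLabel.LT_GALLOP: GaitLabel.RT_GALLOP,
    GaitLabel.UNUSUAL_CANTER_R: GaitLabel.UNUSUAL_CANTER_L,
    GaitLabel.UNUSUAL_CANTER_L: GaitLabel.UNUSUAL_CANTER_R,
}


def mirror_gait(gait: GaitLabel) -> GaitLabel:
    """Label obtained by exchanging the left and right body sides."""
    return _MIRROR_LABEL.get(gait, gait)


def format_swing_order(order: tuple[tuple[Leg, ...], ...]) -> str:
    parts = []
    for group in order:
        if len(group) == 1:
            parts.append(group[0].value)
        else:
            parts.append("(" + ",".join(l.value for l in group) + ")")
    return "-".join(parts)


def mirror_swing_order(
    order: tuple[tuple[Leg, ...], ...]
) -> tuple[tuple[Leg, ...], ...]:
    mirrored = tuple(
        tuple(sorted((MIRROR[l] for l in group), key=lambda l: l.value))
        for group in order
    )
    start = next(i for i, g in enumerate(mirrored) if Leg.LF in g)
    return mirrored[start:] + mirrored[:start]
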