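"""Leg identifiers and diagonal-pair bookkeeping shared across the package.

Leg naming follows the usual quadruped convention: LF/RF are the left/right
forelegs, LH/RH the left/right hindlegs.  The 1st diagonal pair is RF+LH and
the 2nd is LF+RH; in a trot the two legs of each pair move in phase while the
two pairs move in anti-phase.
"""
from __future__ import annotations

from enum import Enum


class Leg(str, Enum):
    LF = "LF"
    LH = "LH"
    RF = "RF"
    RH = "RH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical leg ordering used for every per-leg array in the package.
LEGS: tuple[Leg, Leg, Leg, Leg] = (Leg.LF, Leg.LH, Leg.RF, Leg.RH)
LEG_INDEX: dict[Leg, int] = {leg: i for i, leg in enumerate(LEGS)}

#: Diagonal pairs: (foreleg, hindleg).
PAIR1: tuple[Leg, Leg] = (Leg.RF, Leg.LH)
PAIR2: tuple[Leg, Leg] = (Leg.LF, Leg.RH)
PAIRS = (PAIR1, PAIR2)

FORELEGS = (Leg.LF, Leg.RF)
HINDLEGS = (Leg.LH, Leg.RH)

#: Left-right mirror map (exchange of the two body sides).
MIRROR: dict[Leg, Leg] = {
    Leg.LF: Leg.RF,
    Leg.RF: Leg.LF,
    Leg.LH: Leg.RH,
    Leg.RH: Leg.LH,
}


def is_foreleg(leg: Leg) -> bool:
    return leg in FORELEGS
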