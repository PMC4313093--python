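"""Matsuoka half-center oscillators and the hard-wired trot-producing network.

Each leg carries one half-center CPG: an extensor and a flexor unit that
inhibit each other (weight ``gamma``).  Corresponding units of the two
contralateral legs inhibit each other with weight ``alpha`` (LF-RF, LH-RH),
and of the two ipsilateral legs with weight ``beta`` (LF-LH, RF-RH).  There
are no connections between diagonal legs.  Because each inhibitory link
favours anti-phase motion, the consistent phase assignment of the network is
the trot: diagonal legs in phase, neighbouring legs in anti-phase.

Dynamics of half-center ``i`` (canonical Matsuoka rate model)::

    tau_u * du_i/dt = -u_i - b*v_i - sum_j W[i,j]*y_j + s0 + feed_i
    tau_v * dv_i/dt = -v_i + y_i
    y_i = max(0, u_i)

``u`` is a membrane-like state, ``v`` a self-adaptation state and ``y`` the
rectified output; ``feed_i`` is an additive sensory input.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .legs import LEGS, LEG_INDEX, Leg

__all__ = [
    "EXTENSOR",
    "FLEXOR",
    "N_HALF_CENTERS",
    "CpgParams",
    "CpgNetworkState",
    "half_center_index",
    "build_coupling",
    "step_network",
    "flexor_output",
    "extensor_output",
    "trot_preset_state",
]

EXTENSOR = 0
FLEXOR = 1
N_HALF_CENTERS = 8


def half_center_index(leg: Leg, side: int) -> int:
    """Flat index of a half-center; legs ordered (LF, LH, RF, RH), extensor first."""
    if side not in (EXTENSOR, FLEXOR):
        raise ValueError(f"side must be EXTENSOR or FLEXOR, got {side!r}")
    return 2 * LEG_INDEX[Leg(leg)] + side


@dataclass(frozen=True)
class CpgParams:
    """Parameters of the oscillators; identical for all four legs.

    Defaults are a tuned oscillatory operating point for this model, stored
    here and in the config files; they are not literature values.
    """

    tau_u: float = 0.05   # membrane time constant (s)
    tau_v: float = 0.6    # adaptation time constant (s)
    b: float = 2.5        # adaptation weight
    s0: float = 1.0       # tonic drive
    alpha: float = 0.2    # contralateral inhibition weight
    beta: float = 0.2     # ipsilateral inhibition weight
    gamma: float = 2.0    # intra-leg flexor<->extensor inhibition weight

    def __post_init__(self) -> None:
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValueError("time constants must be positive")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("coupling weights are inhibitory magnitudes, >= 0")

    def time_scaled(self, factor: float) -> "CpgParams":
        """Both time constants scaled by ``factor`` (changes period only)."""
        if factor <= 0:
            raise ValueError("time scale factor must be positive")
        return replace(self, tau_u=self.tau_u * factor, tau_v=self.tau_v * factor)


@dataclass
class CpgNetworkState:
    """State of the eight half-centers (two per leg)."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != (N_HALF_CENTERS,) or self.v.shape != (N_HALF_CENTERS,):
            raise ValueError(f"state arrays must have shape ({N_HALF_CENTERS},)")

    @property
    def y(self) -> np.ndarray:
        """Rectified outputs, y = max(0, u)."""
        return np.maximum(self.u, 0.0)

    @classmethod
    def zeros(cls) -> "CpgNetworkState":
        return cls(np.zeros(N_HALF_CENTERS), np.zeros(N_HALF_CENTERS))

    def copy(self) -> "CpgNetworkState":
        return CpgNetworkState(self.u.copy(), self.v.copy())


def build_coupling(params: CpgParams) -> np.ndarray:
    """Inhibition-weight matrix W (8x8, non-negative, applied with minus sign).

    W[i, j] is the weight with which unit j's output inhibits unit i.
    Contralateral links carry ``alpha``, ipsilateral links ``beta``, the
    intra-leg flexor/extensor link ``gamma``; diagonal legs are unconnected.
    """
    W = np.zeros((N_HALF_CENTERS, N_HALF_CENTERS))
    pairs_alpha = ((Leg.LF, Leg.RF), (Leg.LH, Leg.RH))
    pairs_beta = ((Leg.LF, Leg.LH), (Leg.RF, Leg.RH))
    for a, b_ in pairs_alpha:
        for side in (EXTENSOR, FLEXOR):
            i, j = half_center_index(a, side), half_center_index(b_, side)
            W[i, j] = W[j, i] = params.alpha
    for a, b_ in pairs_beta:
        for side in (EXTENSOR, FLEXOR):
            i, j = half_center_index(a, side), half_center_index(b_, side)
            W[i, j] = W[j, i] = params.beta
    for leg in LEGS:
        i = half_center_index(leg, EXTENSOR)
        j = half_center_index(leg, FLEXOR)
        W[i, j] = W[j, i] = params.gamma
    return W


def _rates(
    u: np.ndarray,
    v: np.ndarray,
    W: np.ndarray,
    tau_u: float,
    tau_v: float,
    b: float,
    s0: float,
    feeds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    y = np.maximum(u, 0.0)
    du = (-u - b * v - W @ y + s0 + feeds) / tau_u
    dv = (-v + y) / tau_v
    return du, dv


def _rk4_arrays(
    u: np.ndarray,
    v: np.ndarray,
    W: np.ndarray,
    tau_u: float,
    tau_v: float,
    b: float,
    s0: float,
    feeds: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One fixed-step RK4 step on the raw state arrays (fast path)."""
    du1, dv1 = _rates(u, v, W, tau_u, tau_v, b, s0, feeds)
    du2, dv2 = _rates(u + 0.5 * dt * du1, v + 0.5 * dt * dv1, W, tau_u, tau_v, b, s0, feeds)
    du3, dv3 = _rates(u + 0.5 * dt * du2, v + 0.5 * dt * dv2, W, tau_u, tau_v, b, s0, feeds)
    du4, dv4 = _rates(u + dt * du3, v + dt * dv3, W, tau_u, tau_v, b, s0, feeds)
    un = u + (dt / 6.0) * (du1 + 2.0 * du2 + 2.0 * du3 + du4)
    vn = v + (dt / 6.0) * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
    return un, vn


def step_network(
    state: CpgNetworkState,
    params: CpgParams,
    feeds: np.ndarray | Iterable[float] | None,
    dt: float,
    *,
    W: np.ndarray | None = None,
    method: str = "rk4",
) -> CpgNetworkState:
    """Advance the eight half-centers one step of size ``dt``.

    ``feeds`` is the per-half-center additive input (length 8); ``W`` may be
    supplied to avoid rebuilding the coupling matrix in tight loops.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.tau_u / 10.0 + 1e-12:
        raise ValueError(
            f"dt={dt} too large for tau_u={params.tau_u}; require dt <= tau_u/10"
        )
    feeds_arr = (
        np.zeros(N_HALF_CENTERS) if feeds is None else np.asarray(feeds, dtype=float)
    )
    if feeds_arr.shape != (N_HALF_CENTERS,):
        raise ValueError(f"feeds must have shape ({N_HALF_CENTERS},)")
    if not (np.all(np.isfinite(state.u)) and np.all(np.isfinite(state.v))
            and np.all(np.isfinite(feeds_arr))):
        raise FloatingPointError("non-finite CPG state or input")
    if W is None:
        W = build_coupling(params)
    if method == "rk4":
        un, vn = _rk4_arrays(
            state.u, state.v, W, params.tau_u, params.tau_v, params.b, params.s0,
            feeds_arr, dt,
        )
    elif method == "euler":
        du, dv = _rates(
            state.u, state.v, W, params.tau_u, params.tau_v, params.b, params.s0,
            feeds_arr,
        )
        un, vn = state.u + dt * du, state.v + dt * dv
    else:
        raise ValueError(f"unknown method {method!r}")
    if not (np.all(np.isfinite(un)) and np.all(np.isfinite(vn))):
        raise FloatingPointError("CPG state became non-finite")
    return CpgNetworkState(un, vn)


def flexor_output(state: CpgNetworkState, leg: Leg) -> float:
    """Rectified flexor output y_f of one leg (drives the swing phase)."""
    return float(max(state.u[half_center_index(Leg(leg), FLEXOR)], 0.0))


def extensor_output(state: CpgNetworkState, leg: Leg) -> float:
    return float(max(state.u[half_center_index(Leg(leg), EXTENSOR)], 0.0))


def trot_preset_state(
    seed: int | None = None, noise: float = 0.05, amplitude: float = 0.5
) -> CpgNetworkState:
    """Initial state biased toward the trot pattern, with seeded jitter.

    The 2nd diagonal pair (LF, RH) starts flexor-high, the 1st pair (RF, LH)
    extensor-high; small noise breaks the exact symmetry so that bistable
    outcomes (e.g. canter lead) depend on the seed.
    """
    u = np.zeros(N_HALF_CENTERS)
    for leg in (Leg.LF, Leg.RH):
        u[half_center_index(leg, FLEXOR)] = amplitude
        u[half_center_index(leg, EXTENSOR)] = -amplitude
    for leg in (Leg.RF, Leg.LH):
        u[half_center_index(leg, FLEXOR)] = -amplitude
        u[half_center_index(leg, EXTENSOR)] = amplitude
    if noise > 0:
        rng = np.random.default_rng(seed)
        u = u + rng.normal(0.0, noise, N_HALF_CENTERS)
    return CpgNetworkState(u, np.zeros(N_HALF_CENTERS))
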