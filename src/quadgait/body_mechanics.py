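"""Planar (sagittal) rigid-torso quadruped with prismatic spring legs.

The torso is a rigid body with three degrees of freedom (x forward, z up,
pitch -- positive nose-down, matching the sign convention used throughout
the package).  Each of the four legs adds a rotary hip angle ``theta``
(relative to the torso, positive with the foot forward of the hip) and a
prismatic leg length ``l``, for 11 generalized coordinates in total.  Leg
segment masses (upper, lower, foot) are lumped as point masses on the leg
line; the foot is a point that interacts with flat ground through a
penalty-type normal spring-damper and Coulomb-capped viscous friction.

Equations of motion are assembled from point-mass Jacobians::

    M(q) qdd = Q_applied(q, qd) - sum_k m_k J_k^T a_bias,k

where ``a_bias,k`` is the acceleration of point ``k`` at qdd = 0.  The hip
torque acts directly on the relative coordinate ``theta`` and the knee force
on ``l``, so joint reactions need no special handling.  Integration is
fixed-step RK4 with contact forces re-evaluated at every stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .legs import LEGS, LEG_INDEX, Leg

__all__ = [
    "MechParams",
    "PlanarBodyState",
    "ModelDescription",
    "ContactEvent",
    "assemble_model",
    "contact_force",
    "step_dynamics",
    "leg_load",
    "standing_state",
]

# generalized-coordinate layout
IX, IZ, IP = 0, 1, 2
ITH = slice(3, 7)   # hip angles, leg order (LF, LH, RF, RH)
IL = slice(7, 11)   # leg lengths
NQ = 11


@dataclass(frozen=True)
class MechParams:
    """Masses, geometry, spring and contact parameters.

    Printed segment masses (4.0 + 4*(0.5 + 0.2 + 0.05) = 7.0 kg total) are
    the defaults.  Segment lengths, torso inertia and the contact model are
    not printed anywhere and are tuned values documented in docs/methods.md.
    """

    m_torso: float = 4.0
    m_upper: float = 0.5      # per leg
    m_lower: float = 0.2      # per leg
    m_foot: float = 0.05      # per leg
    torso_length: float = 0.50          # hip-to-hip distance (m)
    pitch_inertia: float = 0.12         # torso pitch inertia (kg m^2)
    hip_drop: float = 0.0               # hip line below torso COM (m, >= 0)
    upper_mass_offset: float = 0.08     # upper-leg mass, distance from hip (m)
    lower_mass_offset: float = 0.06     # lower-leg mass, distance from foot (m)
    leg_natural_length: float = 0.25    # natural stance length l_d.st (m)
    l_min: float = 0.10
    l_max: float = 0.35
    stop_stiffness: float = 2.0e4       # prismatic travel stops (N/m)
    stop_damping: float = 200.0
    gravity: float = 9.81
    k_contact: float = 3.0e4            # ground normal stiffness (N/m)
    c_contact: float = 300.0            # ground normal damping (N s/m)
    mu: float = 1.2                     # Coulomb friction coefficient
    k_slip: float = 4000.0              # tangential viscous coeff. below the cap

    def __post_init__(self) -> None:
        for name in ("m_torso", "m_upper", "m_lower", "m_foot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("torso_length", "pitch_inertia", "leg_natural_length",
                     "l_min", "l_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.l_min < self.leg_natural_length < self.l_max:
            raise ValueError("need l_min < leg_natural_length < l_max")

    @property
    def total_mass(self) -> float:
        return self.m_torso + 4.0 * (self.m_upper + self.m_lower + self.m_foot)

    @property
    def leg_mass(self) -> float:
        return self.m_upper + self.m_lower + self.m_foot

    def hip_offsets_x(self) -> np.ndarray:
        """Body-frame x of each hip, leg order (LF, LH, RF, RH)."""
        a = 0.5 * self.torso_length
        return np.array([a, -a, a, -a])


@dataclass(frozen=True)
class ModelDescription:
    """Validated summary of an assembled model."""

    params: MechParams
    total_mass: float
    n_joints: int
    standing_height: float

    @property
    def weight(self) -> float:
        return self.total_mass * self.params.gravity


@dataclass(frozen=True)
class ContactEvent:
    """One stance interval of one leg."""

    leg: Leg
    touchdown: float
    liftoff: float

    def __post_init__(self) -> None:
        if not self.liftoff > self.touchdown:
            raise ValueError("liftoff must follow touchdown")


def assemble_model(params: MechParams) -> ModelDescription:
    """Validate parameters and return the model summary (mass, joints)."""
    # 4 rotary hips + 4 prismatic knees
    return ModelDescription(
        params=params,
        total_mass=params.total_mass,
        n_joints=8,
        standing_height=params.leg_natural_length + params.hip_drop,
    )


@dataclass
class PlanarBodyState:
    """Full mechanical state: q = (x, z, pitch, theta[4], l[4]) and rates.

    ``loads`` (N) and ``contacts`` are the most recent ground-reaction
    normal-force magnitudes / contact flags per leg, refreshed by
    :func:`step_dynamics`; a swing leg always has zero load.
    """

    q: np.ndarray
    qd: np.ndarray
    t: float = 0.0
    loads: np.ndarray = field(default_factory=lambda: np.zeros(4))
    contacts: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=bool))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        if self.q.shape != (NQ,) or self.qd.shape != (NQ,):
            raise ValueError(f"q and qd must have shape ({NQ},)")

    # torso pose
    @property
    def x(self) -> float:
        return float(self.q[IX])

    @property
    def z(self) -> float:
        return float(self.q[IZ])

    @property
    def pitch(self) -> float:
        """Pitch angle (rad), positive while tilting (nose) down."""
        return float(self.q[IP])

    @property
    def vx(self) -> float:
        return float(self.qd[IX])

    @property
    def hip_angles(self) -> np.ndarray:
        return self.q[ITH]

    @property
    def hip_rates(self) -> np.ndarray:
        return self.qd[ITH]

    @property
    def leg_lengths(self) -> np.ndarray:
        return self.q[IL]

    @property
    def length_rates(self) -> np.ndarray:
        return self.qd[IL]

    def copy(self) -> "PlanarBodyState":
        return PlanarBodyState(
            self.q.copy(), self.qd.copy(), self.t, self.loads.copy(),
            self.contacts.copy(),
        )

    def foot_positions(self, params: MechParams) -> np.ndarray:
        """World (x, z) of the four feet, shape (4, 2)."""
        return _foot_positions(self.q, params)


def _foot_positions(q: np.ndarray, params: MechParams) -> np.ndarray:
    p = q[IP]
    cp, sp = np.cos(p), np.sin(p)
    ax = params.hip_offsets_x()
    b = -params.hip_drop
    hip = np.stack(
        [q[IX] + ax * cp + b * sp, q[IZ] - ax * sp + b * cp], axis=-1
    )
    chi = q[ITH] - p
    u = np.stack([np.sin(chi), -np.cos(chi)], axis=-1)
    return hip + q[IL][:, None] * u


def contact_force(
    foot_height: float,
    foot_velocity: Sequence[float],
    params: MechParams,
) -> tuple[float, float]:
    """Ground reaction (normal, tangential) force on a single foot.

    Normal: penalty spring-damper ``max(0, k*d - c*vz)`` on penetration
    depth ``d = -foot_height``; zero out of contact.  Tangential: viscous
    drag ``-k_slip*vx`` clipped to the Coulomb cone ``mu * normal``.
    """
    vx, vz = float(foot_velocity[0]), float(foot_velocity[1])
    if not (np.isfinite(foot_height) and np.isfinite(vx) and np.isfinite(vz)):
        raise ValueError("non-finite contact input")
    d = -float(foot_height)
    if d <= 0.0:
        return 0.0, 0.0
    fn = params.k_contact * d - params.c_contact * vz
    if fn <= 0.0:
        return 0.0, 0.0
    cap = params.mu * fn
    ft = float(np.clip(-params.k_slip * vx, -cap, cap))
    return fn, ft


def _dynamics(
    q: np.ndarray,
    qd: np.ndarray,
    hip_torques: np.ndarray,
    knee_forces: np.ndarray,
    params: MechParams,
    external_wrench: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generalized accelerations plus per-leg (normal load, contact flag)."""
    p = q[IP]
    pd_ = qd[IP]
    th = q[ITH]
    thd = qd[ITH]
    l = q[IL]
    ld = qd[IL]
    cp, sp = np.cos(p), np.sin(p)
    ax = params.hip_offsets_x()
    b = -params.hip_drop

    hip_off = np.stack([ax * cp + b * sp, -ax * sp + b * cp], axis=-1)  # (4,2)
    dhip_dp = np.stack([-ax * sp + b * cp, -ax * cp - b * sp], axis=-1)
    chi = th - p
    schi, cchi = np.sin(chi), np.cos(chi)
    u = np.stack([schi, -cchi], axis=-1)        # along leg, hip -> foot
    uperp = np.stack([cchi, schi], axis=-1)

    # point-mass arms along the leg: upper (fixed), lower (l - c), foot (l)
    m_pts = np.array([params.m_upper, params.m_lower, params.m_foot])
    S = np.stack(
        [np.full(4, params.upper_mass_offset), l - params.lower_mass_offset, l],
        axis=0,
    )  # (3, 4)
    sig = np.array([0.0, 1.0, 1.0])  # dS/dl per point type

    # Jacobian columns (w.r.t. p, theta_i, l_i) for each point: (3, 4, 2, 3)
    su = S[..., None] * uperp[None, :, :]       # (3,4,2)
    C = np.empty((3, 4, 2, 3))
    C[..., 0] = dhip_dp[None, :, :] - su
    C[..., 1] = su
    C[..., 2] = sig[:, None, None] * u[None, :, :]

    mC = m_pts[:, None, None, None] * C
    sum_mC = mC.sum(axis=0)                     # (4, 2, 3)
    sum_mCtC = np.einsum("jiak,jial->ikl", mC, C)  # (4, 3, 3)

    M = np.zeros((NQ, NQ))
    m_total = params.m_torso + 4.0 * params.leg_mass
    M[IX, IX] = m_total
    M[IZ, IZ] = m_total
    M[IP, IP] = params.pitch_inertia

    # bias accelerations of leg points (qdd = 0)
    chid = thd - pd_
    a_bias = (
        -hip_off[None, :, :] * pd_ ** 2
        + 2.0 * (sig[:, None] * ld[None, :] * chid[None, :])[..., None] * uperp[None, :, :]
        - (S * chid[None, :] ** 2)[..., None] * u[None, :, :]
    )  # (3, 4, 2)

    Q = np.zeros(NQ)
    g = params.gravity
    # gravity: torso + all leg points on z; leg-point lever terms via C
    Q[IZ] -= m_total * g
    # per leg, generalized gravity force on (p, theta, l): -g * sum_j m_j C_z
    grav_leg = -g * mC[:, :, 1, :].sum(axis=0)  # (4,3)

    # bias generalized force: sum_k m_k J_k^T a_k
    bias_xz = (m_pts[:, None, None] * a_bias).sum(axis=(0, 1))  # (2,)
    bias_leg = np.einsum("jiak,jia->ik", mC, a_bias)            # (4,3)

    Q[IX] -= bias_xz[0]
    Q[IZ] -= bias_xz[1]

    # ground contact at the feet
    foot = hip_off + np.array([q[IX], q[IZ]]) + l[:, None] * u
    foot_v = (
        np.array([qd[IX], qd[IZ]])[None, :]
        + dhip_dp * pd_
        + ld[:, None] * u
        + (l * chid)[:, None] * uperp
    )
    loads = np.zeros(4)
    contacts = np.zeros(4, dtype=bool)
    F_feet = np.zeros((4, 2))
    for i in range(4):
        if foot[i, 1] < 0.0:
            fn, ft = contact_force(foot[i, 1], foot_v[i], params)
            if fn > 0.0:
                loads[i] = fn
                contacts[i] = True
                F_feet[i] = (ft, fn)

    # prismatic travel stops (keep l within [l_min, l_max])
    f_stop = np.zeros(4)
    below = l < params.l_min
    above = l > params.l_max
    f_stop[below] = params.stop_stiffness * (params.l_min - l[below]) \
        - params.stop_damping * ld[below]
    f_stop[above] = params.stop_stiffness * (params.l_max - l[above]) \
        - params.stop_damping * ld[above]

    Q[IX] += F_feet[:, 0].sum()
    Q[IZ] += F_feet[:, 1].sum()

    for i in range(4):
        idx = [IP, 3 + i, 7 + i]
        blk = sum_mCtC[i]
        M[np.ix_(idx, idx)] += blk
        M[IX, idx] += sum_mC[i, 0, :]
        M[idx, IX] += sum_mC[i, 0, :]
        M[IZ, idx] += sum_mC[i, 1, :]
        M[idx, IZ] += sum_mC[i, 1, :]
        Q[idx] += grav_leg[i] - bias_leg[i]
        # foot contact through the foot-point Jacobian columns C[2, i]
        Q[idx] += C[2, i].T @ F_feet[i]
        Q[3 + i] += hip_torques[i]
        Q[7 + i] += knee_forces[i] + f_stop[i]

    if external_wrench is not None:
        Q[IX] += external_wrench[0]
        Q[IZ] += external_wrench[1]
        Q[IP] += external_wrench[2]
    qdd = np.linalg.solve(M, Q)
    return qdd, loads, contacts


def _rk4_step_arrays(
    q: np.ndarray,
    qd: np.ndarray,
    tau: np.ndarray,
    fk: np.ndarray,
    params: MechParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """RK4 step on raw arrays; loads/contacts taken from the last stage."""
    k1v, _, _ = _dynamics(q, qd, tau, fk, params)
    k1q = qd
    q2, qd2 = q + 0.5 * dt * k1q, qd + 0.5 * dt * k1v
    k2v, _, _ = _dynamics(q2, qd2, tau, fk, params)
    k2q = qd2
    q3, qd3 = q + 0.5 * dt * k2q, qd + 0.5 * dt * k2v
    k3v, _, _ = _dynamics(q3, qd3, tau, fk, params)
    k3q = qd3
    q4, qd4 = q + dt * k3q, qd + dt * k3v
    k4v, loads, contacts = _dynamics(q4, qd4, tau, fk, params)
    k4q = qd4
    qn = q + (dt / 6.0) * (k1q + 2 * k2q + 2 * k3q + k4q)
    qdn = qd + (dt / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
    if not (np.all(np.isfinite(qn)) and np.all(np.isfinite(qdn))):
        raise FloatingPointError("dynamics diverged (non-finite state)")
    return qn, qdn, loads, contacts


def step_dynamics(
    state: PlanarBodyState,
    hip_torques: Sequence[float],
    knee_forces: Sequence[float],
    params: MechParams,
    dt: float,
    external_wrench: Sequence[float] | None = None,
) -> PlanarBodyState:
    """Advance the mechanics one RK4 step with zero-order-hold actuation.

    Contact forces are state-dependent and re-evaluated at each RK4 stage;
    the commanded hip torques and knee forces are held constant over the
    step.  Raises ``FloatingPointError`` if the state blows up.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = np.asarray(hip_torques, dtype=float)
    fk = np.asarray(knee_forces, dtype=float)
    if tau.shape != (4,) or fk.shape != (4,):
        raise ValueError("hip_torques and knee_forces must have length 4")
    if not (np.all(np.isfinite(tau)) and np.all(np.isfinite(fk))):
        raise FloatingPointError("non-finite actuation")
    q, qd = state.q, state.qd
    wrench = None if external_wrench is None else np.asarray(external_wrench, float)

    def f(q_, qd_):
        qdd, loads, contacts = _dynamics(q_, qd_, tau, fk, params, wrench)
        return qd_, qdd, loads, contacts

    k1q, k1v, _, _ = f(q, qd)
    k2q, k2v, _, _ = f(q + 0.5 * dt * k1q, qd + 0.5 * dt * k1v)
    k3q, k3v, _, _ = f(q + 0.5 * dt * k2q, qd + 0.5 * dt * k2v)
    k4q, k4v, _, _ = f(q + dt * k3q, qd + dt * k3v)
    qn = q + (dt / 6.0) * (k1q + 2 * k2q + 2 * k3q + k4q)
    qdn = qd + (dt / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
    if not (np.all(np.isfinite(qn)) and np.all(np.isfinite(qdn))):
        raise FloatingPointError("dynamics diverged (non-finite state)")
    # refresh the load/contact cache at the new state
    _, loads, contacts = _dynamics(qn, qdn, tau, fk, params, wrench)
    return PlanarBodyState(qn, qdn, state.t + dt, loads, contacts)


def leg_load(state: PlanarBodyState, leg: Leg) -> float:
    """Ground-reaction normal force (N) on one leg; 0 in swing or flight."""
    return float(state.loads[LEG_INDEX[Leg(leg)]])


def standing_state(
    params: MechParams,
    hip_angle: float = 0.0,
    forward_speed: float = 0.0,
    settle_fraction: float = 0.25,
) -> PlanarBodyState:
    """A static four-leg standing pose with feet on the ground.

    ``settle_fraction`` pre-loads the contact springs with that fraction of
    the weight-per-leg penetration, reducing the initial drop transient.
    """
    l0 = params.leg_natural_length
    pen = settle_fraction * params.total_mass * params.gravity / (
        4.0 * params.k_contact
    )
    z0 = params.hip_drop + l0 * np.cos(hip_angle) - pen
    q = np.zeros(NQ)
    q[IZ] = z0
    q[ITH] = hip_angle
    q[IL] = l0
    qd = np.zeros(NQ)
    qd[IX] = forward_speed
    return PlanarBodyState(q, qd)


def mechanical_energy(
    state: PlanarBodyState,
    params: MechParams,
    knee_stiffness: float | None = None,
) -> float:
    """Total mechanical energy (J): kinetic + gravity + contact spring
    (+ optionally a linear knee spring about the natural length).

    Useful for integrator-accuracy checks on passive motions.
    """
    q, qd = state.q, state.qd
    p = q[IP]
    cp, sp = np.cos(p), np.sin(p)
    ax = params.hip_offsets_x()
    b = -params.hip_drop
    hip = np.stack([q[IX] + ax * cp + b * sp, q[IZ] - ax * sp + b * cp], axis=-1)
    dhip_dp = np.stack([-ax * sp + b * cp, -ax * cp - b * sp], axis=-1)
    chi = q[ITH] - p
    u = np.stack([np.sin(chi), -np.cos(chi)], axis=-1)
    uperp = np.stack([np.cos(chi), np.sin(chi)], axis=-1)
    chid = qd[ITH] - qd[IP]
    m_pts = np.array([params.m_upper, params.m_lower, params.m_foot])
    S = np.stack(
        [np.full(4, params.upper_mass_offset), q[IL] - params.lower_mass_offset,
         q[IL]], axis=0,
    )
    sig = np.array([0.0, 1.0, 1.0])
    vxy = np.array([qd[IX], qd[IZ]])
    ke = 0.5 * params.m_torso * (vxy @ vxy) + 0.5 * params.pitch_inertia * qd[IP] ** 2
    pe = params.m_torso * params.gravity * q[IZ]
    for j in range(3):
        for i in range(4):
            pos = hip[i] + S[j, i] * u[i]
            vel = (
                vxy + dhip_dp[i] * qd[IP]
                + sig[j] * qd[IL][i] * u[i]
                + S[j, i] * chid[i] * uperp[i]
            )
            ke += 0.5 * m_pts[j] * (vel @ vel)
            pe += m_pts[j] * params.gravity * pos[1]
    foot = _foot_positions(q, params)
    pen = np.clip(-foot[:, 1], 0.0, None)
    pe += 0.5 * params.k_contact * (pen ** 2).sum()
    below = np.clip(params.l_min - q[IL], 0.0, None)
    above = np.clip(q[IL] - params.l_max, 0.0, None)
    pe += 0.5 * params.stop_stiffness * ((below ** 2) + (above ** 2)).sum()
    if knee_stiffness is not None:
        dl = params.leg_natural_length - q[IL]
        pe += 0.5 * knee_stiffness * (dl ** 2).sum()
    return float(ke + pe)
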