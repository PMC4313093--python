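"""Leg phase generation, PD motion control and the two afferent feedbacks.

A leg is in the swing phase while its flexor half-center is excited
(y_f > 0) and in the stance phase otherwise.  Each phase has a target hip
angle and a target leg length, tracked by a PD controller; with the stance
length held at its natural value the prismatic knee behaves as a virtual
spring, so each stance leg is effectively a spring-loaded inverted pendulum.

Two afferent signals close the loop back to the CPGs:

* hip-angle feedback (gain ``k1``): the hip angle relative to mid-stroke is
  injected antisymmetrically, +k1*(theta - theta_mid) to the extensor and
  -k1*(theta - theta_mid) to the flexor.  The extensor is excited as the hip
  swings forward past mid-stroke (promoting touchdown) and the flexor as it
  is swept backward (promoting liftoff); this keeps the CPG rhythm entrained
  to the mechanical stepping.
* leg-loading feedback (gain ``k2 >= 0``): ``-k2 * Leg_load`` injected into
  the flexor half-center only, delaying the stance-to-swing transition while
  the leg is loaded.  ``k2 = 0`` is the baseline model without load feedback.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .cpg_network import CpgParams

__all__ = [
    "PhaseLabel",
    "PdGains",
    "ControlParams",
    "SpeedParams",
    "leg_phase",
    "setpoints",
    "pd_command",
    "hip_feedback",
    "load_feedback",
]


class PhaseLabel(Enum):
    SWING = "swing"
    STANCE = "stance"


@dataclass(frozen=True)
class PdGains:
    kp: float
    kd: float

    def __post_init__(self) -> None:
        if self.kp < 0 or self.kd < 0:
            raise ValueError("PD gains must be non-negative")


@dataclass(frozen=True)
class ControlParams:
    """Per-leg control parameters; identical across the four legs.

    Angles in rad (hip angle positive with the foot forward of the hip),
    lengths in m.  ``l_d_sw < l_d_st``: the leg is retracted in swing to
    avoid tripping and extended to its natural length in stance.
    """

    k1: float = 2.0            # hip-angle feedback gain (1/rad)
    k2: float = 0.0            # load feedback gain (1/N); 0 = baseline model
    feed2_cap: float = float("inf")  # saturation of |k2 * load| (dimensionless)
    theta_d_sw: float = 0.20   # swing target hip angle (rad, forward)
    theta_d_st: float = -0.20  # stance target hip angle (rad, backward)
    l_d_sw: float = 0.18       # swing target leg length (m)
    l_d_st: float = 0.25       # stance target (= natural spring) length (m)
    hip_gains_sw: PdGains = PdGains(30.0, 1.5)
    hip_gains_st: PdGains = PdGains(60.0, 4.0)
    len_gains_sw: PdGains = PdGains(600.0, 30.0)
    len_gains_st: PdGains = PdGains(3000.0, 60.0)

    def __post_init__(self) -> None:
        if self.k2 < 0:
            raise ValueError("k2 must be >= 0")
        if not self.l_d_sw < self.l_d_st:
            raise ValueError("require l_d_sw < l_d_st (swing leg retracted)")

    @property
    def theta_mid(self) -> float:
        """Mid-stroke hip angle, the zero of the hip feedback."""
        return 0.5 * (self.theta_d_sw + self.theta_d_st)


def leg_phase(y_f: float) -> PhaseLabel:
    """SWING while the flexor half-center is excited (y_f > 0), else STANCE."""
    if y_f < 0:
        raise ValueError("rectified flexor output cannot be negative")
    return PhaseLabel.SWING if y_f > 0 else PhaseLabel.STANCE


def setpoints(phase: PhaseLabel, params: ControlParams) -> tuple[float, float]:
    """Target (hip angle, leg length) for the given phase."""
    if phase is PhaseLabel.SWING:
        return params.theta_d_sw, params.l_d_sw
    if phase is PhaseLabel.STANCE:
        return params.theta_d_st, params.l_d_st
    raise TypeError(f"not a PhaseLabel: {phase!r}")


def pd_command(target: float, actual: float, rate: float, gains: PdGains) -> float:
    """Kp*(target - actual) - Kd*rate; used for both hip torque and knee force."""
    if not (math.isfinite(target) and math.isfinite(actual) and math.isfinite(rate)):
        raise ValueError("non-finite PD input")
    return gains.kp * (target - actual) - gains.kd * rate


def hip_feedback(
    k1: float, hip_angle: float, theta_mid: float = 0.0
) -> tuple[float, float]:
    """Additive CPG inputs (extensor, flexor) from the hip angle."""
    if not math.isfinite(hip_angle):
        raise ValueError("non-finite hip angle")
    e = k1 * (hip_angle - theta_mid)
    return e, -e


def load_feedback(k2: float, leg_load: float) -> float:
    """Additive input to the flexor half-center: -k2 * Leg_load (inhibitory)."""
    if leg_load < 0:
        raise ValueError("leg load must be >= 0")
    if k2 < 0:
        raise ValueError("k2 must be >= 0")
    return -k2 * leg_load


@dataclass(frozen=True)
class SpeedParams:
    """Map from a scalar speed command (m/s) to the per-leg speed parameters.

    Speed is set by (i) the half-amplitude of the hip-angle sweep, affine in
    the command, (ii) the tonic drive s0, affine in the command, and (iii) a
    time-scale factor on the oscillator time constants, affine in the command
    and clamped, which shortens the cycle at speed.  The map never touches
    the coupling weights (alpha, beta, gamma) or the feedback gains (k1, k2),
    so adjusting speed cannot change the interlimb wiring.
    """

    theta_amp0: float = 0.135    # hip half-amplitude at v = 0 (rad)
    theta_amp_slope: float = 0.07  # d(half-amplitude)/dv (rad per m/s)
    theta_mid: float = 0.0       # centre of the hip sweep (rad)
    s0_0: float = 1.0            # tonic drive at v = 0
    s0_slope: float = 0.0        # d(s0)/dv
    time_scale0: float = 1.15    # tau scale factor at v = 0
    time_scale_slope: float = -0.154  # d(scale)/dv
    time_scale_min: float = 0.45
    time_scale_max: float = 1.6
    rate_limited_sweep: bool = True  # sweep the stance target at the matched rate
    sweep_gain: float = 1.1      # stance sweep rate = gain(v) * v / l_stance
    sweep_gain_slope: float = 0.35  # d(gain)/dv (compensates contact losses)
    sweep_rate_min: float = 0.6  # floor on the stance sweep rate (rad/s)
    sweep_rate_max: float = 8.0  # cap on the stance sweep rate (rad/s)
    push_gain: float = 0.0       # extra stance-length target per m/s (push-off)
    push_max: float = 0.06       # cap on the extra extension (m)
    drive_asym0: float = 0.25    # extensor-vs-flexor drive asymmetry at v = 0
    drive_asym_slope: float = -0.10  # d(asymmetry)/dv (asymmetry clipped to [0, 0.5])

    def theta_targets(self, v: float) -> tuple[float, float]:
        """(theta_d_sw, theta_d_st) at speed command ``v``."""
        amp = max(0.0, self.theta_amp0 + self.theta_amp_slope * v)
        return self.theta_mid + amp, self.theta_mid - amp

    def stance_sweep_rate(self, v: float, l_stance: float) -> float:
        """Backward hip-sweep rate (rad/s) matching the speed command.

        A foot anchored on the ground while the hip sweeps backward at
        ``v / l`` carries the body forward at ``v``; the gain slightly
        overdrives to compensate contact creep.
        """
        gain = self.sweep_gain + self.sweep_gain_slope * v
        rate = gain * v / l_stance
        return min(max(self.sweep_rate_min, rate), self.sweep_rate_max)

    def time_scale(self, v: float) -> float:
        ts = self.time_scale0 + self.time_scale_slope * v
        return min(max(ts, self.time_scale_min), self.time_scale_max)

    def s0(self, v: float) -> float:
        return max(0.0, self.s0_0 + self.s0_slope * v)

    def stance_length_target(self, v: float, l_d_st: float) -> float:
        """Stance-length target with speed-dependent push-off preload."""
        return l_d_st + min(self.push_max, self.push_gain * v)

    def drive_asymmetry(self, v: float) -> float:
        """Relative tonic-drive surplus of the extensor half-centers.

        A positive asymmetry lengthens the extensor burst relative to the
        flexor burst, raising the duty factor; tapering it off with speed
        keeps the swing duration roughly speed-invariant, as in animals.
        """
        return float(np.clip(self.drive_asym0 + self.drive_asym_slope * v, 0.0, 0.5))

    def control_for_speed(self, v: float, base: ControlParams) -> ControlParams:
        """Control parameters with the speed-dependent targets substituted.

        Gains k1/k2 and the PD gains are taken from ``base`` unchanged.
        """
        th_sw, th_st = self.theta_targets(v)
        return replace(base, theta_d_sw=th_sw, theta_d_st=th_st)

    def cpg_for_speed(self, v: float, base: CpgParams) -> CpgParams:
        """CPG parameters at speed ``v``: s0 and time constants adjusted only.

        Coupling weights alpha/beta/gamma are passed through untouched.
        """
        scaled = base.time_scaled(self.time_scale(v))
        return replace(scaled, s0=self.s0(v))
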