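"""Closed-loop neuromechanical simulation engine.

Couples the trot-wired CPG network, the per-leg phase/PD controller with
its two afferent feedbacks, and the planar mechanics.  Per control step
(one mechanics step, default 1 ms):

1. read hip angles and leg loads from the mechanics,
2. form the CPG feeds: hip-angle feedback to both half-centers and
   ``-k2 * Leg_load`` to the flexor,
3. advance the CPG network,
4. derive each leg's phase (swing while y_f > 0) and PD commands toward
   the phase's speed-dependent setpoints,
5. advance the mechanics with those hip torques and knee forces.

The interlimb wiring (alpha, beta, gamma) and the feedback gains (k1, k2)
are never touched by the speed command; only the hip-sweep amplitude, the
tonic drive and the oscillator time scale follow it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import body_mechanics as bm
from . import cpg_network as cpg
from .leg_control import ControlParams, SpeedParams
from .legs import LEGS

__all__ = ["SimulationSettings", "FallError", "Simulator", "TRACE_COLUMNS"]


class FallError(RuntimeError):
    """The model fell (torso below the fall threshold)."""

    def __init__(self, t: float, speed_cmd: float, height: float):
        super().__init__(
            f"model fell at t={t:.2f}s (speed command {speed_cmd:.2f} m/s, "
            f"torso height {height:.3f} m)"
        )
        self.t = t
        self.speed_cmd = speed_cmd
        self.height = height


TRACE_COLUMNS = (
    ["t", "v_cmd", "x", "z", "pitch", "vx"]
    + [f"hip_{leg.value}" for leg in LEGS]
    + [f"len_{leg.value}" for leg in LEGS]
    + [f"load_{leg.value}" for leg in LEGS]
    + [f"contact_{leg.value}" for leg in LEGS]
    + [f"y_f_{leg.value}" for leg in LEGS]
    + [f"y_e_{leg.value}" for leg in LEGS]
)


@dataclass
class SimulationSettings:
    """Numerical settings of a closed-loop run."""

    dt: float = 0.001          # integration / control step (s)
    sample_dt: float = 0.005   # trace sampling interval (s)
    cpg_warmup: float = 2.0    # CPG-only settling time before stepping (s)
    fall_height_ratio: float = 0.5  # abort below this fraction of standing height
    seed: int = 0
    init_noise: float = 0.05   # s.d. of the CPG initial-state jitter


class Simulator:
    """Closed-loop simulator for one parameter set.

    The speed command is a callable ``v_cmd(t)`` (m/s); constant-speed and
    ramp experiments provide it.  ``run`` integrates for a duration and
    returns the sampled trace as a DataFrame with :data:`TRACE_COLUMNS`.
    """

    def __init__(
        self,
        mech: bm.MechParams,
        cpg_params: cpg.CpgParams,
        control: ControlParams,
        speed_map: SpeedParams,
        settings: SimulationSettings | None = None,
    ):
        self.mech = mech
        self.cpg_params = cpg_params
        self.control = control
        self.speed_map = speed_map
        self.settings = settings or SimulationSettings()
        self.model = bm.assemble_model(mech)
        self.W = cpg.build_coupling(cpg_params)
        self._fall_height = self.settings.fall_height_ratio * self.model.standing_height

    def _initial_states(
        self, v0: float
    ) -> tuple[bm.PlanarBodyState, cpg.CpgNetworkState]:
        s = self.settings
        body = bm.standing_state(
            self.mech, hip_angle=self.speed_map.theta_mid, forward_speed=v0
        )
        net = cpg.trot_preset_state(seed=s.seed, noise=s.init_noise)
        # let the network settle onto its limit cycle before walking
        params_v = self.speed_map.cpg_for_speed(v0, self.cpg_params)
        n_warm = int(round(s.cpg_warmup / s.dt))
        u, v = net.u, net.v
        p = params_v
        for _ in range(n_warm):
            u, v = cpg._rk4_arrays(
                u, v, self.W, p.tau_u, p.tau_v, p.b, p.s0,
                np.zeros(cpg.N_HALF_CENTERS), s.dt,
            )
        return body, cpg.CpgNetworkState(u, v)

    def run(
        self,
        duration: float,
        v_cmd: Callable[[float], float],
        *,
        raise_on_fall: bool = True,
    ) -> pd.DataFrame:
        """Integrate the closed loop for ``duration`` seconds.

        Raises :class:`FallError` if the torso drops below the fall
        threshold (or truncates the trace if ``raise_on_fall`` is false).
        """
        if duration < 0:
            raise ValueError("duration must be >= 0")
        s = self.settings
        dt = s.dt
        n_steps = int(round(duration / dt))
        sample_every = max(1, int(round(s.sample_dt / dt)))
        n_samples = n_steps // sample_every + 1

        body, net = self._initial_states(v_cmd(0.0))
        u, v = net.u.copy(), net.v.copy()
        q, qd = body.q.copy(), body.qd.copy()
        loads = body.loads.copy()

        out = np.zeros((n_samples, len(TRACE_COLUMNS)))
        n_written = 0
        theta_mid = self.speed_map.theta_mid
        k1, k2 = self.control.k1, self.control.k2
        base_ctrl = self.control
        feeds = np.zeros(cpg.N_HALF_CENTERS)
        s0_vec = np.zeros(cpg.N_HALF_CENTERS)
        fell = False
        # rate-limited stance hip target: initialized at touchdown, swept
        # backward at the speed-matched rate until it reaches theta_d_st
        stance_tgt = q[bm.ITH].copy()
        prev_swing = np.maximum(u[1::2], 0.0) > 0.0

        for step in range(n_steps + 1):
            t = step * dt
            vc = float(v_cmd(t))
            p = self.speed_map.cpg_for_speed(vc, self.cpg_params)
            th_sw, th_st = self.speed_map.theta_targets(vc)
            th = q[bm.ITH]
            thd = qd[bm.ITH]
            l = q[bm.IL]
            ld = qd[bm.IL]
            y_f = np.maximum(u[1::2], 0.0)
            y_e = np.maximum(u[0::2], 0.0)

            if step % sample_every == 0:
                row = out[n_written]
                row[0] = t
                row[1] = vc
                row[2:6] = (q[bm.IX], q[bm.IZ], q[bm.IP], qd[bm.IX])
                row[6:10] = th
                row[10:14] = l
                row[14:18] = loads
                row[18:22] = loads > 0
                row[22:26] = y_f
                row[26:30] = y_e
                n_written += 1
            if step == n_steps:
                break

            # afferent feeds
            err = k1 * (th - theta_mid)
            feed2 = np.minimum(k2 * loads, base_ctrl.feed2_cap)
            feeds[0::2] = err                      # extensor
            feeds[1::2] = -err - feed2             # flexor (load inhibits)
            asym = self.speed_map.drive_asymmetry(vc)
            if asym > 0.0:
                s0_vec[0::2] = p.s0 * (1.0 + asym)
                s0_vec[1::2] = p.s0 * (1.0 - asym)
                s0_arg = s0_vec
            else:
                s0_arg = p.s0
            u, v = cpg._rk4_arrays(
                u, v, self.W, p.tau_u, p.tau_v, p.b, s0_arg, feeds, dt
            )

            # per-leg PD commands toward the phase setpoints
            swing = u[1::2] > 0.0
            omega = self.speed_map.stance_sweep_rate(vc, base_ctrl.l_d_st)
            if (self.speed_map.rate_limited_sweep
                    and omega < self.speed_map.sweep_rate_max):
                touchdown = prev_swing & ~swing
                stance_tgt[touchdown] = th_sw
                stance_tgt[~swing] = np.maximum(
                    th_st, stance_tgt[~swing] - omega * dt
                )
                prev_swing = swing
            else:
                # fast regime: drive the stance leg straight to theta_d_st
                stance_tgt[:] = th_st
            tau = np.where(
                swing,
                base_ctrl.hip_gains_sw.kp * (th_sw - th)
                - base_ctrl.hip_gains_sw.kd * thd,
                base_ctrl.hip_gains_st.kp * (stance_tgt - th)
                - base_ctrl.hip_gains_st.kd * thd,
            )
            l_st_tgt = self.speed_map.stance_length_target(vc, base_ctrl.l_d_st)
            fknee = np.where(
                swing,
                base_ctrl.len_gains_sw.kp * (base_ctrl.l_d_sw - l)
                - base_ctrl.len_gains_sw.kd * ld,
                base_ctrl.len_gains_st.kp * (l_st_tgt - l)
                - base_ctrl.len_gains_st.kd * ld,
            )

            q, qd, loads, _ = bm._rk4_step_arrays(q, qd, tau, fknee, self.mech, dt)

            if q[bm.IZ] < self._fall_height:
                if raise_on_fall:
                    raise FallError(t, vc, float(q[bm.IZ]))
                fell = True
                break

        trace = pd.DataFrame(out[:n_written], columns=TRACE_COLUMNS)
        trace.attrs["fell"] = fell
        return trace
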