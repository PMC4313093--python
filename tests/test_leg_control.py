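"""Phase generation, PD law, afferent feedbacks and the speed map."""
import dataclasses

import numpy as np
import pytest

from quadgait.cpg_network import (
    CpgNetworkState,
    CpgParams,
    build_coupling,
    half_center_index,
    step_network,
    EXTENSOR,
    FLEXOR,
)
from quadgait.leg_control import (
    ControlParams,
    PdGains,
    PhaseLabel,
    SpeedParams,
    hip_feedback,
    leg_phase,
    load_feedback,
    pd_command,
    setpoints,
)
from quadgait.legs import Leg


class TestLegPhase:
    @pytest.mark.parametrize(
        "y_f, expected",
        [(0.7, PhaseLabel.SWING), (0.0, PhaseLabel.STANCE),
         (1e-12, PhaseLabel.SWING)],
    )
    def test_swing_iff_flexor_positive(self, y_f, expected):
        assert leg_phase(y_f) is expected

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            leg_phase(-0.1)


class TestSetpoints:
    def test_swing_and_stance_targets(self):
        p = ControlParams(theta_d_sw=0.3, theta_d_st=-0.25, l_d_sw=0.17,
                          l_d_st=0.26)
        assert setpoints(PhaseLabel.SWING, p) == (0.3, 0.17)
        assert setpoints(PhaseLabel.STANCE, p) == (-0.25, 0.26)

    def test_swing_leg_is_retracted(self):
        with pytest.raises(ValueError):
            ControlParams(l_d_sw=0.3, l_d_st=0.25)


class TestPdCommand:
    def test_zero_error_zero_rate(self):
        assert pd_command(0.2, 0.2, 0.0, PdGains(50, 5)) == 0.0

    def test_linear_in_error(self):
        g = PdGains(50, 5)
        c1 = pd_command(1.0, 0.0, 0.0, g)
        c2 = pd_command(2.0, 0.0, 0.0, g)
        assert c2 == pytest.approx(2 * c1)

    def test_stance_spring_static_balance(self):
        """A stance leg under constant load compresses until Kp*dl = load."""
        g = PdGains(3000.0, 60.0)
        load = 40.0
        dl = load / g.kp
        force = pd_command(0.25, 0.25 - dl, 0.0, g)
        assert force == pytest.approx(load)  # pushes outward against the load


class TestHipFeedback:
    def test_zero_at_midstroke(self):
        assert hip_feedback(2.0, 0.05, theta_mid=0.05) == (0.0, 0.0)

    def test_zero_gain(self):
        assert hip_feedback(0.0, 0.4) == (0.0, 0.0)

    def test_antisymmetric_injection(self):
        e, f = hip_feedback(1.5, 0.3, theta_mid=0.1)
        assert e == pytest.approx(1.5 * 0.2)
        assert f == pytest.approx(-e)

    def test_entrainment_to_imposed_hip_motion(self):
        """A driven single CPG locks 1:1 to a detuned sinusoidal hip angle."""
        p = CpgParams(alpha=0.0, beta=0.0)
        W = build_coupling(p)
        dt = 0.001
        i_f = half_center_index(Leg.LF, FLEXOR)
        i_e = half_center_index(Leg.LF, EXTENSOR)

        def locked_period(t_drive, k1):
            state = CpgNetworkState.zeros()
            state.u[i_e], state.u[i_f] = 0.1, -0.1
            feeds = np.zeros(8)
            onsets = []
            prev = 0.0
            for k in range(int(25.0 / dt)):
                theta = 0.3 * np.sin(2 * np.pi * k * dt / t_drive)
                fe, ff = hip_feedback(k1, theta)
                feeds[i_e], feeds[i_f] = fe, ff
                state = step_network(state, p, feeds, dt, W=W)
                y = max(state.u[i_f], 0.0)
                if y > 0 and prev <= 0 and k * dt > 15.0:
                    onsets.append(k * dt)
                prev = y
            return float(np.diff(onsets).mean())

        # free-running period of this oscillator is about 1.13 s; drive 10%
        # away on either side and check 1:1 locking within 1%
        for t_drive in (1.0, 1.25):
            assert locked_period(t_drive, k1=2.0) == pytest.approx(
                t_drive, rel=0.01
            )


class TestLoadFeedback:
    def test_baseline_gain_zero(self):
        assert load_feedback(0.0, 55.0) == 0.0

    def test_zero_load(self):
        assert load_feedback(0.05, 0.0) == 0.0

    def test_inhibitory_sign(self):
        assert load_feedback(0.03, 40.0) == pytest.approx(-1.2)

    def test_rejects_negative_load_or_gain(self):
        with pytest.raises(ValueError):
            load_feedback(0.03, -1.0)
        with pytest.raises(ValueError):
            load_feedback(-0.01, 1.0)


def stance_duration_under_load(k2, load, n_cycles=8):
    """Mean extensor-burst (stance) duration of one CPG with the load
    feedback applied to the flexor whenever the leg is in stance."""
    p = CpgParams(alpha=0.0, beta=0.0)
    W = build_coupling(p)
    dt = 0.001
    i_e = half_center_index(Leg.LF, EXTENSOR)
    i_f = half_center_index(Leg.LF, FLEXOR)
    state = CpgNetworkState.zeros()
    state.u[i_e], state.u[i_f] = 0.1, -0.1
    feeds = np.zeros(8)
    durations = []
    stance_start = None
    for k in range(int(20.0 / dt)):
        in_stance = max(state.u[i_f], 0.0) == 0.0
        feeds[i_f] = load_feedback(k2, load if in_stance else 0.0)
        state = step_network(state, p, feeds, dt, W=W)
        now_stance = max(state.u[i_f], 0.0) == 0.0
        t = k * dt
        if now_stance and not in_stance:
            stance_start = t
        elif in_stance and not now_stance and stance_start is not None and t > 5:
            durations.append(t - stance_start)
    return float(np.mean(durations[-n_cycles:]))


def flexor_onset_delay(delta_load, k2=0.004, base_load=30.0, t_end=12.0,
                       n_compare=6):
    """Delay of the more-loaded oscillator's flexor burst behind its
    equally-wired, in-phase-started twin, after ``n_compare`` bursts.

    Models the two legs of one diagonal pair under a tilted posture: the
    leg carrying ``base_load + delta_load`` versus the leg carrying
    ``base_load``, each feeding back -k2*load to its own flexor while in
    stance."""
    p = CpgParams(alpha=0.0, beta=0.0)
    W = build_coupling(p)
    dt = 0.001
    state = CpgNetworkState.zeros()
    for leg in (Leg.LF, Leg.LH):
        state.u[half_center_index(leg, EXTENSOR)] = 0.1
        state.u[half_center_index(leg, FLEXOR)] = -0.1
    feeds = np.zeros(8)
    onsets = {Leg.LF: [], Leg.LH: []}
    prev = {Leg.LF: 0.0, Leg.LH: 0.0}
    loads = {Leg.LF: base_load + delta_load, Leg.LH: base_load}
    for k in range(int(t_end / dt)):
        for leg in (Leg.LF, Leg.LH):
            i_f = half_center_index(leg, FLEXOR)
            in_stance = max(state.u[i_f], 0.0) == 0.0
            feeds[i_f] = load_feedback(k2, loads[leg] if in_stance else 0.0)
        state = step_network(state, p, feeds, dt, W=W)
        for leg in (Leg.LF, Leg.LH):
            y = max(state.u[half_center_index(leg, FLEXOR)], 0.0)
            if y > 0 and prev[leg] <= 0:
                onsets[leg].append(k * dt)
            prev[leg] = y
    n = min(n_compare, len(onsets[Leg.LF]), len(onsets[Leg.LH]))
    return onsets[Leg.LF][n - 1] - onsets[Leg.LH][n - 1]


class TestLoadProlongsStance:
    def test_stance_duration_monotone_in_load(self):
        loads = [0.0, 15.0, 30.0, 45.0]
        durs = [stance_duration_under_load(0.005, L) for L in loads]
        assert all(b > a for a, b in zip(durs, durs[1:]))

    def test_flat_without_feedback(self):
        durs = [stance_duration_under_load(0.0, L) for L in (0.0, 30.0, 60.0)]
        assert max(durs) - min(durs) < 1e-6

    def test_unequal_loads_split_two_oscillators(self):
        """The less-loaded oscillator's flexor burst leads; the lead grows
        with the load difference (the within-pair splitting mechanism)."""
        leads = [flexor_onset_delay(d) for d in (0.0, 10.0, 20.0)]
        assert leads[0] == pytest.approx(0.0, abs=1e-9)
        assert all(b > a for a, b in zip(leads, leads[1:]))
        assert leads[1] > 0  # more-loaded oscillator is delayed


class TestSpeedParams:
    def test_targets_widen_with_speed(self):
        sp = SpeedParams()
        sw0, st0 = sp.theta_targets(0.25)
        sw1, st1 = sp.theta_targets(2.0)
        assert sw1 - st1 > sw0 - st0
        assert sw0 > st0

    def test_speed_map_never_touches_coupling_or_gains(self):
        """Changing the speed command leaves the interlimb wiring and the
        feedback gains untouched (config-level invariant)."""
        sp = SpeedParams()
        base_cpg = CpgParams(alpha=0.2, beta=0.2, gamma=2.0)
        base_ctrl = ControlParams(k1=2.0, k2=0.03)
        for v in (0.0, 0.25, 1.1, 2.5):
            cpgv = sp.cpg_for_speed(v, base_cpg)
            assert cpgv.alpha == base_cpg.alpha
            assert cpgv.beta == base_cpg.beta
            assert cpgv.gamma == base_cpg.gamma
            ctrlv = sp.control_for_speed(v, base_ctrl)
            assert ctrlv.k1 == base_ctrl.k1
            assert ctrlv.k2 == base_ctrl.k2
            assert ctrlv.hip_gains_st == base_ctrl.hip_gains_st

    def test_time_scale_clamped(self):
        sp = SpeedParams()
        assert sp.time_scale(100.0) == sp.time_scale_min
        assert sp.time_scale(-100.0) == sp.time_scale_max

    def test_drive_asymmetry_clipped(self):
        sp = SpeedParams(drive_asym0=0.9, drive_asym_slope=0.0)
        assert sp.drive_asymmetry(0.0) == 0.5
        sp2 = SpeedParams(drive_asym0=0.25, drive_asym_slope=-0.1)
        assert sp2.drive_asymmetry(10.0) == 0.0
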