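"""Footfall digitization, stride metrics, classification, fixtures."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from quadgait.gait_analysis import (
    DEFAULT_LOAD_THRESHOLD,
    FootfallDiagram,
    body_leg_frequency_ratio,
    classify_gait,
    detect_flight,
    extract_footfalls,
    generate_ideal_trace,
    stride_metrics,
    tilt_state_sequence,
)
from quadgait.gait_rule import GaitLabel, TiltState, expected_tilts_for_gait, mirror_gait
from quadgait.legs import LEGS, Leg

NINE_GAITS = [g for g in GaitLabel if g is not GaitLabel.UNKNOWN]


def square_wave_trace(period=1.0, high=50.0, duration=4.0, dt=0.005):
    t = np.arange(0.0, duration, dt)
    phase = (t % period) < period / 2
    frame = {"t": t, "pitch": np.zeros_like(t)}
    for leg in LEGS:
        frame[f"load_{leg.value}"] = np.where(phase, high, 0.0)
    return pd.DataFrame(frame)


class TestExtractFootfalls:
    def test_zero_loads_give_empty_diagram(self):
        tr = square_wave_trace(high=0.0)
        diag = extract_footfalls(tr, 1.0)
        assert all(len(diag.intervals[leg]) == 0 for leg in LEGS)

    def test_square_wave_recovered_within_one_sample(self):
        tr = square_wave_trace(period=1.0, high=50.0, duration=4.0, dt=0.005)
        diag = extract_footfalls(tr, 1.0)
        for leg in LEGS:
            for k, (on, off) in enumerate(diag.intervals[leg]):
                assert on == pytest.approx(k * 1.0, abs=0.006)
                assert off == pytest.approx(k * 1.0 + 0.5, abs=0.006)

    def test_debounce_removes_short_dropouts(self):
        tr = square_wave_trace(period=1.0, high=50.0, duration=2.0, dt=0.001)
        col = tr["load_LF"].to_numpy().copy()
        col[100:103] = 0.0  # 3 ms dropout inside a stance
        tr["load_LF"] = col
        diag = extract_footfalls(tr, 1.0)
        assert len(diag.intervals[Leg.LF]) == 2  # not split by the dropout

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            extract_footfalls(pd.DataFrame({"t": []}), 1.0)

    def test_trot_fixture_diagonal_onsets_coincide(self):
        trace, _ = generate_ideal_trace(GaitLabel.TROT, 0.5, 0.5, 8, 0.0, 0)
        diag = extract_footfalls(trace, DEFAULT_LOAD_THRESHOLD)
        on_lf = diag.onsets(Leg.LF)
        on_rh = diag.onsets(Leg.RH)
        assert len(on_lf) == len(on_rh)
        assert np.allclose(on_lf, on_rh, atol=0.006)


class TestStrideMetrics:
    def test_ideal_trot_phases(self):
        _, diag = generate_ideal_trace(GaitLabel.TROT, 0.5, 0.5, 10, 0.0, 0)
        m = stride_metrics(diag)
        assert m.period == pytest.approx(0.5, rel=1e-6)
        assert abs(m.delta1) < 0.01
        assert abs(m.delta2) < 0.01
        assert min(m.phases[Leg.LH], 1 - m.phases[Leg.LH]) == pytest.approx(
            0.5, abs=0.01
        ) or abs(m.phases[Leg.LH] - 0.5) < 0.01

    def test_ideal_walk_phases_quarter_spaced(self):
        _, diag = generate_ideal_trace(GaitLabel.L_WALK, 0.6, 0.6, 10, 0.0, 0)
        m = stride_metrics(diag)
        phases = sorted(m.phases.values())
        gaps = np.diff(phases + [phases[0] + 1.0])
        assert np.allclose(gaps, 0.25, atol=0.01)

    def test_time_translation_invariance(self):
        _, diag = generate_ideal_trace(GaitLabel.R_CANTER, 0.5, 0.5, 12, 0.0, 0)
        m0 = stride_metrics(diag)
        shifted = FootfallDiagram(
            {leg: [(on + 0.2, off + 0.2) for on, off in ivs]
             for leg, ivs in diag.intervals.items()},
            diag.duration + 0.2,
        )
        m1 = stride_metrics(shifted)
        assert m1.delta1 == pytest.approx(m0.delta1, abs=1e-9)
        assert m1.delta2 == pytest.approx(m0.delta2, abs=1e-9)
        assert m1.period == pytest.approx(m0.period, rel=1e-9)

    def test_too_few_strides_rejected(self):
        _, diag = generate_ideal_trace(GaitLabel.TROT, 0.5, 0.5, 2, 0.0, 0)
        with pytest.raises(ValueError):
            stride_metrics(diag)


class TestClassifyGait:
    @pytest.mark.parametrize("gait", NINE_GAITS)
    def test_round_trip_all_nine_gaits(self, gait):
        _, diag = generate_ideal_trace(gait, 0.5, 0.55, 10, 0.0, 0)
        assert classify_gait(stride_metrics(diag)) is gait

    @pytest.mark.parametrize("gait", NINE_GAITS)
    def test_round_trip_under_jitter(self, gait):
        for seed in range(5):
            _, diag = generate_ideal_trace(gait, 0.5, 0.55, 12, 0.02, seed)
            assert classify_gait(stride_metrics(diag)) is gait

    @pytest.mark.parametrize("gait", NINE_GAITS)
    def test_mirror_maps_leads(self, gait):
        _, diag = generate_ideal_trace(gait, 0.5, 0.55, 10, 0.0, 0)
        mirrored = diag.mirrored()
        assert classify_gait(stride_metrics(mirrored)) is mirror_gait(gait)

    def test_pace_pattern_returns_unknown(self):
        """Lateral-pair synchrony matches no cell of the rule table."""
        period, duty, dur = 0.5, 0.5, 6.0
        intervals = {}
        for leg, ph in ((Leg.LF, 0.0), (Leg.LH, 0.0), (Leg.RF, 0.5),
                        (Leg.RH, 0.5)):
            intervals[leg] = [
                ((k + ph) * period, (k + ph) * period + duty * period)
                for k in range(int(dur / period) - 1)
            ]
        diag = FootfallDiagram(intervals, dur)
        assert classify_gait(stride_metrics(diag)) is GaitLabel.UNKNOWN

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        gait=st.sampled_from(NINE_GAITS),
        seed=st.integers(0, 2 ** 16),
        period=st.floats(0.3, 0.8),
        duty=st.floats(0.35, 0.7),
    )
    def test_round_trip_property_over_periods_and_duties(
        self, gait, seed, period, duty
    ):
        """classify(generate(g)) == g across stride periods, duty factors
        and jitter seeds (jitter well below the phase tolerance)."""
        _, diag = generate_ideal_trace(gait, period, duty, 10, 0.015, seed)
        assert classify_gait(stride_metrics(diag)) is gait

    def test_tol_bounds_validated(self):
        _, diag = generate_ideal_trace(GaitLabel.TROT, 0.5, 0.5, 10, 0.0, 0)
        m = stride_metrics(diag)
        with pytest.raises(ValueError):
            classify_gait(m, tol=0.3)


class TestFrequencyRatio:
    def make_trace(self, n_cycles_per_stride, period=0.5, n_strides=8):
        trace, diag = generate_ideal_trace(
            GaitLabel.TROT, period, 0.5, n_strides, 0.0, 0
        )
        t = trace["t"].to_numpy()
        trace["pitch"] = 0.05 * np.sin(
            2 * np.pi * n_cycles_per_stride * t / period
        )
        return trace, diag

    def test_two_cycles_per_stride(self):
        trace, diag = self.make_trace(2)
        assert body_leg_frequency_ratio(trace, diag).ratio == pytest.approx(
            2.0, abs=0.1
        )

    def test_one_cycle_per_stride(self):
        trace, diag = self.make_trace(1)
        assert body_leg_frequency_ratio(trace, diag).ratio == pytest.approx(
            1.0, abs=0.1
        )

    def test_constant_pitch_flagged(self):
        trace, diag = self.make_trace(0)
        trace["pitch"] = 0.0
        res = body_leg_frequency_ratio(trace, diag)
        assert res.ratio == 0.0
        assert res.low_amplitude

    def test_unsteady_trace_rejected(self):
        trace, _ = generate_ideal_trace(GaitLabel.TROT, 0.5, 0.5, 12, 0.0, 0)
        # strongly irregular stride periods (alternating 0.35 s / 0.75 s)
        onsets = np.cumsum([0.0] + [0.35, 0.75] * 4)
        bad = FootfallDiagram(
            {leg: [(on, on + 0.2) for on in onsets] for leg in LEGS},
            float(onsets[-1] + 0.5),
        )
        with pytest.raises(ValueError, match="non-steady"):
            body_leg_frequency_ratio(trace, bad)


class TestTiltStates:
    def test_zero_pitch_is_level(self):
        trace, diag = generate_ideal_trace(GaitLabel.TROT, 0.5, 0.5, 8, 0.0, 0)
        assert tilt_state_sequence(trace, diag) == (
            TiltState.LEVEL, TiltState.LEVEL
        )

    @pytest.mark.parametrize("gait", NINE_GAITS)
    def test_fixture_pitch_realizes_rule_tilts(self, gait):
        trace, diag = generate_ideal_trace(gait, 0.5, 0.55, 10, 0.0, 0)
        assert tilt_state_sequence(trace, diag) == expected_tilts_for_gait(gait)

    def test_antisymmetric_under_pitch_flip(self):
        trace, diag = generate_ideal_trace(GaitLabel.L_WALK, 0.5, 0.55, 10, 0.0, 0)
        flipped = trace.copy()
        flipped["pitch"] = -flipped["pitch"]
        t1 = tilt_state_sequence(trace, diag)
        t2 = tilt_state_sequence(flipped, diag)
        flip = {TiltState.TILTED_UP: TiltState.TILTED_DOWN,
                TiltState.TILTED_DOWN: TiltState.TILTED_UP,
                TiltState.LEVEL: TiltState.LEVEL}
        assert t2 == (flip[t1[0]], flip[t1[1]])


class TestDetectFlight:
    def test_high_duty_walk_has_no_flight(self):
        _, diag = generate_ideal_trace(GaitLabel.L_WALK, 0.6, 0.7, 10, 0.0, 0)
        inner = [iv for iv in detect_flight(diag)
                 if iv[0] > 1.0 and iv[1] < diag.duration - 1.0]
        assert inner == []

    def test_gallop_fixture_has_flight_each_stride(self):
        _, diag = generate_ideal_trace(GaitLabel.RT_GALLOP, 0.5, 0.2, 10, 0.0, 0)
        inner = [iv for iv in detect_flight(diag)
                 if iv[0] > 1.0 and iv[1] < diag.duration - 1.0]
        assert len(inner) >= 8

    def test_partition_covers_window(self):
        _, diag = generate_ideal_trace(GaitLabel.R_CANTER, 0.5, 0.5, 8, 0.0, 0)
        flight = detect_flight(diag)
        stance_events = []
        for leg in LEGS:
            stance_events.extend(diag.intervals[leg])
        # sweep the window: every instant is in a stance or a flight interval
        probes = np.linspace(0.0, diag.duration - 1e-9, 997)
        for t in probes:
            in_stance = any(on <= t < off for on, off in stance_events)
            in_flight = any(a <= t < b for a, b in flight)
            assert in_stance != in_flight  # exactly one of the two


def test_diagram_json_and_plot_export(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from quadgait.gait_analysis import diagram_to_json, plot_footfall_diagram

    _, diag = generate_ideal_trace(GaitLabel.TROT, 0.5, 0.5, 6, 0.0, 0)
    payload = diagram_to_json(diag)
    assert set(payload["intervals"]) == {leg.value for leg in LEGS}
    ax = plot_footfall_diagram(diag)
    assert ax.get_xlim()[1] == diag.duration


class TestGenerateIdealTrace:
    def test_deterministic_for_fixed_seed(self):
        a, _ = generate_ideal_trace(GaitLabel.L_CANTER, 0.5, 0.5, 8, 0.03, 7)
        b, _ = generate_ideal_trace(GaitLabel.L_CANTER, 0.5, 0.5, 8, 0.03, 7)
        pd.testing.assert_frame_equal(a, b)

    def test_rt_gallop_footfall_order(self):
        """RT-gallop fixture footfalls follow the documented LF-RF-LH-RH."""
        _, diag = generate_ideal_trace(GaitLabel.RT_GALLOP, 0.5, 0.4, 8, 0.0, 0)
        m = stride_metrics(diag)
        seq = sorted(LEGS, key=lambda leg: m.phases[leg])
        assert [l.value for l in seq] == ["LF", "RF", "LH", "RH"]

    def test_rejects_unknown_and_bad_duty(self):
        with pytest.raises(ValueError):
            generate_ideal_trace(GaitLabel.UNKNOWN, 0.5, 0.5, 8, 0.0, 0)
        with pytest.raises(ValueError):
            generate_ideal_trace(GaitLabel.TROT, 0.5, 1.5, 8, 0.0, 0)
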