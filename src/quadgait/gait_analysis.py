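"""From raw locomotion traces to footfall diagrams, phases and gait labels.

A *trace* is a pandas DataFrame sampled at a fixed rate with at least the
columns ``t``, ``pitch`` and ``load_<leg>`` for the four legs (simulator
traces carry more).  Footfalls are digitized from the load signals with a
hysteresis threshold and a debounce, stride metrics are computed from the
stance-onset phases (circular statistics), and the signed diagonal-pair
phase differences are mapped onto the nine cells of the tilt-combination
rule table.

The module also contains :func:`generate_ideal_trace`, a first-class
synthetic generator producing idealized footfall/pitch traces for any of
the nine gaits: footfall phases follow the gait's canonical swing order,
and the pitch signal realizes the gait's tilt states with the correct
body/stride frequency ratio (2 per stride for walks, 1 for canters and
gallops, ~0 for the trot).  It defines the test conditions for the
classifier independently of the neuromechanical simulator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .legs import LEGS, Leg, MIRROR, PAIR1, PAIR2
from .gait_rule import (
    GaitLabel,
    TiltState,
    expected_tilts_for_gait,
    predict_gait,
    swing_phases,
)

__all__ = [
    "FootfallDiagram",
    "StrideMetrics",
    "FrequencyRatioResult",
    "extract_footfalls",
    "stride_metrics",
    "classify_gait",
    "body_leg_frequency_ratio",
    "tilt_state_sequence",
    "detect_flight",
    "generate_ideal_trace",
    "diagram_to_json",
    "plot_footfall_diagram",
    "DEFAULT_LOAD_THRESHOLD",
]

#: Default footfall threshold: 2% of the default 7.0 kg model's weight.
DEFAULT_LOAD_THRESHOLD = 0.02 * 7.0 * 9.81


@dataclass
class FootfallDiagram:
    """Per-leg stance intervals (s) over a trace of length ``duration``."""

    intervals: dict[Leg, list[tuple[float, float]]]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for leg in LEGS:
            ivs = self.intervals.setdefault(leg, [])
            ivs.sort()
            prev_end = -math.inf
            for on, off in ivs:
                if not (0.0 <= on < off <= self.duration + 1e-9):
                    raise ValueError(f"bad interval ({on}, {off}) for {leg}")
                if on < prev_end:
                    raise ValueError(f"overlapping intervals for {leg}")
                prev_end = off

    def onsets(self, leg: Leg) -> np.ndarray:
        return np.array([on for on, _ in self.intervals[Leg(leg)]])

    def stance_at(self, leg: Leg, t: float) -> bool:
        return any(on <= t < off for on, off in self.intervals[Leg(leg)])

    def shifted(self, offset: float) -> "FootfallDiagram":
        """Time-translated copy (intervals clipped to the new window)."""
        new = {
            leg: [
                (on + offset, off + offset)
                for on, off in ivs
                if on + offset >= 0 and off + offset <= self.duration
            ]
            for leg, ivs in self.intervals.items()
        }
        return FootfallDiagram(new, self.duration)

    def mirrored(self) -> "FootfallDiagram":
        """Left-right exchanged copy."""
        return FootfallDiagram(
            {MIRROR[leg]: list(ivs) for leg, ivs in self.intervals.items()},
            self.duration,
        )


@dataclass
class StrideMetrics:
    """Stride-cycle summary of a footfall diagram.

    Phases are stance-onset phases in cycles, LF as the zero reference.
    ``delta1 = phi(RF) - phi(LH)`` and ``delta2 = phi(LF) - phi(RH)`` are the
    signed diagonal-pair phase differences, wrapped to (-0.5, 0.5].
    """

    period: float
    duty: dict[Leg, float]
    phases: dict[Leg, float]
    delta1: float
    delta2: float
    flight_fraction: float
    n_strides: int = 0


@dataclass
class FrequencyRatioResult:
    """Body-pitch oscillation frequency / stride frequency."""

    ratio: float
    n_strides: int
    pitch_cycles: float
    low_amplitude: bool = False

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.ratio


def _wrap_half(x: float) -> float:
    """Wrap a phase difference to (-0.5, 0.5]."""
    w = (x + 0.5) % 1.0 - 0.5
    return 0.5 if w == -0.5 else w


def _circular_mean_phase(phases: np.ndarray) -> float:
    ang = 2.0 * np.pi * phases
    m = math.atan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2.0 * np.pi)
    return m % 1.0


def extract_footfalls(
    trace: pd.DataFrame,
    load_threshold: float = DEFAULT_LOAD_THRESHOLD,
    *,
    hysteresis_ratio: float = 0.5,
    min_duration: float = 0.010,
) -> FootfallDiagram:
    """Digitize per-leg stance intervals from the load signals.

    Stance turns on when the load exceeds ``load_threshold`` and off when it
    falls below ``hysteresis_ratio * load_threshold``; stances and gaps
    shorter than ``min_duration`` are debounced away (gaps merged first).
    """
    if load_threshold <= 0:
        raise ValueError("load_threshold must be positive")
    if len(trace) == 0:
        raise ValueError("empty trace")
    t = trace["t"].to_numpy(dtype=float)
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("trace must span positive time")
    t0 = t[0]
    low = hysteresis_ratio * load_threshold
    intervals: dict[Leg, list[tuple[float, float]]] = {}
    for leg in LEGS:
        load = trace[f"load_{leg.value}"].to_numpy(dtype=float)
        raw: list[tuple[float, float]] = []
        on_t: float | None = None
        state = load[0] > load_threshold
        if state:
            on_t = t[0]
        for k in range(1, len(t)):
            if not state and load[k] > load_threshold:
                state, on_t = True, t[k]
            elif state and load[k] < low:
                state = False
                raw.append((on_t - t0, t[k] - t0))
        if state:
            raw.append((on_t - t0, t[-1] - t0))
        # debounce: merge short gaps, then drop short stances
        merged: list[tuple[float, float]] = []
        for iv in raw:
            if merged and iv[0] - merged[-1][1] < min_duration:
                merged[-1] = (merged[-1][0], iv[1])
            else:
                merged.append(iv)
        intervals[leg] = [
            (on, min(off, duration)) for on, off in merged
            if off - on >= min_duration
        ]
    return FootfallDiagram(intervals, duration)


def stride_metrics(
    diagram: FootfallDiagram, reference: Leg = Leg.LF
) -> StrideMetrics:
    """Stride period, duty factors and relative phases from stance onsets.

    The period is the mean inter-onset interval of the reference leg; each
    leg's phase is the circular mean of its onset offsets from the previous
    reference onset, in cycles.  Requires at least three complete strides
    per leg.
    """
    ref_on = diagram.onsets(reference)
    if len(ref_on) < 4:
        raise ValueError("need at least 3 complete strides of the reference leg")
    period = float(np.diff(ref_on).mean())
    if period <= 0:
        raise ValueError("non-increasing reference onsets")
    phases: dict[Leg, float] = {}
    duty: dict[Leg, float] = {}
    for leg in LEGS:
        ons = diagram.onsets(leg)
        if len(ons) < 4:
            raise ValueError(f"need at least 3 complete strides for {leg}")
        offs = []
        for on in ons:
            prev = ref_on[ref_on <= on + 1e-12]
            if len(prev) == 0:
                continue
            offs.append((on - prev[-1]) / period)
        phases[leg] = _circular_mean_phase(np.asarray(offs))
        durs = [off - on for on, off in diagram.intervals[leg]]
        # interior stances only: edge stances may be clipped by the window
        interior = durs[1:-1] if len(durs) > 2 else durs
        duty[leg] = float(np.mean(interior) / period)
    delta1 = _wrap_half(phases[PAIR1[0]] - phases[PAIR1[1]])
    delta2 = _wrap_half(phases[PAIR2[0]] - phases[PAIR2[1]])
    flight = detect_flight(diagram)
    total_flight = sum(b - a for a, b in flight)
    return StrideMetrics(
        period=period,
        duty=duty,
        phases=phases,
        delta1=delta1,
        delta2=delta2,
        flight_fraction=total_flight / diagram.duration,
        n_strides=len(ref_on) - 1,
    )


def _pair_tilt_from_delta(
    delta: float, tol: float, max_split: float
) -> TiltState | None:
    """Tilt state implied by a signed fore-minus-hind phase difference.

    The pair's foreleg swinging first (negative delta) is the tilted-up
    signature; in-phase within ``tol`` is level.  A split larger than
    ``max_split`` matches no rule cell.
    """
    if abs(delta) <= tol:
        return TiltState.LEVEL
    if abs(delta) > max_split:
        return None
    return TiltState.TILTED_UP if delta < 0 else TiltState.TILTED_DOWN


def classify_gait(
    metrics: StrideMetrics,
    tol: float = 0.07,
    *,
    max_split: float = 0.38,
    origin_tol: float = 0.18,
) -> GaitLabel:
    """Map signed diagonal-pair phase differences to one of the nine gaits.

    Each pair is judged level (|delta| <= tol) or split toward one leg; the
    pair-origin anti-phase of the underlying rule (the mean phases of the
    two pairs differ by half a cycle) is also checked.  Patterns matching no
    cell return UNKNOWN.  All quantities are phase differences, so the
    result is invariant under cyclic rotation of the stride origin.
    """
    if not 0 < tol < 0.25:
        raise ValueError("tol must lie in (0, 0.25)")
    t1 = _pair_tilt_from_delta(metrics.delta1, tol, max_split)
    t2 = _pair_tilt_from_delta(metrics.delta2, tol, max_split)
    if t1 is None or t2 is None:
        return GaitLabel.UNKNOWN
    origin1 = (metrics.phases[PAIR1[1]] + metrics.delta1 / 2.0) % 1.0
    origin2 = (metrics.phases[PAIR2[1]] + metrics.delta2 / 2.0) % 1.0
    if abs(abs(_wrap_half(origin1 - origin2)) - 0.5) > origin_tol:
        return GaitLabel.UNKNOWN
    return predict_gait(t1, t2).gait


def _count_half_cycles(signal: np.ndarray, eps: float) -> int:
    """Alternating +/-eps threshold crossings (robust zero-crossing count)."""
    count = 0
    state = 0  # last extreme side seen: +1, -1, or 0 (none yet)
    for x in signal:
        if x > eps and state <= 0:
            if state == -1:
                count += 1
            state = 1
        elif x < -eps and state >= 0:
            if state == 1:
                count += 1
            state = -1
    return count + (1 if state != 0 else 0)


def body_leg_frequency_ratio(
    trace: pd.DataFrame,
    diagram: FootfallDiagram | None = None,
    *,
    reference: Leg = Leg.LF,
    load_threshold: float = DEFAULT_LOAD_THRESHOLD,
    min_strides: int = 5,
    steadiness_cv: float = 0.2,
    amplitude_floor: float = 1e-3,
) -> FrequencyRatioResult:
    """Dominant pitch-oscillation frequency divided by the stride frequency.

    The pitch signal is mean-removed over an integer number of strides and
    its oscillation cycles are counted by alternating threshold crossings
    (a hysteresis-robust zero-crossing count); the ratio is cycles per
    stride.  A near-constant pitch yields ratio 0 with ``low_amplitude``
    set.  Raises on traces with fewer than ``min_strides`` strides or with
    stride-period variability above ``steadiness_cv``.
    """
    if diagram is None:
        diagram = extract_footfalls(trace, load_threshold)
    ref_on = diagram.onsets(reference)
    if len(ref_on) < min_strides + 1:
        raise ValueError(f"need at least {min_strides} strides")
    periods = np.diff(ref_on)
    if periods.std() / periods.mean() > steadiness_cv:
        raise ValueError("non-steady trace: stride period variance too large")
    t = trace["t"].to_numpy(dtype=float)
    t0_abs = t[0]
    lo, hi = ref_on[0] + t0_abs, ref_on[-1] + t0_abs
    mask = (t >= lo) & (t <= hi)
    pitch = trace["pitch"].to_numpy(dtype=float)[mask]
    n_strides = len(ref_on) - 1
    # light smoothing (~5 samples) to suppress sample-level chatter
    if len(pitch) > 10:
        kernel = np.ones(5) / 5.0
        pitch = np.convolve(pitch, kernel, mode="same")
    x = pitch - pitch.mean()
    amp = float(np.std(x))
    if amp < amplitude_floor:
        return FrequencyRatioResult(0.0, n_strides, 0.0, low_amplitude=True)
    eps = 0.25 * amp
    half_cycles = _count_half_cycles(x, eps)
    cycles = half_cycles / 2.0
    return FrequencyRatioResult(
        ratio=cycles / n_strides,
        n_strides=n_strides,
        pitch_cycles=cycles,
    )


def _pair_overlap_windows(
    diagram: FootfallDiagram, pair: tuple[Leg, Leg]
) -> list[tuple[float, float]]:
    a, b = pair
    out = []
    for on_a, off_a in diagram.intervals[a]:
        for on_b, off_b in diagram.intervals[b]:
            lo, hi = max(on_a, on_b), min(off_a, off_b)
            if hi > lo:
                out.append((lo, hi))
    out.sort()
    return out


def tilt_state_sequence(
    trace: pd.DataFrame,
    diagram: FootfallDiagram,
    deadband: float = math.radians(0.5),
) -> tuple[TiltState, TiltState]:
    """Tilt state of each diagonal pair from the pitch trace.

    For each pair, the pitch is averaged over the latter half of every
    window in which both legs of the pair are in stance; the time-weighted
    grand mean is mapped to TILTED_DOWN (> +deadband), TILTED_UP
    (< -deadband) or LEVEL.
    """
    t = trace["t"].to_numpy(dtype=float)
    t_rel = t - t[0]
    pitch = trace["pitch"].to_numpy(dtype=float)
    states: list[TiltState] = []
    for pair in (PAIR1, PAIR2):
        windows = _pair_overlap_windows(diagram, pair)
        if not windows:
            raise ValueError(f"pair {pair} never in overlapping stance")
        total, weight = 0.0, 0.0
        for lo, hi in windows:
            mid = 0.5 * (lo + hi)
            mask = (t_rel >= mid) & (t_rel <= hi)
            if mask.any():
                total += pitch[mask].sum()
                weight += mask.sum()
        if weight == 0:
            raise ValueError("trace sampling too coarse for stance windows")
        mean_pitch = total / weight
        if mean_pitch > deadband:
            states.append(TiltState.TILTED_DOWN)
        elif mean_pitch < -deadband:
            states.append(TiltState.TILTED_UP)
        else:
            states.append(TiltState.LEVEL)
    return states[0], states[1]


def detect_flight(diagram: FootfallDiagram) -> list[tuple[float, float]]:
    """Intervals of the diagram window in which no leg is in stance."""
    events: list[tuple[float, int]] = []
    for leg in LEGS:
        for on, off in diagram.intervals[leg]:
            events.append((on, +1))
            events.append((off, -1))
    events.sort(key=lambda e: (e[0], -e[1]))
    flight: list[tuple[float, float]] = []
    depth = 0
    gap_start = 0.0
    for time_, delta in events:
        if depth == 0 and time_ > gap_start:
            flight.append((gap_start, time_))
        depth += delta
        if depth == 0:
            gap_start = time_
    if gap_start < diagram.duration:
        flight.append((gap_start, diagram.duration))
    return [(a, b) for a, b in flight if b - a > 1e-12]


def _raised_cosine_bump(
    t: np.ndarray, center: float, width: float
) -> np.ndarray:
    out = np.zeros_like(t)
    mask = np.abs(t - center) < width / 2.0
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t[mask] - center) / width))
    return out


def generate_ideal_trace(
    gait: GaitLabel,
    period: float = 0.5,
    duty: float = 0.55,
    n_strides: int = 10,
    jitter: float = 0.0,
    seed: int | None = 0,
    *,
    dt: float = 0.005,
    load_amplitude: float = 30.0,
    pitch_amplitude: float = 0.06,
) -> tuple[pd.DataFrame, FootfallDiagram]:
    """Idealized (trace, footfall diagram) fixture for one of the nine gaits.

    Footfall onset phases follow the gait's canonical swing order; loads are
    square pulses of ``load_amplitude``; the pitch signal is a train of
    raised-cosine bumps placed in the latter half of each diagonal pair's
    overlapping stance with the sign of that pair's tilt state, which
    reproduces the gait's tilt signature and its body/stride frequency
    ratio.  Deterministic for a fixed seed; ``jitter`` is the s.d. of the
    onset perturbation in cycles.
    """
    if gait is GaitLabel.UNKNOWN:
        raise ValueError("cannot generate a trace for UNKNOWN")
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must lie in (0, 1)")
    if period <= 0 or n_strides < 1:
        raise ValueError("period and n_strides must be positive")
    tilts = expected_tilts_for_gait(gait)
    swing_ph = swing_phases(*tilts)
    rng = np.random.default_rng(seed)
    duration = (n_strides + 1) * period
    t = np.arange(0.0, duration + dt / 2.0, dt)
    loads = {leg: np.zeros_like(t) for leg in LEGS}
    intervals: dict[Leg, list[tuple[float, float]]] = {leg: [] for leg in LEGS}
    for leg in LEGS:
        onset_phase = (swing_ph[leg] + (1.0 - duty)) % 1.0
        for k in range(n_strides + 1):
            on = (k + onset_phase) * period
            if jitter > 0:
                on += rng.normal(0.0, jitter * period)
            off = on + duty * period
            if on < 0 or off > duration:
                continue
            intervals[leg].append((on, off))
            loads[leg][(t >= on) & (t < off)] = load_amplitude
    diagram = FootfallDiagram(intervals, duration)

    pitch = np.zeros_like(t)
    tilt_sign = {
        TiltState.TILTED_DOWN: 1.0,
        TiltState.LEVEL: 0.0,
        TiltState.TILTED_UP: -1.0,
    }
    for pair, tilt in ((PAIR1, tilts[0]), (PAIR2, tilts[1])):
        sgn = tilt_sign[tilt]
        if sgn == 0.0:
            continue
        for lo, hi in _pair_overlap_windows(diagram, pair):
            center = 0.25 * lo + 0.75 * hi  # midpoint of the latter half
            width = max(hi - lo, 4 * dt)
            pitch += sgn * pitch_amplitude * _raised_cosine_bump(t, center, width)

    frame = {"t": t, "pitch": pitch}
    for leg in LEGS:
        frame[f"load_{leg.value}"] = loads[leg]
    return pd.DataFrame(frame), diagram


def diagram_to_json(diagram: FootfallDiagram) -> dict:
    """JSON-serializable form of a footfall diagram."""
    return {
        "duration": diagram.duration,
        "intervals": {
            leg.value: [[on, off] for on, off in ivs]
            for leg, ivs in diagram.intervals.items()
        },
    }


def plot_footfall_diagram(diagram: FootfallDiagram, ax=None, flight: bool = True):
    """Hildebrand-style gait diagram: one stance bar row per leg.

    Flight phases, if requested, are shaded across all rows.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.4))
    for row, leg in enumerate(reversed(LEGS)):
        for on, off in diagram.intervals[leg]:
            ax.barh(row, off - on, left=on, height=0.6, color="k")
    if flight:
        for a, b in detect_flight(diagram):
            ax.axvspan(a, b, color="0.85", zorder=0)
    ax.set_yticks(range(len(LEGS)))
    ax.set_yticklabels([leg.value for leg in reversed(LEGS)])
    ax.set_xlabel("time (s)")
    ax.set_xlim(0, diagram.duration)
    return ax
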