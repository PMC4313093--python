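"""End-to-end locomotion experiments: constant speed, ramps and sweeps.

An :class:`ExperimentConfig` bundles every parameter section (mechanics,
CPG, control, speed map, schedule, numerics) and round-trips through YAML.
``run_constant_speed`` classifies the steady gait after a transient,
``run_ramp`` produces the merged time-ordered gait-label sequence of an
acceleration/deceleration run, and ``speed_sweep`` tabulates the steady
gait, flight fraction and body/stride frequency ratio over a list of
speeds with replicated initial conditions.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .body_mechanics import MechParams
from .cpg_network import CpgParams
from .gait_analysis import (
    DEFAULT_LOAD_THRESHOLD,
    FootfallDiagram,
    body_leg_frequency_ratio,
    classify_gait,
    extract_footfalls,
    stride_metrics,
)
from .gait_rule import GaitLabel
from .leg_control import ControlParams, PdGains, SpeedParams
from .legs import Leg
from .simulate import FallError, SimulationSettings, Simulator, TRACE_COLUMNS

__all__ = [
    "SpeedSchedule",
    "ExperimentConfig",
    "RunResult",
    "run_constant_speed",
    "run_ramp",
    "speed_sweep",
    "write_trace",
    "read_trace",
    "TraceSchemaError",
]

TRACE_FORMAT_VERSION = 1


class TraceSchemaError(ValueError):
    """A trace file does not match the expected schema or version."""


@dataclass(frozen=True)
class SpeedSchedule:
    """Piecewise-linear speed command v(t).

    ``times`` strictly increasing, ``speeds`` the same length and >= 0; the
    command is clamped to the end values outside the time range.  Constant
    and single-slope ramp schedules are convenience constructors.
    """

    times: tuple[float, ...]
    speeds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.speeds) or len(self.times) == 0:
            raise ValueError("times and speeds must be equal-length, non-empty")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if min(self.speeds) < 0:
            raise ValueError("schedule speeds must be >= 0")

    @classmethod
    def constant(cls, v: float) -> "SpeedSchedule":
        return cls((0.0,), (v,))

    @classmethod
    def ramp(
        cls, v_start: float, v_end: float, slope: float, t_start: float = 0.0
    ) -> "SpeedSchedule":
        """Ramp at |slope| m/s^2 from v_start to v_end, holding afterwards."""
        if slope == 0:
            raise ValueError("ramp slope must be nonzero")
        t_ramp = abs((v_end - v_start) / slope)
        if t_ramp == 0:
            return cls.constant(v_start)
        return cls((t_start, t_start + t_ramp), (v_start, v_end))

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.times, self.speeds))

    @property
    def duration_hint(self) -> float:
        return self.times[-1]


@dataclass
class ExperimentConfig:
    """Complete, serializable description of one experiment."""

    mech: MechParams = field(default_factory=MechParams)
    cpg: CpgParams = field(default_factory=CpgParams)
    control: ControlParams = field(default_factory=ControlParams)
    speed_map: SpeedParams = field(default_factory=SpeedParams)
    schedule: SpeedSchedule = field(
        default_factory=lambda: SpeedSchedule.constant(1.0)
    )
    duration: float = 15.0
    dt: float = 0.001
    sample_dt: float = 0.005
    seed: int = 0
    transient_time: float = 3.0       # discard at least this ...
    transient_strides: int = 5        # ... and at least this many strides
    label_window_strides: int = 2     # ramp labeling window
    load_threshold: float = DEFAULT_LOAD_THRESHOLD
    phase_tol: float = 0.07           # in-phase vs split tolerance (cycles)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "format_version": TRACE_FORMAT_VERSION,
            "mech": enc(self.mech),
            "cpg": enc(self.cpg),
            "control": enc(self.control),
            "speed": enc(self.speed_map),
            "schedule": enc(self.schedule),
            "run": {
                "duration": self.duration,
                "dt": self.dt,
                "sample_dt": self.sample_dt,
                "seed": self.seed,
                "transient_time": self.transient_time,
                "transient_strides": self.transient_strides,
                "label_window_strides": self.label_window_strides,
                "load_threshold": self.load_threshold,
                "phase_tol": self.phase_tol,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        version = d.get("format_version", TRACE_FORMAT_VERSION)
        if version != TRACE_FORMAT_VERSION:
            raise TraceSchemaError(
                f"config format version {version} != {TRACE_FORMAT_VERSION}"
            )
        ctrl = dict(d["control"])
        for key in ("hip_gains_sw", "hip_gains_st", "len_gains_sw", "len_gains_st"):
            if key in ctrl and isinstance(ctrl[key], dict):
                ctrl[key] = PdGains(**ctrl[key])
        sched = d["schedule"]
        run = d.get("run", {})
        return cls(
            mech=MechParams(**d["mech"]),
            cpg=CpgParams(**d["cpg"]),
            control=ControlParams(**ctrl),
            speed_map=SpeedParams(**d["speed"]),
            schedule=SpeedSchedule(
                tuple(sched["times"]), tuple(sched["speeds"])
            ),
            **run,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ExperimentConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def make_simulator(self) -> Simulator:
        settings = SimulationSettings(
            dt=self.dt, sample_dt=self.sample_dt, seed=self.seed
        )
        return Simulator(
            self.mech, self.cpg, self.control, self.speed_map, settings
        )


@dataclass
class RunResult:
    """Outcome of one simulated experiment."""

    trace: pd.DataFrame
    diagram: FootfallDiagram | None
    labels: list[tuple[float, float, GaitLabel, float]]  # (t0, t1, label, mean v)
    config: ExperimentConfig
    steady: bool = True
    fell: bool = False
    messages: list[str] = field(default_factory=list)

    @property
    def gait(self) -> GaitLabel:
        """The single steady label (last window) or UNKNOWN."""
        return self.labels[-1][2] if self.labels else GaitLabel.UNKNOWN

    @property
    def label_sequence(self) -> list[GaitLabel]:
        """Time-ordered labels with consecutive duplicates merged."""
        seq: list[GaitLabel] = []
        for _, _, lab, _ in self.labels:
            if not seq or seq[-1] is not lab:
                seq.append(lab)
        return seq


def _post_transient(
    trace: pd.DataFrame, config: ExperimentConfig
) -> tuple[pd.DataFrame, FootfallDiagram]:
    """Trace and diagram with the startup transient discarded.

    The transient is the longer of ``transient_time`` and
    ``transient_strides`` reference strides.
    """
    diagram = extract_footfalls(trace, config.load_threshold)
    ons = diagram.onsets(Leg.LF)
    t0 = config.transient_time
    if len(ons) > config.transient_strides:
        t0 = max(t0, float(ons[config.transient_strides]))
    t_abs0 = float(trace["t"].iloc[0])
    steady = trace[trace["t"] >= t_abs0 + t0].reset_index(drop=True)
    if len(steady) < 10:
        raise ValueError("trace too short after transient discard")
    return steady, extract_footfalls(steady, config.load_threshold)


def run_constant_speed(config: ExperimentConfig) -> RunResult:
    """Simulate at a constant speed command and label the steady gait."""
    if len(set(config.schedule.speeds)) != 1:
        raise ValueError("run_constant_speed requires a constant schedule")
    sim = config.make_simulator()
    trace = sim.run(config.duration, config.schedule)
    steady_trace, diagram = _post_transient(trace, config)
    messages: list[str] = []
    steady = True
    try:
        metrics = stride_metrics(diagram)
        label = classify_gait(metrics, config.phase_tol)
    except ValueError as err:
        steady = False
        label = GaitLabel.UNKNOWN
        messages.append(str(err))
        metrics = None
    t0 = float(steady_trace["t"].iloc[0])
    t1 = float(steady_trace["t"].iloc[-1])
    v_mean = float(steady_trace["vx"].mean())
    return RunResult(
        trace=trace,
        diagram=diagram,
        labels=[(t0, t1, label, v_mean)],
        config=config,
        steady=steady,
        messages=messages,
    )


def run_ramp(config: ExperimentConfig) -> RunResult:
    """Simulate a speed ramp and label gaits in overlapping stride windows.

    Windows are ``label_window_strides`` reference strides long with 50%
    overlap; consecutive duplicate labels are merged in
    ``RunResult.label_sequence``.
    """
    if config.duration == 0:
        return RunResult(pd.DataFrame(columns=["t"]), None, [], config)
    sim = config.make_simulator()
    trace = sim.run(config.duration, config.schedule)
    steady_trace, diagram = _post_transient(trace, config)
    ons = diagram.onsets(Leg.LF)
    w = config.label_window_strides
    labels: list[tuple[float, float, GaitLabel, float]] = []
    t_abs0 = float(steady_trace["t"].iloc[0])
    step = max(1, w // 2) if w > 1 else 1
    k = 0
    while k + w < len(ons):
        lo, hi = ons[k], ons[k + w]
        sub = steady_trace[
            (steady_trace["t"] >= t_abs0 + lo - 0.5)
            & (steady_trace["t"] <= t_abs0 + hi + 0.5)
        ]
        try:
            sub_diag = extract_footfalls(sub, config.load_threshold)
            metrics = stride_metrics(sub_diag)
            label = classify_gait(metrics, config.phase_tol)
        except ValueError:
            label = GaitLabel.UNKNOWN
        vs = steady_trace[
            (steady_trace["t"] >= t_abs0 + lo) & (steady_trace["t"] <= t_abs0 + hi)
        ]["vx"].mean()
        labels.append((t_abs0 + lo, t_abs0 + hi, label, float(vs)))
        k += step
    return RunResult(trace=trace, diagram=diagram, labels=labels, config=config)


def speed_sweep(
    config: ExperimentConfig,
    speeds: list[float],
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Steady-gait table over speeds x replicated initial conditions.

    Replicates differ only in the seed of the CPG initial-state jitter,
    which is what selects between bistable outcomes such as the two canter
    leads.  Failed runs (falls, unsteady traces) appear as flagged rows.
    """
    rows = []
    for v in speeds:
        for rep in range(n_replicates):
            cfg = replace(
                config,
                schedule=SpeedSchedule.constant(v),
                seed=config.seed + 101 * rep + 7919 * int(round(1000 * v)) % 100000,
            )
            row = {
                "speed": v,
                "replicate": rep,
                "seed": cfg.seed,
                "gait": None,
                "flight_fraction": np.nan,
                "frequency_ratio": np.nan,
                "mean_speed": np.nan,
                "ok": False,
                "error": "",
            }
            try:
                result = run_constant_speed(cfg)
                steady_trace, diagram = _post_transient(result.trace, cfg)
                metrics = stride_metrics(diagram)
                row["gait"] = result.gait.value
                row["flight_fraction"] = metrics.flight_fraction
                row["mean_speed"] = result.labels[0][3]
                try:
                    fr = body_leg_frequency_ratio(steady_trace, diagram)
                    row["frequency_ratio"] = fr.ratio
                except ValueError as err:
                    row["error"] = f"ratio: {err}"
                row["ok"] = result.steady
            except (FallError, ValueError, FloatingPointError) as err:
                row["error"] = str(err)
            rows.append(row)
    return pd.DataFrame(rows)


# ---- trace I/O ---------------------------------------------------------

def write_trace(result: RunResult, path: str | Path) -> None:
    """Write a run's sampled trace as CSV with embedded config metadata."""
    path = Path(path)
    meta = {
        "format": "quadgait-trace",
        "version": TRACE_FORMAT_VERSION,
        "config_hash": result.config.config_hash(),
        "config": result.config.to_dict(),
    }
    with path.open("w") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        result.trace.to_csv(fh, index=False, float_format="%.17g")


def read_trace(
    path: str | Path, config: ExperimentConfig | None = None
) -> RunResult:
    """Read a trace CSV back into a :class:`RunResult`.

    Verifies the schema; if ``config`` is supplied and its hash differs
    from the embedded one, a warning is issued.  The footfall diagram is
    recomputed from the loaded trace.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise TraceSchemaError("missing metadata header line")
        try:
            meta = json.loads(first[2:])
        except json.JSONDecodeError as err:
            raise TraceSchemaError(f"bad metadata header: {err}") from err
        if meta.get("format") != "quadgait-trace":
            raise TraceSchemaError("not a quadgait trace file")
        if meta.get("version") != TRACE_FORMAT_VERSION:
            raise TraceSchemaError(
                f"trace version {meta.get('version')} != {TRACE_FORMAT_VERSION}"
            )
        trace = pd.read_csv(fh)
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise TraceSchemaError(f"trace is missing columns: {missing}")
    file_config = ExperimentConfig.from_dict(meta["config"])
    if config is not None and config.config_hash() != meta["config_hash"]:
        warnings.warn(
            "provided config hash differs from the one stored in the trace",
            stacklevel=2,
        )
    use_config = config or file_config
    try:
        diagram = extract_footfalls(trace, use_config.load_threshold)
    except ValueError:
        diagram = None
    return RunResult(
        trace=trace, diagram=diagram, labels=[], config=file_config
    )
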