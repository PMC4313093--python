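"""Named experiment configurations (the package's study conditions).

``baseline_config``: the model without leg-loading feedback (k2 = 0).  Its
hard-wired network keeps a trot at every speed command; the body-pitch to
stride frequency ratio is 2 at low speed and 1 at high, flight-bearing
speed.

``gait_generation_config``: the model with the leg-loading feedback
switched on (k2 > 0, with the saturating feed and a mild speed-dependent
push-off).  Under this condition lateral- and diagonal-sequence walks
emerge spontaneously from the trot-wired network at walking speeds.  See
docs/methods.md for what this condition does and does not reproduce.
"""
from __future__ import annotations

from dataclasses import replace

from .experiments import ExperimentConfig
from .leg_control import ControlParams, SpeedParams

__all__ = ["baseline_config", "gait_generation_config"]

#: Load-feedback gain of the gait-generation condition (1/N).
GAIT_GENERATION_K2 = 0.06
#: Saturation of the load feed in that condition (dimensionless).
GAIT_GENERATION_FEED2_CAP = 2.0
#: Push-off preload slope in that condition (m per m/s).
GAIT_GENERATION_PUSH_GAIN = 0.012


def baseline_config(**overrides) -> ExperimentConfig:
    """Model without leg-loading feedback (k2 = 0); trots at every speed."""
    return ExperimentConfig(**overrides)


def gait_generation_config(**overrides) -> ExperimentConfig:
    """Model with the tuned leg-loading feedback; non-trot gaits emerge."""
    cfg = ExperimentConfig(**overrides)
    return replace(
        cfg,
        control=replace(
            cfg.control,
            k2=GAIT_GENERATION_K2,
            feed2_cap=GAIT_GENERATION_FEED2_CAP,
        ),
        speed_map=replace(cfg.speed_map, push_gain=GAIT_GENERATION_PUSH_GAIN),
    )
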