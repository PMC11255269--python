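"""Run configuration shared by all pipeline stages.

Timing conventions: frame 0 is stimulus onset, windows are half-open
``[start, end)`` in seconds, and a time ``t`` maps to frame
``t0_frame + floor(t * frame_rate)``.  The task is a 1-s tone followed by a
2-s response window; fluorescence is recorded at 30 frames/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

SESSION_NAMES = ("Stable", "Uncertain", "Reversal", "Re-stable")

#: Trial-type composition of each session.  Stable and Re-stable interleave
#: go/no-go 50/50; the Uncertain session adds 10% reward-omission (RO) and
#: 10% un-cued-reward (UR) trials; Reversal is 50/50 with the tone-outcome
#: contingency swapped.
DEFAULT_SESSION_DESIGNS: dict[str, dict[str, float]] = {
    "Stable": {"go": 0.5, "nogo": 0.5},
    "Uncertain": {"go": 0.40, "nogo": 0.40, "RO": 0.10, "UR": 0.10},
    "Reversal": {"go": 0.5, "nogo": 0.5},
    "Re-stable": {"go": 0.5, "nogo": 0.5},
}

#: Within-session phase fractions (T1..T3).  Reversal uses 15/35/50 because
#: behavioral switching concentrates in the earliest trials; the other
#: sessions split into thirds.
DEFAULT_PHASE_FRACTIONS: dict[str, tuple[float, ...]] = {
    "Stable": (1 / 3, 1 / 3, 1 / 3),
    "Uncertain": (1 / 3, 1 / 3, 1 / 3),
    "Reversal": (0.15, 0.35, 0.50),
    "Re-stable": (1 / 3, 1 / 3, 1 / 3),
}

#: Early/late period split used by the functional classification: Uncertain
#: compares the first 67% against the last 33% of trials, Reversal the first
#: 15% against the last 85%.
DEFAULT_EARLY_FRACTIONS: dict[str, float] = {
    "Stable": 2 / 3,
    "Uncertain": 2 / 3,
    "Reversal": 0.15,
    "Re-stable": 2 / 3,
}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    frame_rate: float = 30.0
    stimulus_window: tuple[float, float] = (0.0, 1.0)
    response_window: tuple[float, float] = (1.0, 3.0)
    baseline_dff: tuple[float, float] = (-2.0, 0.0)
    baseline_z: tuple[float, float] = (-0.5, 0.0)
    session_designs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SESSION_DESIGNS.items()}
    )
    phase_fractions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS)
    )
    n_trials: int = 100
    n_neurons: int = 200
    output_dir: str = "accvi_out"

    def __post_init__(self) -> None:
        for name in ("stimulus_window", "response_window", "baseline_dff", "baseline_z"):
            lo, hi = getattr(self, name)
            if not (lo < hi and abs(lo) < 1e6 and abs(hi) < 1e6):
                raise ConfigError(f"{name} must be a finite (start, end) with start < end")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        for session, props in self.session_designs.items():
            if session not in SESSION_NAMES:
                raise ConfigError(f"unknown session name: {session!r}")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"proportions for {session} sum to {total}, expected 1")
        for session, fracs in self.phase_fractions.items():
            if session not in SESSION_NAMES:
                raise ConfigError(f"unknown session name: {session!r}")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ConfigError(f"phase fractions for {session} must sum to 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("stimulus_window", "response_window", "baseline_dff", "baseline_z"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "phase_fractions" in raw:
            raw["phase_fractions"] = {k: tuple(v) for k, v in raw["phase_fractions"].items()}
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def time_to_frame(t: float, frame_rate: float, t0_frame: int) -> int:
    """Map a time in seconds (0 = event) to a frame index."""
    import math

    return t0_frame + math.floor(t * frame_rate)


def frame_times(n_frames: int, frame_rate: float, t0_frame: int):
    """Times (s) of each frame relative to the alignment event."""
    import numpy as np

    return (np.arange(n_frames) - t0_frame) / frame_rate
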