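"""Optogenetic stimulation schedules.

The training regimen used throughout is 5 ms light pulses at 20 Hz for one
second, every other second — i.e. a 1 s-on / 1 s-off duty cycle with a 2 s
period. A one-hour regimen therefore comprises 1,800 cycles (36,000 pulses).
During recordings the same pattern is applied in short blocks of 10 cycles
placed at equidistant times.

Pulse times are computed from integer cycle and pulse indices (never from a
running sum), so schedules are exact and independent of floating-point
accumulation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .types import Epoch, EpochSet

__all__ = [
    "StimulationProtocol",
    "RecordingStimPlan",
    "build_training_protocol",
    "pulse_onsets",
    "build_recording_plan",
    "epochs_from_plan",
]

# Training-regimen defaults: 5 ms pulses, 20 Hz, 1 s on, 2 s cycle period.
DEFAULT_PULSE_WIDTH_S = 0.005
DEFAULT_PULSE_RATE_HZ = 20.0
DEFAULT_ON_DURATION_S = 1.0
DEFAULT_CYCLE_PERIOD_S = 2.0


@dataclass(frozen=True)
class StimulationProtocol:
    """A pulsed-light schedule: n_cycles repetitions of an on/off cycle."""

    n_cycles: int
    pulse_width_s: float = DEFAULT_PULSE_WIDTH_S
    pulse_rate_hz: float = DEFAULT_PULSE_RATE_HZ
    on_duration_s: float = DEFAULT_ON_DURATION_S
    cycle_period_s: float = DEFAULT_CYCLE_PERIOD_S
    block_start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cycles < 0:
            raise ValidationError("n_cycles must be non-negative")
        if self.pulse_width_s > 1.0 / self.pulse_rate_hz + 1e-12:
            raise ValidationError("pulse width exceeds the inter-pulse interval")
        if self.on_duration_s > self.cycle_period_s + 1e-12:
            raise ValidationError("on-duration exceeds the cycle period")
        for name in ("pulse_width_s", "pulse_rate_hz", "on_duration_s", "cycle_period_s"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def pulses_per_cycle(self) -> int:
        return int(round(self.pulse_rate_hz * self.on_duration_s))

    @property
    def n_pulses(self) -> int:
        return self.n_cycles * self.pulses_per_cycle

    @property
    def total_duration_s(self) -> float:
        return self.n_cycles * self.cycle_period_s

    @property
    def block_end_s(self) -> float:
        return self.block_start_s + self.total_duration_s

    def to_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "pulse_width_s": self.pulse_width_s,
            "pulse_rate_hz": self.pulse_rate_hz,
            "on_duration_s": self.on_duration_s,
            "cycle_period_s": self.cycle_period_s,
            "block_start_s": self.block_start_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        return cls(**d)


def build_training_protocol(duration_s: float, **overrides) -> StimulationProtocol:
    """Training regimen over ``duration_s``: n_cycles = floor(duration / period).

    A one-hour session (3600 s at the default 2 s period) yields 1,800 cycles.
    """
    if not duration_s > 0:
        raise ValidationError("duration_s must be positive")
    period = overrides.get("cycle_period_s", DEFAULT_CYCLE_PERIOD_S)
    return StimulationProtocol(n_cycles=int(math.floor(duration_s / period)), **overrides)


def pulse_onsets(protocol: StimulationProtocol) -> np.ndarray:
    """All pulse intervals as an ``[n_pulses, 2]`` array of (start_s, end_s).

    start = block_start + cycle*period + pulse_index/pulse_rate, computed from
    integer indices.
    """
    ppc = protocol.pulses_per_cycle
    if protocol.n_cycles == 0 or ppc == 0:
        return np.empty((0, 2))
    cycles = np.repeat(np.arange(protocol.n_cycles), ppc)
    pulses = np.tile(np.arange(ppc), protocol.n_cycles)
    starts = (
        protocol.block_start_s
        + cycles * protocol.cycle_period_s
        + pulses / protocol.pulse_rate_hz
    )
    return np.column_stack([starts, starts + protocol.pulse_width_s])


@dataclass(frozen=True)
class RecordingStimPlan:
    """Stimulation blocks placed inside one recording session."""

    blocks: tuple[StimulationProtocol, ...]
    recording_duration_s: float

    def __post_init__(self) -> None:
        if not self.recording_duration_s > 0:
            raise ValidationError("recording_duration_s must be positive")
        blocks = tuple(sorted(self.blocks, key=lambda b: b.block_start_s))
        object.__setattr__(self, "blocks", blocks)
        for b in blocks:
            if b.block_start_s < 0 or b.block_end_s > self.recording_duration_s:
                raise ValidationError("stimulation block extends outside the recording")
        for a, b in zip(blocks, blocks[1:]):
            if b.block_start_s < a.block_end_s:
                raise ValidationError("stimulation blocks overlap")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_intervals(self) -> list[tuple[float, float]]:
        return [(b.block_start_s, b.block_end_s) for b in self.blocks]

    def all_pulses(self) -> np.ndarray:
        if not self.blocks:
            return np.empty((0, 2))
        return np.vstack([pulse_onsets(b) for b in self.blocks])

    def to_dict(self) -> dict:
        return {
            "recording_duration_s": self.recording_duration_s,
            "blocks": [b.to_dict() for b in self.blocks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingStimPlan":
        return cls(
            blocks=tuple(StimulationProtocol.from_dict(b) for b in d["blocks"]),
            recording_duration_s=float(d["recording_duration_s"]),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "RecordingStimPlan":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_recording_plan(
    recording_duration_s: float,
    n_blocks: int = 3,
    cycles_per_block: int = 10,
    block_starts_s: list[float] | None = None,
    **protocol_overrides,
) -> RecordingStimPlan:
    """Place ``n_blocks`` stimulation blocks inside a recording.

    By default block centers sit at fractions (k+1)/(n_blocks+1) of the
    recording, which leaves a leading stimulation-free spontaneous segment.
    Explicit ``block_starts_s`` override the placement.
    """
    proto = StimulationProtocol(n_cycles=cycles_per_block, **protocol_overrides)
    block_len = proto.total_duration_s
    if block_starts_s is None:
        block_starts_s = [
            (k + 1) * recording_duration_s / (n_blocks + 1) - block_len / 2.0
            for k in range(n_blocks)
        ]
    blocks = tuple(replace(proto, block_start_s=float(s)) for s in block_starts_s)
    return RecordingStimPlan(blocks=blocks, recording_duration_s=recording_duration_s)


def epochs_from_plan(
    plan: RecordingStimPlan, pre_window_s: float, post_window_s: float
) -> EpochSet:
    """Pre/stim/post epoch triplets per block, plus a leading spontaneous epoch.

    For a block ``[s, e)``: pre = ``[s - pre_window, s)``, stim = ``[s, e)``,
    post = ``[e, e + post_window)``. Windows must not collide with adjacent
    blocks or the recording boundaries.
    """
    if not (pre_window_s > 0 and post_window_s > 0):
        raise ValidationError("pre and post windows must be positive")
    epochs: list[Epoch] = []
    intervals = plan.block_intervals()
    for k, (s, e) in enumerate(intervals):
        pre_start = s - pre_window_s
        post_end = e + post_window_s
        if pre_start < 0:
            raise ValidationError("pre window extends before the recording start")
        if post_end > plan.recording_duration_s:
            raise ValidationError("post window extends beyond the recording end")
        if k > 0 and pre_start < intervals[k - 1][1] + post_window_s:
            raise ValidationError("pre window collides with the previous block's post window")
        epochs.append(Epoch("pre", pre_start, s, block=k))
        epochs.append(Epoch("stim", s, e, block=k))
        epochs.append(Epoch("post", e, post_end, block=k))
    if intervals:
        first_pre = intervals[0][0] - pre_window_s
        if first_pre > 0:
            epochs.insert(0, Epoch("spontaneous", 0.0, first_pre))
    else:
        epochs.append(Epoch("spontaneous", 0.0, plan.recording_duration_s))
    return EpochSet(epochs)
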