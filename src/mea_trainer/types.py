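"""Core in-memory containers for MEA recordings and derived spike data.

Units are seconds for time and microvolts for voltage everywhere in the
package; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "ElectrodeLayout",
    "RawRecording",
    "SpikeTrainSet",
    "Epoch",
    "EpochSet",
    "standard_layout",
]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Ordered electrode labels with grid coordinates and an optional ground.

    Parameters
    ----------
    electrode_ids
        Unique string labels, in acquisition column order.
    grid_positions
        One ``(row, col)`` integer pair per electrode; unique.
    ground_id
        Label of the ground electrode, if the array has one. Must be a member
        of ``electrode_ids``; the ground channel carries noise and artifacts
        but no biological spikes and is used for threshold calibration.
    """

    electrode_ids: tuple[str, ...]
    grid_positions: tuple[tuple[int, int], ...]
    ground_id: str | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(e) for e in self.electrode_ids)
        pos = tuple((int(r), int(c)) for r, c in self.grid_positions)
        object.__setattr__(self, "electrode_ids", ids)
        object.__setattr__(self, "grid_positions", pos)
        if len(set(ids)) != len(ids):
            raise ValidationError("electrode ids must be unique")
        if len(pos) != len(ids):
            raise ValidationError("one grid position per electrode required")
        if len(set(pos)) != len(pos):
            raise ValidationError("grid positions must be unique")
        if self.ground_id is not None and self.ground_id not in ids:
            raise ValidationError(f"ground electrode {self.ground_id!r} not in layout")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def index_of(self, electrode_id: str) -> int:
        try:
            return self.electrode_ids.index(electrode_id)
        except ValueError:
            raise ValidationError(f"unknown electrode id {electrode_id!r}") from None

    def recording_ids(self) -> tuple[str, ...]:
        """Electrode ids excluding the ground channel."""
        return tuple(e for e in self.electrode_ids if e != self.ground_id)

    def to_dict(self) -> dict:
        return {
            "electrode_ids": list(self.electrode_ids),
            "grid_positions": [list(p) for p in self.grid_positions],
            "ground_id": self.ground_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ElectrodeLayout":
        return cls(
            electrode_ids=tuple(d["electrode_ids"]),
            grid_positions=tuple(tuple(p) for p in d["grid_positions"]),
            ground_id=d.get("ground_id"),
        )


def standard_layout(n_electrodes: int = 60, ground_id: str | None = None) -> ElectrodeLayout:
    """Build a conventional planar MEA layout.

    For ``n_electrodes == 60`` this is the classic 8x8 grid with the four
    corners omitted; otherwise electrodes fill a near-square grid row-major.
    If ``ground_id`` is given, an extra ground channel is appended at a spare
    grid position.
    """
    if n_electrodes == 60:
        pos = [
            (r, c)
            for r in range(8)
            for c in range(8)
            if (r, c) not in {(0, 0), (0, 7), (7, 0), (7, 7)}
        ]
    else:
        side = int(np.ceil(np.sqrt(n_electrodes)))
        pos = [(k // side, k % side) for k in range(n_electrodes)]
    ids = [f"E{k + 1}" for k in range(n_electrodes)]
    if ground_id is not None:
        ids.append(ground_id)
        max_row = max(r for r, _ in pos)
        pos.append((max_row + 1, 0))
    return ElectrodeLayout(tuple(ids), tuple(pos), ground_id=ground_id)


@dataclass
class RawRecording:
    """Multichannel extracellular voltage matrix.

    ``samples`` is ``[n_samples, n_electrodes]`` in microvolts, one column per
    electrode in layout order.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    layout: ElectrodeLayout
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D [n_samples, n_electrodes] matrix")
        if self.samples.shape[0] < 1:
            raise ValidationError("recording must contain at least one sample")
        if self.samples.shape[1] != self.layout.n_electrodes:
            raise ValidationError(
                f"sample matrix has {self.samples.shape[1]} columns but layout "
                f"declares {self.layout.n_electrodes} electrodes"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def channel(self, electrode_id: str) -> np.ndarray:
        return self.samples[:, self.layout.index_of(electrode_id)]


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike timestamps over a fixed recording length.

    Every electrode in the layout has an entry (possibly empty). Timestamps
    are seconds in ``[0, duration_s]``, strictly increasing within a train.
    """

    trains: dict[str, np.ndarray]
    duration_s: float
    layout: ElectrodeLayout

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be positive")
        clean: dict[str, np.ndarray] = {}
        for eid in self.layout.electrode_ids:
            t = np.asarray(self.trains.get(eid, ()), dtype=float).ravel()
            if t.size:
                if np.any(np.diff(t) <= 0):
                    raise ValidationError(f"spike train {eid!r} is not strictly increasing")
                if t[0] < 0 or t[-1] > self.duration_s:
                    raise ValidationError(
                        f"spike train {eid!r} has timestamps outside [0, {self.duration_s}]"
                    )
            clean[eid] = t
        unknown = set(self.trains) - set(self.layout.electrode_ids)
        if unknown:
            raise ValidationError(f"spike trains for electrodes not in layout: {sorted(unknown)}")
        self.trains = clean

    def __getitem__(self, electrode_id: str) -> np.ndarray:
        return self.trains[electrode_id]

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def counts(self) -> dict[str, int]:
        return {e: int(t.size) for e, t in self.trains.items()}

    def subset(self, electrode_ids: Iterable[str]) -> "SpikeTrainSet":
        """Restrict to a subset of electrodes (layout order preserved)."""
        keep = set(electrode_ids)
        for e in keep:
            self.layout.index_of(e)  # validates membership
        ids = tuple(e for e in self.layout.electrode_ids if e in keep)
        pos = tuple(
            self.layout.grid_positions[self.layout.index_of(e)] for e in ids
        )
        ground = self.layout.ground_id if self.layout.ground_id in keep else None
        sub_layout = ElectrodeLayout(ids, pos, ground_id=ground)
        return SpikeTrainSet(
            {e: self.trains[e] for e in ids}, self.duration_s, sub_layout
        )


_EPOCH_LABELS = {"pre", "stim", "post", "spontaneous", "custom"}


@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    end_s: float
    block: int | None = None

    def __post_init__(self) -> None:
        if self.label not in _EPOCH_LABELS:
            raise ValidationError(f"epoch label must be one of {sorted(_EPOCH_LABELS)}")
        if not self.start_s < self.end_s:
            raise ValidationError("epoch start must precede end")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Half-open membership [start, end)."""
        t = np.asarray(t)
        return (t >= self.start_s) & (t < self.end_s)


@dataclass
class EpochSet:
    """Labelled analysis windows; same-label epochs may not overlap."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_label: dict[str, list[Epoch]] = {}
        for ep in self.epochs:
            by_label.setdefault(ep.label, []).append(ep)
        for label, eps in by_label.items():
            eps = sorted(eps, key=lambda e: e.start_s)
            for a, b in zip(eps, eps[1:]):
                if b.start_s < a.end_s:
                    raise ValidationError(f"overlapping {label!r} epochs")

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    def with_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]

    def blocks(self) -> list[int]:
        return sorted({e.block for e in self.epochs if e.block is not None})
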