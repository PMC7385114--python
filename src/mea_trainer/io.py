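"""Readers and writers for raw recordings, spike tables, and result tables.

Raw traces travel as delimited ASCII (time column + one microvolt column per
electrode, mirroring typical acquisition-software exports) or as a compact
HDF5 container (``/raw`` int16 with a microvolt scale-factor attribute,
``/meta`` JSON). Spike tables are plain CSV ``electrode_id,time_s``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import ElectrodeLayout, RawRecording, SpikeTrainSet

__all__ = [
    "read_raw_ascii",
    "write_raw_ascii",
    "read_raw_hdf5",
    "write_raw_hdf5",
    "read_spike_csv",
    "write_spike_csv",
    "write_results_table",
    "read_results_table",
]

_TIME_TOL_S = 1e-6


def read_raw_ascii(path, sampling_rate_hz: float, layout: ElectrodeLayout) -> RawRecording:
    """Read a delimited text export: first column seconds, then microvolts.

    Accepts comma or tab/whitespace delimiters and ``#`` comment headers. The
    time column must be uniform to within 1 microsecond and consistent with
    ``sampling_rate_hz``.
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    except ValueError:
        try:
            data = np.loadtxt(path, comments="#", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"could not parse {path} as delimited text: {exc}") from None
    if data.shape[1] != layout.n_electrodes + 1:
        raise FormatError(
            f"{path} has {data.shape[1]} columns; expected time + "
            f"{layout.n_electrodes} electrode columns"
        )
    t = data[:, 0]
    if t.size > 1:
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > _TIME_TOL_S):
            raise FormatError(f"{path}: time column is not uniformly sampled")
        if abs(dt[0] - 1.0 / sampling_rate_hz) > _TIME_TOL_S:
            raise FormatError(
                f"{path}: time step {dt[0]:.6g} s inconsistent with "
                f"sampling rate {sampling_rate_hz} Hz"
            )
    return RawRecording(
        samples=data[:, 1:],
        sampling_rate_hz=sampling_rate_hz,
        layout=layout,
        t0_s=float(t[0]) if t.size else 0.0,
    )


def write_raw_ascii(recording: RawRecording, path, delimiter: str = ",") -> None:
    path = Path(path)
    header = "time_s" + delimiter + delimiter.join(
        f"{e}_uV" for e in recording.layout.electrode_ids
    )
    out = np.column_stack([recording.times(), recording.samples])
    np.savetxt(path, out, delimiter=delimiter, header=header, fmt="%.9g")


def write_raw_hdf5(recording: RawRecording, path) -> None:
    """Store as int16 with a microvolt scale factor chosen from the data range."""
    peak = float(np.max(np.abs(recording.samples))) if recording.samples.size else 0.0
    scale = max(peak / 32000.0, 1e-6)  # microvolts per integer count
    with h5py.File(Path(path), "w") as f:
        ds = f.create_dataset(
            "raw",
            data=np.round(recording.samples / scale).astype(np.int16),
            compression="gzip",
        )
        ds.attrs["scale_uv"] = scale
        meta = {
            "sampling_rate_hz": recording.sampling_rate_hz,
            "t0_s": recording.t0_s,
            "layout": recording.layout.to_dict(),
            "units": {"time": "s", "voltage": "uV"},
        }
        f.create_dataset("meta", data=json.dumps(meta))


def read_raw_hdf5(path) -> RawRecording:
    with h5py.File(Path(path), "r") as f:
        if "raw" not in f or "meta" not in f:
            raise FormatError(f"{path} is missing /raw or /meta")
        meta = json.loads(f["meta"][()])
        samples = f["raw"][()].astype(float) * float(f["raw"].attrs["scale_uv"])
    return RawRecording(
        samples=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        layout=ElectrodeLayout.from_dict(meta["layout"]),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


def read_spike_csv(path, duration_s: float, layout: ElectrodeLayout) -> SpikeTrainSet:
    """Read ``electrode_id,time_s`` rows; absent electrodes get empty trains."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"electrode_id", "time_s"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} must have columns {sorted(required)}")
    trains: dict[str, list[float]] = {e: [] for e in layout.electrode_ids}
    for eid, t in zip(df["electrode_id"].astype(str), df["time_s"].astype(float)):
        if eid not in trains:
            raise ValidationError(f"{path}: unknown electrode id {eid!r}")
        if not (0.0 <= t <= duration_s):
            raise ValidationError(
                f"{path}: spike time {t} outside [0, {duration_s}] for {eid!r}"
            )
        trains[eid].append(t)
    return SpikeTrainSet(
        {e: np.unique(np.asarray(ts)) for e, ts in trains.items()},
        duration_s=duration_s,
        layout=layout,
    )


def write_spike_csv(spikes: SpikeTrainSet, path) -> None:
    rows = [
        {"electrode_id": e, "time_s": float(t)}
        for e in spikes.layout.electrode_ids
        for t in spikes.trains[e]
    ]
    pd.DataFrame(rows, columns=["electrode_id", "time_s"]).to_csv(
        Path(path), index=False, float_format="%.9f"
    )


def write_results_table(records: Sequence[Mapping], path) -> None:
    """Write tidy result rows sharing one schema to CSV.

    Numeric fields round-trip at 12 significant digits. Zero records produce a
    header-only file when the schema can be inferred, otherwise an empty file
    with the canonical header.
    """
    path = Path(path)
    if not records:
        pd.DataFrame(columns=["metric", "value"]).to_csv(path, index=False)
        return
    schema = tuple(records[0].keys())
    for r in records:
        if tuple(r.keys()) != schema:
            raise ValidationError("result records do not share a common schema")
    pd.DataFrame(list(records), columns=list(schema)).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
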