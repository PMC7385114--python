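"""Evoked-response metrics around in-recording stimulation blocks.

For each block, firing rates are computed over pre/stim/post epochs
(FR_pre, FR_stim, FR_post, spikes/s averaged over the analyzed electrodes)
and summarized as the ratios FR_stim/FR_pre and FR_post/FR_pre. The
post-stimulation quiescence duration is the time from block end until the
pooled network rate first recovers to a configurable fraction (default 50 %)
of the pre-stimulation baseline, measured in 1 s smoothing bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import EpochSet, SpikeTrainSet

__all__ = ["EvokedResponseRecord", "evoked_rates", "quiescence_duration"]


@dataclass(frozen=True)
class EvokedResponseRecord:
    """Per-block firing rates and ratios; ratios are NaN when FR_pre is 0."""

    block: int
    fr_pre_hz: float
    fr_stim_hz: float
    fr_post_hz: float
    ratio_stim: float
    ratio_post: float
    quiescence_s: float | None = None

    @property
    def defined(self) -> bool:
        return self.fr_pre_hz > 0


def _epoch_rate(
    spikes: SpikeTrainSet, electrode_ids: Sequence[str], start: float, end: float
) -> float:
    """Mean spikes/s per electrode over the subset (half-open interval)."""
    length = end - start
    counts = [
        int(np.count_nonzero((spikes.trains[e] >= start) & (spikes.trains[e] < end)))
        for e in electrode_ids
    ]
    return float(np.mean(counts)) / length


def evoked_rates(
    spikes: SpikeTrainSet, epochs: EpochSet, electrode_ids: Sequence[str] | None = None
) -> tuple[list[EvokedResponseRecord], pd.DataFrame]:
    """One record per stimulation block, plus the per-electrode rate table."""
    if electrode_ids is None:
        electrode_ids = spikes.layout.recording_ids()
    electrode_ids = list(electrode_ids)
    if not electrode_ids:
        raise ValidationError("electrode subset is empty")

    per_rows = []
    records: list[EvokedResponseRecord] = []
    for block in epochs.blocks():
        by_label = {}
        for ep in epochs:
            if ep.block == block and ep.label in {"pre", "stim", "post"}:
                by_label[ep.label] = ep
        if set(by_label) != {"pre", "stim", "post"}:
            raise ValidationError(f"block {block} lacks a full pre/stim/post triplet")
        rates = {}
        for label, ep in by_label.items():
            rates[label] = _epoch_rate(spikes, electrode_ids, ep.start_s, ep.end_s)
            for e in electrode_ids:
                t = spikes.trains[e]
                n = int(np.count_nonzero((t >= ep.start_s) & (t < ep.end_s)))
                per_rows.append(
                    {
                        "block": block,
                        "label": label,
                        "electrode_id": e,
                        "count": n,
                        "rate_hz": n / ep.length_s,
                    }
                )
        pre, stim, post = rates["pre"], rates["stim"], rates["post"]
        defined = pre > 0
        records.append(
            EvokedResponseRecord(
                block=block,
                fr_pre_hz=pre,
                fr_stim_hz=stim,
                fr_post_hz=post,
                ratio_stim=stim / pre if defined else float("nan"),
                ratio_post=post / pre if defined else float("nan"),
            )
        )
    return records, pd.DataFrame(per_rows)


def quiescence_duration(
    spikes: SpikeTrainSet,
    block: tuple[float, float],
    fr_pre_hz: float,
    electrode_ids: Sequence[str] | None = None,
    smoothing_bin_s: float = 1.0,
    recovery_fraction: float = 0.5,
    cap_s: float | None = None,
) -> tuple[float, bool]:
    """Time from block end until the network rate recovers to baseline.

    The pooled per-electrode rate is evaluated in ``smoothing_bin_s`` bins
    after the block end; quiescence ends at the start of the first bin whose
    rate reaches ``recovery_fraction * fr_pre_hz`` (0 if the first bin already
    qualifies). The search is capped at ``cap_s`` after the block end (default:
    recording end, or the next block's pre-window when the caller passes it);
    returns ``(duration_s, capped_flag)``.
    """
    if not fr_pre_hz > 0:
        raise ValidationError("fr_pre_hz must be positive")
    if electrode_ids is None:
        electrode_ids = spikes.layout.recording_ids()
    electrode_ids = list(electrode_ids)
    _, block_end = block
    horizon = spikes.duration_s - block_end if cap_s is None else cap_s
    n_bins = int(horizon // smoothing_bin_s)
    if n_bins < 1:
        raise ValidationError("no room for a single smoothing bin after the block")
    target = recovery_fraction * fr_pre_hz
    for k in range(n_bins):
        s = block_end + k * smoothing_bin_s
        r = _epoch_rate(spikes, electrode_ids, s, s + smoothing_bin_s)
        if r >= target:
            return k * smoothing_bin_s, False
    return n_bins * smoothing_bin_s, True
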