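"""Network synchrony via zero-lag cross-correlation of binned spike trains.

For electrodes x and y with binned count series f and g, the discrete
cross-correlation (f*g)[n] = sum_m f[m] g[m+n] is normalized so each
autocorrelation has unit value at zero lag; the zero-lag value

    chi(x, y) = sum_m f[m] g[m] / sqrt(sum f[m]^2 * sum g[m]^2)

is stored in an N x N matrix (60 x 60 for a full array). chi lies in [0, 1]
for count series by Cauchy-Schwarz and non-negativity. The per-electrode mean
(self excluded) maps onto the array geometry; the culture mean (chi-bar) is
the average over off-diagonal pairs. A time-resolved variant evaluates the
matrix in consecutive 10 s segments, from which pre/post stimulation ratios
(chi_post / chi_pre) are formed.

Silent (all-zero) trains produce missing values, not zeros, so inactive
electrodes do not deflate the network average. The default 50 ms bin matches
the burst-onset timescale, so co-participation in network bursts (not
millisecond coincidence) drives chi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .spectral import bin_spikes
from .types import ElectrodeLayout, SpikeTrainSet

__all__ = [
    "SynchronyConfig",
    "SynchronyMatrix",
    "zero_lag_correlation",
    "synchrony_matrix",
    "spatial_map",
    "timecourse_synchrony",
    "pre_post_ratio",
]


@dataclass(frozen=True)
class SynchronyConfig:
    bin_width_s: float = 0.050
    segment_s: float = 10.0
    use_active_only: bool = True
    exclude_self: bool = True
    mean_subtract: bool = False

    def __post_init__(self) -> None:
        if not self.bin_width_s > 0:
            raise ValidationError("bin_width_s must be positive")
        ratio = self.segment_s / self.bin_width_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("segment_s must be a multiple of bin_width_s")


@dataclass
class SynchronyMatrix:
    """Symmetric zero-lag correlation matrix with its summary means."""

    values: np.ndarray  # [n, n], NaN where undefined
    electrode_ids: tuple[str, ...]
    mean_per_electrode: np.ndarray  # chi-bar_e, self excluded
    mean: float  # culture chi-bar over off-diagonal pairs

    @property
    def n(self) -> int:
        return len(self.electrode_ids)


def zero_lag_correlation(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Normalized zero-lag cross-correlation of two count series.

    Returns NaN (missing, not zero) when either series is all-zero, since the
    normalization is undefined there.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("count series must be 1-D and of equal length")
    na, nb = np.dot(a, a), np.dot(b, b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.dot(a, b) / np.sqrt(na * nb))


def _binned_matrix(
    spikes: SpikeTrainSet,
    electrode_ids: Sequence[str],
    bin_width_s: float,
    interval: tuple[float, float],
) -> np.ndarray:
    start, end = interval
    if not (0.0 <= start < end <= spikes.duration_s + 1e-9):
        raise ValidationError("interval must lie within the recording")
    rows = []
    for eid in electrode_ids:
        t = spikes.trains[eid]
        t = t[(t >= start) & (t < end)] - start
        rows.append(bin_spikes(t, bin_width_s, end - start))
    return np.asarray(rows)


def _chi_matrix(counts: np.ndarray, mean_subtract: bool) -> np.ndarray:
    c = counts - counts.mean(axis=1, keepdims=True) if mean_subtract else counts
    sq = np.sum(c * c, axis=1)
    chi = np.full((c.shape[0], c.shape[0]), np.nan)
    ok = sq > 0
    if ok.any():
        sub = c[ok]
        # counts are integer-valued, so the inner products are exact and the
        # result matches a direct evaluation of the definition bit-for-bit
        m = (sub @ sub.T) / np.sqrt(np.outer(sq[ok], sq[ok]))
        np.fill_diagonal(m, 1.0)
        chi[np.ix_(ok, ok)] = m
    return chi


def _summaries(chi: np.ndarray, exclude_self: bool) -> tuple[np.ndarray, float]:
    n = chi.shape[0]
    off = chi.copy()
    if exclude_self:
        np.fill_diagonal(off, np.nan)
    per_e = np.array(
        [np.nanmean(row) if np.any(~np.isnan(row)) else np.nan for row in off]
    )
    iu = np.triu_indices(n, k=1)
    upper = chi[iu]
    mean = float(np.nanmean(upper)) if np.any(~np.isnan(upper)) else float("nan")
    return per_e, mean


def synchrony_matrix(
    spikes: SpikeTrainSet,
    electrode_ids: Sequence[str] | None = None,
    config: SynchronyConfig = SynchronyConfig(),
    interval: tuple[float, float] | None = None,
) -> SynchronyMatrix:
    """Zero-lag correlation matrix over an electrode subset and time interval."""
    if electrode_ids is None:
        electrode_ids = spikes.layout.recording_ids()
    electrode_ids = tuple(electrode_ids)
    if len(electrode_ids) < 2:
        raise ValidationError("synchrony needs at least two electrodes")
    if interval is None:
        interval = (0.0, spikes.duration_s)
    counts = _binned_matrix(spikes, electrode_ids, config.bin_width_s, interval)
    chi = _chi_matrix(counts, config.mean_subtract)
    per_e, mean = _summaries(chi, config.exclude_self)
    return SynchronyMatrix(
        values=chi, electrode_ids=electrode_ids, mean_per_electrode=per_e, mean=mean
    )


def spatial_map(matrix: SynchronyMatrix, layout: ElectrodeLayout) -> np.ndarray:
    """Per-electrode mean chi placed at its grid position; NaN elsewhere."""
    rows = [layout.grid_positions[layout.index_of(e)] for e in matrix.electrode_ids]
    max_r = max(r for r, _ in rows)
    max_c = max(c for _, c in rows)
    grid = np.full((max_r + 1, max_c + 1), np.nan)
    for (r, c), v in zip(rows, matrix.mean_per_electrode):
        grid[r, c] = v
    return grid


def timecourse_synchrony(
    spikes: SpikeTrainSet,
    electrode_ids: Sequence[str] | None = None,
    config: SynchronyConfig = SynchronyConfig(),
) -> dict:
    """Synchrony evaluated on consecutive non-overlapping segments.

    Returns segment start times, the culture chi-bar series, and the
    per-electrode chi-bar raster ``[n_electrodes, n_segments]``. Segments with
    no spikes anywhere are missing (NaN).
    """
    if electrode_ids is None:
        electrode_ids = spikes.layout.recording_ids()
    electrode_ids = tuple(electrode_ids)
    n_segments = int(spikes.duration_s // config.segment_s)
    if n_segments < 1:
        raise ValidationError("recording shorter than one segment")
    starts = np.arange(n_segments) * config.segment_s
    series = np.full(n_segments, np.nan)
    raster = np.full((len(electrode_ids), n_segments), np.nan)
    for k, s in enumerate(starts):
        m = synchrony_matrix(
            spikes, electrode_ids, config, interval=(float(s), float(s + config.segment_s))
        )
        series[k] = m.mean
        raster[:, k] = m.mean_per_electrode
    return {
        "segment_starts_s": starts,
        "segment_s": config.segment_s,
        "chi_series": series,
        "electrode_ids": electrode_ids,
        "chi_raster": raster,
    }


def pre_post_ratio(
    timecourse: dict, stim_block: tuple[float, float], window_s: float
) -> dict:
    """chi_post / chi_pre around one stimulation block.

    chi_pre averages segments wholly inside [block_start - window,
    block_start); chi_post averages segments wholly inside [block_end,
    block_end + window). The ratio is flagged undefined when chi_pre is
    missing or zero.
    """
    starts = np.asarray(timecourse["segment_starts_s"], dtype=float)
    seg = float(timecourse["segment_s"])
    series = np.asarray(timecourse["chi_series"], dtype=float)
    b0, b1 = stim_block
    pre_mask = (starts >= b0 - window_s - 1e-9) & (starts + seg <= b0 + 1e-9)
    post_mask = (starts >= b1 - 1e-9) & (starts + seg <= b1 + window_s + 1e-9)
    if not pre_mask.any() or not post_mask.any():
        raise ValidationError("window does not cover a full segment on each side")
    chi_pre = float(np.nanmean(series[pre_mask])) if np.any(~np.isnan(series[pre_mask])) else float("nan")
    chi_post = float(np.nanmean(series[post_mask])) if np.any(~np.isnan(series[post_mask])) else float("nan")
    defined = np.isfinite(chi_pre) and chi_pre > 0 and np.isfinite(chi_post)
    return {
        "chi_pre": chi_pre,
        "chi_post": chi_post,
        "ratio": chi_post / chi_pre if defined else float("nan"),
        "defined": bool(defined),
    }
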