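"""Windowed spectral profiling of binned spike counts.

Spikes are binned at 2.5 ms (Nyquist exactly 200 Hz), the count series is
split into non-overlapping 10 s windows over the spontaneous analysis segment
(default: the initial 4 min), each window is Fourier transformed, the power
(|DFT|^2) is restricted to 0.1-200 Hz (dropping the DC component), smoothed
with a centered 3-point moving average, and normalized so the area under the
retained band is exactly 1 per window. All-zero windows are flagged missing
(NaN) rather than normalized. Per-electrode spectrograms are summed within a
culture and averaged across cultures; band powers are Riemann sums
(power x frequency step) over a band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .types import SpikeTrainSet

__all__ = [
    "SpectralConfig",
    "Spectrogram",
    "bin_spikes",
    "window_psd",
    "aggregate_spectra",
    "band_power",
    "electrode_spectrograms",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SpectralConfig:
    bin_width_s: float = 0.0025
    window_s: float = 10.0
    analysis_start_s: float = 0.0
    analysis_end_s: float = 240.0
    f_min_hz: float = 0.1
    f_max_hz: float = 200.0
    smooth_points: int = 3
    report_band: tuple[float, float] = (0.1, 5.0)
    sum_band: tuple[float, float] = (0.1, 1.0)
    smooth_before_normalize: bool = False
    taper: str | None = None  # None (rectangular, as-measured) or "hann"

    def __post_init__(self) -> None:
        if not self.bin_width_s > 0:
            raise ValidationError("bin_width_s must be positive")
        if self.f_max_hz > 0.5 / self.bin_width_s + _EPS:
            raise ValidationError("f_max exceeds the Nyquist frequency of the binning")
        if self.analysis_end_s - self.analysis_start_s < self.window_s:
            raise ValidationError("analysis segment shorter than one window")
        if self.smooth_points < 1 or self.smooth_points % 2 == 0:
            raise ValidationError("smooth_points must be odd and >= 1")
        n = self.window_s / self.bin_width_s
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("window_s must be an integer number of bins")


@dataclass
class Spectrogram:
    """Window x frequency matrix of normalized power.

    Missing (all-zero) windows are NaN rows. For a single normalized
    spectrogram every non-missing row satisfies sum(power) * df == 1 over the
    retained band; aggregated spectrograms scale linearly (a sum of k
    normalized spectrograms has row AUC k).
    """

    values: np.ndarray  # [n_windows, n_freq]
    frequencies_hz: np.ndarray
    window_s: float
    label: str = ""

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def df_hz(self) -> float:
        return 1.0 / self.window_s

    def missing_windows(self) -> np.ndarray:
        return np.isnan(self.values).all(axis=1)

    def window_auc(self) -> np.ndarray:
        return np.sum(self.values, axis=1) * self.df_hz


def bin_spikes(
    train: Sequence[float] | np.ndarray, bin_width_s: float, duration_s: float
) -> np.ndarray:
    """Half-open binning: counts[k] = #spikes in [k*w, (k+1)*w)."""
    if not bin_width_s > 0:
        raise ValidationError("bin_width_s must be positive")
    n_bins = int(math.ceil(duration_s / bin_width_s - _EPS))
    t = np.asarray(train, dtype=float)
    idx = np.floor(t / bin_width_s).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    return np.bincount(idx, minlength=n_bins).astype(float)


def _smooth(row: np.ndarray, points: int) -> np.ndarray:
    """Centered moving average with reflected edges.

    Reflection keeps the edge bins comparable to interior bins (a truncated
    kernel would over-weight the band edges, e.g. manufacturing a spurious
    maximum at the Nyquist end of a flat harmonic series).
    """
    if points <= 1:
        return row
    half = points // 2
    padded = np.pad(row, half, mode="reflect")
    return np.convolve(padded, np.ones(points) / points, mode="valid")


def window_psd(counts: np.ndarray, config: SpectralConfig, label: str = "") -> Spectrogram:
    """Per-window power spectra of a binned count series.

    Each 10 s window is transformed without mean subtraction; power is the
    squared DFT modulus at positive frequencies, restricted to
    [f_min, f_max]. Windows with zero power in the retained band are flagged
    missing. The retained band is normalized to unit area after smoothing, so
    the AUC contract holds in either smoothing order.
    """
    counts = np.asarray(counts, dtype=float)
    nw = int(round(config.window_s / config.bin_width_s))
    start = int(round(config.analysis_start_s / config.bin_width_s))
    end = int(round(config.analysis_end_s / config.bin_width_s))
    end = min(end, counts.size)
    n_windows = (end - start) // nw
    if n_windows < 1:
        raise ValidationError("analysis segment does not cover one full window")

    freqs = np.fft.rfftfreq(nw, d=config.bin_width_s)
    keep = (freqs >= config.f_min_hz - _EPS) & (freqs <= config.f_max_hz + _EPS)
    f_kept = freqs[keep]
    df = 1.0 / config.window_s
    taper = np.hanning(nw) if config.taper == "hann" else None

    rows = np.full((n_windows, f_kept.size), np.nan)
    for w in range(n_windows):
        x = counts[start + w * nw : start + (w + 1) * nw]
        if taper is not None:
            x = x * taper
        power = np.abs(np.fft.rfft(x)) ** 2
        band = power[keep]
        total = band.sum() * df
        if total <= 0:
            continue  # missing window
        if config.smooth_before_normalize:
            band = _smooth(band, config.smooth_points)
            band = band / (band.sum() * df)
        else:
            band = band / total
            band = _smooth(band, config.smooth_points)
            band = band / (band.sum() * df)  # edge-mass correction
        rows[w] = band
    return Spectrogram(values=rows, frequencies_hz=f_kept, window_s=config.window_s, label=label)


def electrode_spectrograms(
    spikes: SpikeTrainSet, electrode_ids: Sequence[str], config: SpectralConfig
) -> list[Spectrogram]:
    """Convenience: bin and transform each electrode's train."""
    out = []
    for eid in electrode_ids:
        counts = bin_spikes(spikes.trains[eid], config.bin_width_s, spikes.duration_s)
        out.append(window_psd(counts, config, label=eid))
    return out


def aggregate_spectra(spectrograms: Sequence[Spectrogram], mode: str) -> Spectrogram:
    """Combine spectrograms element-wise.

    ``mode='sum_electrodes'`` sums normalized per-electrode spectra within a
    culture; ``mode='mean_cultures'`` averages culture spectra. Missing
    windows propagate as missing.
    """
    if mode not in {"sum_electrodes", "mean_cultures"}:
        raise ValidationError("mode must be 'sum_electrodes' or 'mean_cultures'")
    if not spectrograms:
        raise ValidationError("nothing to aggregate")
    ref = spectrograms[0]
    for s in spectrograms[1:]:
        if s.values.shape != ref.values.shape or not np.allclose(
            s.frequencies_hz, ref.frequencies_hz
        ):
            raise ValidationError("spectrograms have mismatched grids")
    stack = np.stack([s.values for s in spectrograms])
    values = stack.sum(axis=0) if mode == "sum_electrodes" else stack.mean(axis=0)
    return Spectrogram(
        values=values,
        frequencies_hz=ref.frequencies_hz.copy(),
        window_s=ref.window_s,
        label=mode,
    )


def band_power(spectrogram: Spectrogram, band: tuple[float, float]) -> float:
    """Sum of power x frequency step over all windows and band frequencies.

    Band membership is half-open ``[lo, hi)``; the upper edge is included only
    when it reaches the top of the retained grid, so disjoint bands that
    partition the retained range have powers that sum exactly to the total.
    Missing windows are excluded.
    """
    lo, hi = band
    f = spectrogram.frequencies_hz
    if not lo < hi:
        raise ValidationError("band must satisfy lo < hi")
    if lo > f[-1] or hi < f[0]:
        raise ValidationError("band lies outside the retained frequency range")
    mask = (f >= lo - _EPS) & (f < hi - _EPS)
    if hi >= f[-1] - _EPS:
        mask |= np.isclose(f, f[-1])
    if not mask.any():
        raise ValidationError("band contains no frequency samples")
    vals = spectrogram.values[~spectrogram.missing_windows()][:, mask]
    return float(np.sum(vals) * spectrogram.df_hz)
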