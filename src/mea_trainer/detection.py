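"""Spike detection on raw MEA traces.

The detection chain: zero-phase 2nd-order Butterworth high-pass at 200 Hz,
per-electrode noise estimation, threshold crossing at a multiple (default 5)
of the noise SD, then two false-positive filters — threshold calibration on
the ground electrode (raise the multiplier until the ground channel yields no
validated detections) and a waveform-phase check requiring depolarization,
repolarization and a refractory-silent tail. Electrodes firing at least
10 spikes/min are classified active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ValidationError
from .types import RawRecording, SpikeTrainSet

__all__ = [
    "DetectionConfig",
    "NoiseEstimate",
    "highpass_filter",
    "estimate_noise",
    "detect_spikes",
    "calibrate_threshold_on_ground",
    "validate_waveforms",
    "active_electrodes",
]

_MAD_TO_SD = 0.6745  # Phi^{-1}(0.75): MAD of a Gaussian in SD units


@dataclass(frozen=True)
class DetectionConfig:
    """Filtering, thresholding and validation parameters."""

    filter_order: int = 2
    cutoff_hz: float = 200.0
    threshold_multiplier: float = 5.0
    polarity: str = "negative"  # negative | positive | both
    dead_time_s: float = 0.001
    validation_pre_s: float = 0.001
    validation_post_s: float = 0.002
    rebound_fraction: float = 0.15
    active_rate_per_min: float = 10.0
    noise_estimator: str = "mad"  # mad | sd
    calibration_cap: float = 12.0
    calibration_step: float = 0.5

    def __post_init__(self) -> None:
        if self.polarity not in {"negative", "positive", "both"}:
            raise ValidationError("polarity must be negative, positive or both")
        if self.noise_estimator not in {"mad", "sd"}:
            raise ValidationError("noise_estimator must be 'mad' or 'sd'")
        if not self.threshold_multiplier > 0:
            raise ValidationError("threshold_multiplier must be positive")
        for name in ("dead_time_s", "validation_pre_s", "validation_post_s"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class NoiseEstimate:
    """Per-electrode noise SD in microvolts."""

    sd_uv: dict[str, float]
    estimator: str

    def __getitem__(self, electrode_id: str) -> float:
        return self.sd_uv[electrode_id]


def highpass_filter(raw: RawRecording, config: DetectionConfig) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth high-pass, per channel."""
    nyquist = raw.sampling_rate_hz / 2.0
    if config.cutoff_hz >= nyquist:
        raise ValidationError(
            f"cutoff {config.cutoff_hz} Hz is at or above Nyquist ({nyquist} Hz)"
        )
    sos = signal.butter(
        config.filter_order, config.cutoff_hz, btype="highpass",
        fs=raw.sampling_rate_hz, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, raw.samples, axis=0)
    return RawRecording(
        samples=filtered,
        sampling_rate_hz=raw.sampling_rate_hz,
        layout=raw.layout,
        t0_s=raw.t0_s,
    )


def estimate_noise(filtered: RawRecording, estimator: str = "mad") -> NoiseEstimate:
    """Noise SD per electrode.

    Default is the robust median-absolute-deviation estimate
    ``median(|x|) / 0.6745`` (the high-passed trace is zero-mean), which large
    spikes barely inflate; ``estimator='sd'`` gives the plain standard
    deviation. All-zero channels yield SD 0 with a warning; thresholds on such
    channels are then infinite and produce no detections.
    """
    sds: dict[str, float] = {}
    for j, eid in enumerate(filtered.layout.electrode_ids):
        x = filtered.samples[:, j]
        if estimator == "mad":
            sd = float(np.median(np.abs(x)) / _MAD_TO_SD)
        elif estimator == "sd":
            sd = float(np.std(x))
        else:
            raise ValidationError("estimator must be 'mad' or 'sd'")
        if sd == 0.0:
            warnings.warn(f"electrode {eid}: constant trace, noise SD is 0")
        sds[eid] = sd
    return NoiseEstimate(sd_uv=sds, estimator=estimator)


def _oriented(x: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "negative":
        return -x
    if polarity == "positive":
        return x
    return np.abs(x)


def _detect_channel(
    x: np.ndarray, threshold_uv: float, fs: float, polarity: str, dead_time_s: float
) -> np.ndarray:
    """Threshold crossings localized at the in-window extremum, then merged
    within the dead time keeping the larger extremum. Returns sample indices."""
    y = _oriented(x, polarity)
    above = y >= threshold_uv
    if not above.any():
        return np.empty(0, dtype=int)
    crossings = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    dead = max(int(round(dead_time_s * fs)), 1)
    peaks = np.array(
        [c + int(np.argmax(y[c : c + dead])) for c in crossings], dtype=int
    )
    # merge detections closer than the dead time, keeping the larger extremum
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < dead:
            if y[p] > y[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return np.asarray(kept, dtype=int)


def detect_spikes(
    filtered: RawRecording, noise: NoiseEstimate, config: DetectionConfig
) -> SpikeTrainSet:
    """Threshold detection at ``threshold_multiplier × noise SD`` per channel."""
    trains: dict[str, np.ndarray] = {}
    for j, eid in enumerate(filtered.layout.electrode_ids):
        sd = noise[eid]
        if sd <= 0:
            trains[eid] = np.empty(0)
            continue
        idx = _detect_channel(
            filtered.samples[:, j],
            config.threshold_multiplier * sd,
            filtered.sampling_rate_hz,
            config.polarity,
            config.dead_time_s,
        )
        trains[eid] = filtered.t0_s + idx / filtered.sampling_rate_hz
    return SpikeTrainSet(trains, duration_s=filtered.duration_s, layout=filtered.layout)


def validate_waveforms(
    filtered: RawRecording,
    candidates: SpikeTrainSet,
    config: DetectionConfig,
    noise: NoiseEstimate | None = None,
) -> SpikeTrainSet:
    """Keep candidates showing the three action-potential voltage phases.

    Within the validation window around each candidate peak: (a) the extremum
    has the configured polarity; (b) an opposite-phase rebound of at least
    ``rebound_fraction`` of the extremum follows it (repolarization); (c) no
    second suprathreshold same-polarity extremum occurs within the dead time
    after the rebound (refractory period).

    ``noise`` should be the estimate used for detection; it sets the
    suprathreshold level of check (c) and is re-estimated when omitted.
    """
    fs = filtered.sampling_rate_hz
    pre = max(int(round(config.validation_pre_s * fs)), 1)
    post = max(int(round(config.validation_post_s * fs)), 1)
    dead = max(int(round(config.dead_time_s * fs)), 1)
    if noise is None:
        noise = estimate_noise(filtered, config.noise_estimator)

    trains: dict[str, np.ndarray] = {}
    for j, eid in enumerate(filtered.layout.electrode_ids):
        x = filtered.samples[:, j]
        thr = config.threshold_multiplier * noise[eid] if noise[eid] > 0 else np.inf
        kept: list[float] = []
        for t in candidates.trains[eid]:
            c = int(round((t - filtered.t0_s) * fs))
            w0, w1 = max(c - pre, 0), min(c + post + 1, x.size)
            win = x[w0:w1]
            if win.size == 0:
                continue
            if config.polarity == "both":
                pol = "negative" if x[c] < 0 else "positive"
            else:
                pol = config.polarity
            y = _oriented(win, pol)
            ext = int(np.argmax(y))
            if y[ext] <= 0:
                continue  # wrong phase sign
            # (b) opposite-phase rebound after the extremum
            tail = -y[ext + 1 :]
            if tail.size == 0 or np.max(tail) < config.rebound_fraction * y[ext]:
                continue
            reb = ext + 1 + int(np.argmax(tail))
            # (c) refractory: no second suprathreshold same-polarity extremum
            r0 = w0 + reb + 1
            r1 = min(r0 + dead, x.size)
            if r1 > r0 and np.max(_oriented(x[r0:r1], pol)) >= thr:
                continue
            kept.append(t)
        trains[eid] = np.unique(np.asarray(kept))
    return SpikeTrainSet(trains, duration_s=candidates.duration_s, layout=filtered.layout)


def calibrate_threshold_on_ground(
    filtered: RawRecording, config: DetectionConfig
) -> DetectionConfig:
    """Raise the threshold multiplier until the ground electrode is silent.

    Searches upward from the configured multiplier (never below it) in
    ``calibration_step`` increments up to ``calibration_cap``; returns the
    first configuration with zero validated detections on the ground channel.
    """
    gid = filtered.layout.ground_id
    if gid is None:
        raise ConfigurationError("layout has no ground electrode to calibrate on")
    noise = estimate_noise(filtered, config.noise_estimator)
    mult = config.threshold_multiplier
    while mult <= config.calibration_cap + 1e-9:
        cand_cfg = replace(config, threshold_multiplier=mult)
        detections = detect_spikes(filtered, noise, cand_cfg)
        validated = validate_waveforms(filtered, detections, cand_cfg, noise)
        if validated.trains[gid].size == 0:
            return cand_cfg
        mult += config.calibration_step
    raise ConfigurationError(
        f"ground electrode still yields detections at the "
        f"{config.calibration_cap}-sigma cap"
    )


def active_electrodes(spikes: SpikeTrainSet, config: DetectionConfig) -> list[str]:
    """Electrodes firing at least ``active_rate_per_min`` spikes/min (inclusive)."""
    minutes = spikes.duration_s / 60.0
    if not minutes > 0:
        raise ValidationError("recording duration must be positive")
    return [
        e
        for e in spikes.layout.electrode_ids
        if spikes.trains[e].size / minutes >= config.active_rate_per_min
    ]
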