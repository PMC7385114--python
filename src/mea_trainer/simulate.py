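"""Synthetic MEA activity with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, not the underlying biology:

* per-electrode background firing as a Poisson process;
* network-burst events shared across a tunable fraction of electrodes, with
  per-electrode onset jitter (the synchrony knob) and exponential within-burst
  inter-spike intervals;
* pulse-locked evoked spikes during optogenetic stimulation blocks;
* post-stimulation rate suppression (or elevation) recovering exponentially,
  applied multiplicatively to background and burst rates by thinning;
* raw-trace synthesis: biphasic spike templates + Gaussian noise + slow
  drift sinusoids + optional rectangular light-artifact pulses, with the
  ground electrode receiving everything except spikes.

Every spike carries a ground-truth label (background / burst / evoked), so
each downstream metric can be validated against the configuration that
produced the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .protocol import RecordingStimPlan
from .types import ElectrodeLayout, RawRecording, SpikeTrainSet, standard_layout

__all__ = [
    "SyntheticNetworkConfig",
    "SyntheticTruth",
    "WaveformTemplate",
    "simulate_spikes",
    "render_raw",
]


@dataclass(frozen=True)
class SyntheticNetworkConfig:
    """Parameters of the synthetic network.

    Defaults describe a moderately synchronous spontaneous culture: 1 Hz
    background per electrode, network bursts every ~5 s joined by 80 % of
    electrodes with 20 ms onset jitter, ~8 spikes per burst at a 20 ms mean
    intra-burst ISI (comfortably inside the 50 ms max-interval burst
    criteria), and a 2 ms absolute refractory period.
    """

    n_electrodes: int = 60
    duration_s: float = 1200.0
    background_rate_hz: float = 1.0
    network_burst_rate_hz: float = 0.2
    participation_prob: float = 0.8
    onset_jitter_s: float = 0.02
    spikes_per_burst_mean: float = 8.0
    intraburst_isi_s: float = 0.02
    refractory_s: float = 0.002
    stim_plan: RecordingStimPlan | None = None
    p_evoke: float = 0.8
    evoke_latency_s: float = 0.004
    post_stim_gain: float = 1.0
    post_stim_tau_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("participation_prob", "p_evoke"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in (
            "background_rate_hz",
            "network_burst_rate_hz",
            "onset_jitter_s",
            "refractory_s",
            "post_stim_gain",
            "post_stim_tau_s",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_electrodes < 1 or self.duration_s <= 0:
            raise ValidationError("need at least one electrode and positive duration")
        if self.spikes_per_burst_mean < 1:
            raise ValidationError("spikes_per_burst_mean must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated spike set.

    ``spike_labels`` partitions the emitted spikes exactly; spikes removed by
    refractory thinning are logged separately.
    """

    burst_event_times: np.ndarray
    spike_times: dict[str, np.ndarray]
    spike_labels: dict[str, np.ndarray]
    participation: np.ndarray  # [n_events, n_electrodes] bool
    removed_times: dict[str, np.ndarray]
    removed_labels: dict[str, np.ndarray]

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {"background": 0, "burst": 0, "evoked": 0}
        for labels in self.spike_labels.values():
            for lab in out:
                out[lab] += int(np.sum(labels == lab))
        return out

    def times_with_label(self, electrode_id: str, label: str) -> np.ndarray:
        mask = self.spike_labels[electrode_id] == label
        return self.spike_times[electrode_id][mask]


def _gain_curve(
    t: np.ndarray, plan: RecordingStimPlan | None, gain: float, tau: float
) -> np.ndarray:
    """Multiplicative rate factor g(t): 1 except during post-block recovery."""
    t = np.asarray(t, dtype=float)
    g = np.ones_like(t)
    if plan is None or gain == 1.0:
        return g
    intervals = plan.block_intervals()
    for k, (_, end) in enumerate(intervals):
        next_start = (
            intervals[k + 1][0] if k + 1 < len(intervals) else plan.recording_duration_s
        )
        mask = (t >= end) & (t < next_start)
        if tau > 0:
            g[mask] = gain + (1.0 - gain) * (1.0 - np.exp(-(t[mask] - end) / tau))
        else:
            g[mask] = 1.0  # instantaneous recovery
    return g


def _thinned_poisson(
    rng: np.random.Generator,
    rate_hz: float,
    duration_s: float,
    plan: RecordingStimPlan | None,
    gain: float,
    tau: float,
) -> np.ndarray:
    """Inhomogeneous Poisson times at rate_hz * g(t), by thinning."""
    gmax = max(1.0, gain)
    n = rng.poisson(rate_hz * gmax * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, size=n))
    if n == 0:
        return t
    accept = rng.uniform(size=n) < _gain_curve(t, plan, gain, tau) / gmax
    return t[accept]


def _truncated_exponential(
    rng: np.random.Generator, mean: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Exponential(mean) conditioned on [lo, hi], by inverse CDF."""
    u = rng.uniform(size=size)
    a, b = np.exp(-lo / mean), np.exp(-hi / mean)
    return -mean * np.log(a - u * (a - b))


def _refractory_thin(
    times: np.ndarray, labels: np.ndarray, refractory_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Forward sweep keeping the earlier spike of any pair closer than the
    refractory period; returns (kept_t, kept_lab, removed_t, removed_lab)."""
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]
    keep = np.zeros(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t - last >= refractory_s:
            keep[i] = True
            last = t
    return times[keep], labels[keep], times[~keep], labels[~keep]


def simulate_spikes(
    config: SyntheticNetworkConfig, layout: ElectrodeLayout | None = None
) -> tuple[SpikeTrainSet, SyntheticTruth]:
    """Simulate per-electrode spike trains; deterministic given ``config.seed``.

    The ground electrode (if the layout declares one) stays silent.
    """
    if layout is None:
        layout = standard_layout(config.n_electrodes)
    rec_ids = layout.recording_ids()
    if len(rec_ids) != config.n_electrodes:
        raise ValidationError(
            f"layout provides {len(rec_ids)} recording electrodes; "
            f"config expects {config.n_electrodes}"
        )
    # One seed stream per electrode plus one global stream, derived from the
    # master seed, so results do not depend on electrode iteration order.
    children = np.random.SeedSequence(config.seed).spawn(config.n_electrodes + 1)
    global_rng = np.random.default_rng(children[0])

    plan, gain, tau = config.stim_plan, config.post_stim_gain, config.post_stim_tau_s
    events = _thinned_poisson(
        global_rng, config.network_burst_rate_hz, config.duration_s, plan, gain, tau
    )
    n_events = events.size
    pulses = plan.all_pulses() if plan is not None else np.empty((0, 2))

    participation = np.zeros((n_events, config.n_electrodes), dtype=bool)
    trains: dict[str, np.ndarray] = {}
    spike_times: dict[str, np.ndarray] = {}
    spike_labels: dict[str, np.ndarray] = {}
    removed_times: dict[str, np.ndarray] = {}
    removed_labels: dict[str, np.ndarray] = {}

    for j, eid in enumerate(rec_ids):
        rng = np.random.default_rng(children[j + 1])
        parts: list[np.ndarray] = []
        labs: list[np.ndarray] = []

        bg = _thinned_poisson(rng, config.background_rate_hz, config.duration_s, plan, gain, tau)
        parts.append(bg)
        labs.append(np.full(bg.size, "background"))

        if n_events:
            joins = rng.uniform(size=n_events) < config.participation_prob
            participation[:, j] = joins
            for ev in events[joins]:
                onset = ev + rng.normal(0.0, config.onset_jitter_s)
                count = 1 + rng.poisson(config.spikes_per_burst_mean - 1.0)
                isis = np.maximum(
                    rng.exponential(config.intraburst_isi_s, size=max(count - 1, 0)),
                    config.refractory_s,
                )
                t = onset + np.concatenate([[0.0], np.cumsum(isis)])
                t = t[(t >= 0.0) & (t < config.duration_s)]
                parts.append(t)
                labs.append(np.full(t.size, "burst"))

        if pulses.size and config.p_evoke > 0:
            evoked_mask = rng.uniform(size=pulses.shape[0]) < config.p_evoke
            n_ev = int(evoked_mask.sum())
            if n_ev:
                lat = _truncated_exponential(rng, config.evoke_latency_s, 0.001, 0.010, n_ev)
                t = pulses[evoked_mask, 0] + lat
                t = t[t < config.duration_s]
                parts.append(t)
                labs.append(np.full(t.size, "evoked"))

        all_t = np.concatenate(parts) if parts else np.empty(0)
        all_l = np.concatenate(labs) if labs else np.empty(0, dtype="U10")
        kept_t, kept_l, rem_t, rem_l = _refractory_thin(all_t, all_l, config.refractory_s)
        trains[eid] = kept_t
        spike_times[eid] = kept_t
        spike_labels[eid] = kept_l
        removed_times[eid] = rem_t
        removed_labels[eid] = rem_l

    if layout.ground_id is not None:
        trains[layout.ground_id] = np.empty(0)
        spike_times[layout.ground_id] = np.empty(0)
        spike_labels[layout.ground_id] = np.empty(0, dtype="U10")
        removed_times[layout.ground_id] = np.empty(0)
        removed_labels[layout.ground_id] = np.empty(0, dtype="U10")

    spikes = SpikeTrainSet(trains, duration_s=config.duration_s, layout=layout)
    truth = SyntheticTruth(
        burst_event_times=events,
        spike_times=spike_times,
        spike_labels=spike_labels,
        participation=participation,
        removed_times=removed_times,
        removed_labels=removed_labels,
    )
    return spikes, truth


@dataclass(frozen=True)
class WaveformTemplate:
    """Sampled biphasic extracellular spike shape (microvolts).

    A single dominant negative trough followed by an opposite-sign rebound,
    so the waveform-phase validation stage accepts inserted instances.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    trough_index: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        trough = int(np.argmin(samples))
        if samples[trough] >= 0:
            raise ValidationError("template must have a negative trough")
        if trough != self.trough_index:
            raise ValidationError("trough_index does not point at the minimum")
        after = samples[trough:]
        if after.size < 2 or np.max(after) <= 0:
            raise ValidationError("template must rebound above zero after the trough")

    @property
    def trough_uv(self) -> float:
        return float(self.samples[self.trough_index])

    @classmethod
    def default(cls, sampling_rate_hz: float = 10_000.0) -> "WaveformTemplate":
        """1.5 ms biphasic template: −60 µV trough then +20 µV rebound."""
        t_ms = np.arange(int(round(0.0015 * sampling_rate_hz))) / sampling_rate_hz * 1e3
        y = -60.0 * np.exp(-(((t_ms - 0.4) / 0.12) ** 2)) + 20.0 * np.exp(
            -(((t_ms - 0.95) / 0.18) ** 2)
        )
        return cls(samples=y, sampling_rate_hz=sampling_rate_hz, trough_index=int(np.argmin(y)))


def render_raw(
    spikes: SpikeTrainSet,
    template: WaveformTemplate,
    noise_sd_uv: float = 5.0,
    drift_components: list[tuple[float, float]] | None = None,
    artifact_plan: RecordingStimPlan | None = None,
    artifact_amplitude_uv: float = 0.0,
    sampling_rate_hz: float = 10_000.0,
    seed: int = 0,
) -> RawRecording:
    """Synthesize a raw voltage matrix from spike trains.

    Each spike inserts one template instance with its trough at the spike
    sample; Gaussian noise, slow drift sinusoids ``(freq_hz, amplitude_uv)``
    and optional rectangular artifact pulses aligned to light pulses are added
    to every channel. The ground electrode receives no spikes. Spikes too
    close to the trace end are truncated with a warning.
    """
    drift_components = drift_components or []
    for f_hz, _ in drift_components:
        if f_hz >= sampling_rate_hz / 2:
            raise ValidationError("drift frequency at or above Nyquist")
    layout = spikes.layout
    n = int(round(spikes.duration_s * sampling_rate_hz))
    rng = np.random.default_rng(seed)
    out = (
        rng.normal(0.0, noise_sd_uv, size=(n, layout.n_electrodes))
        if noise_sd_uv > 0
        else np.zeros((n, layout.n_electrodes))
    )
    t = np.arange(n) / sampling_rate_hz
    for f_hz, amp in drift_components:
        out += amp * np.sin(2 * np.pi * f_hz * t)[:, None]
    if artifact_plan is not None and artifact_amplitude_uv != 0.0:
        for start, end in artifact_plan.all_pulses():
            i0, i1 = int(round(start * sampling_rate_hz)), int(round(end * sampling_rate_hz))
            out[max(i0, 0) : min(i1, n), :] += artifact_amplitude_uv

    tmpl = template.samples
    truncated = 0
    for j, eid in enumerate(layout.electrode_ids):
        if eid == layout.ground_id:
            continue
        for spike_t in spikes.trains[eid]:
            center = int(round(spike_t * sampling_rate_hz))
            i0 = center - template.trough_index
            i1 = i0 + tmpl.size
            s0, s1 = max(i0, 0), min(i1, n)
            if s1 < i1 or s0 > i0:
                truncated += 1
            if s1 > s0:
                out[s0:s1, j] += tmpl[s0 - i0 : s1 - i0]
    if truncated:
        warnings.warn(f"{truncated} spike template(s) truncated at trace boundaries")
    return RawRecording(samples=out, sampling_rate_hz=sampling_rate_hz, layout=layout)
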