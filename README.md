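# mea-trainer

Analysis pipeline for multi-electrode-array (MEA) electrophysiology of
cultured neural networks under optogenetic stimulation, together with a
synthetic MEA generator that makes every stage verifiable against known
ground truth.

MEA recordings of stem-cell-derived neural cultures (e.g. motor-neuron
embryoid bodies expressing channelrhodopsin-2) are multichannel extracellular
voltage traces, typically 60 electrodes sampled at 10 kHz for 20 minutes.
This package implements the standard analysis chain for such recordings:

- **Spike detection** — zero-phase 2nd-order Butterworth high-pass at
  200 Hz, per-electrode noise SD from the median absolute deviation, spike
  threshold at 5×SD, plus two false-positive filters: the threshold is raised
  until the ground electrode yields no detections, and every candidate must
  show the three action-potential voltage phases (depolarization,
  repolarization, refractory period). Electrodes with at least 10 spikes/min
  count as *active*.
- **Burst detection** — the max-interval method with the five classic
  parameters: max ISI to start 50 ms, max ISI to continue 50 ms, min
  inter-burst interval 100 ms, min duration 50 ms, min 4 spikes.
- **Spectral profiling** — spike counts binned at 2.5 ms (Nyquist 200 Hz),
  FFT over non-overlapping 10 s windows of the spontaneous segment,
  power restricted to 0.1–200 Hz, 3-point moving-average smoothing, and
  per-window normalization to unit area under the curve; band powers (e.g.
  the 0.1–1 Hz sum) are Riemann sums over the normalized spectra.
- **Network synchrony** — the zero-lag cross-correlation
  χ(x,y) = Σₘ f[m]g[m] / √(Σf² · Σg²) of binned spike trains, normalized so
  each autocorrelation is 1 at zero lag, stored as an N×N matrix (60×60 for a
  full array); per-electrode means map onto the array geometry and the
  culture mean χ̄ summarizes the network. A time-resolved variant over 10 s
  segments yields χ̄_post/χ̄_pre around stimulation.
- **Evoked response** — firing rates before, during, and after each
  stimulation block (FR_pre, FR_stim, FR_post), their ratios, and the
  post-stimulation quiescence time (time until the pooled rate recovers to
  50 % of baseline).
- **Stimulation protocols** — the pulsed-light training regimen (5 ms pulses
  at 20 Hz for 1 s every other second; 1,800 cycles/hour) and in-recording
  plans (3 blocks of 10 cycles at equidistant times) as exact, enumerable
  schedule objects.
- **Synthetic data** — per-electrode Poisson background, network-burst
  events with tunable participation probability and onset jitter (the
  synchrony knobs), pulse-locked evoked spikes, post-stimulation suppression
  with exponential recovery, and raw-trace synthesis (biphasic templates +
  Gaussian noise + drift + light artifacts), all labelled with ground truth.

## Worked example

```python
from mea_trainer import (
    SyntheticNetworkConfig, simulate_spikes, synchrony_matrix,
    SpectralConfig, electrode_spectrograms, aggregate_spectra, band_power,
    detect_bursts, BurstParams, build_recording_plan, epochs_from_plan,
    evoked_rates, quiescence_duration,
)

plan = build_recording_plan(600.0, n_blocks=1, cycles_per_block=10)
cfg = SyntheticNetworkConfig(
    n_electrodes=60, duration_s=600.0, background_rate_hz=1.0,
    network_burst_rate_hz=0.2, participation_prob=0.8, onset_jitter_s=0.02,
    stim_plan=plan, p_evoke=0.5, post_stim_gain=0.15, post_stim_tau_s=4.0,
    seed=1,
)
spikes, truth = simulate_spikes(cfg)

m = synchrony_matrix(spikes, interval=(0.0, 270.0))
spec = SpectralConfig(analysis_end_s=240.0)
culture = aggregate_spectra(
    electrode_spectrograms(spikes, spikes.layout.recording_ids(), spec),
    "sum_electrodes",
)
low = band_power(culture, (0.1, 1.0)) / band_power(culture, (0.1, 200.0))

epochs = epochs_from_plan(plan, 20.0, 20.0)
records, _ = evoked_rates(spikes, epochs)
r = records[0]
q, _ = quiescence_duration(spikes, plan.block_intervals()[0], r.fr_pre_hz)
```

Printing these results gives:

```
simulated 87951 spikes on 60 electrodes (125 network bursts)
spontaneous culture synchrony chi-bar = 0.387
0.1-1 Hz fraction of normalized power = 0.017
5404 single-electrode bursts detected
FR_pre = 2.97 Hz, FR_stim = 7.51 Hz
FR_stim/FR_pre = 2.53, FR_post/FR_pre = 0.40, quiescence = 13.0 s
```

Reading the numbers: with 80 % burst participation and 20 ms onset jitter the
spontaneous culture synchrony sits at χ̄ ≈ 0.39; light pulses with a 50 %
per-pulse evoked-spike probability raise the network rate 2.5-fold during the
20 s block; and the configured post-stimulation suppression (gain 0.15
recovering with τ = 4 s) keeps FR_post below baseline. The 13 s quiescence
estimate is longer than the suppression time constant because the baseline is
bursty: the pooled 1 s-bin rate only re-crosses 50 % of FR_pre when a network
burst lands in a bin.

The same stages are scriptable from the shell:

```bash
mea-trainer simulate --n-electrodes 60 --duration-s 1200 --seed 1 --out spikes.csv
mea-trainer synchrony --spikes spikes.csv --duration-s 1200 --out chi.csv
mea-trainer run --config run.yaml     # full pipeline with a manifest
```

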