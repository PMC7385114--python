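# Methods

Conventions used throughout: time in seconds, voltage in microvolts, all
intervals half-open `[start, end)`. Every stochastic routine takes an
explicit seed and is deterministic given it.

## Stimulation protocols

A `StimulationProtocol` is a cycle pattern — pulse width (default 5 ms),
pulse rate (20 Hz), on-duration (1 s), cycle period (2 s) — repeated
`n_cycles` times. The training regimen over a duration `D` has
`floor(D / period)` cycles, so one hour gives 1,800 cycles and 36,000 pulses.
Pulse times are computed from integer cycle and pulse indices
(`block_start + c·period + k/rate`), never from a running sum, so schedules
are exact and independent of floating-point accumulation order.

In-recording plans place `n_blocks` blocks (default 3, each 10 cycles = 20 s)
at equidistant times, with centers at fractions `(k+1)/(n_blocks+1)` of the
recording. This placement leaves a leading stimulation-free spontaneous
segment (the first ~4 min of a 20-min recording, which the spectral analysis
expects) and is overridable via explicit block starts.

## Synthetic MEA activity

The generator reproduces the statistical structure the analyses measure, not
the biophysics. Per electrode, a spike train is the superposition of:

1. **Background**: Poisson at `background_rate_hz` (default 1 Hz — a typical
   spontaneous multi-unit rate for an active electrode), modulated by the
   post-stimulation gain `g(t)` by thinning.
2. **Network bursts**: global events arrive as a Poisson process
   (`network_burst_rate_hz`, default 0.2 Hz, i.e. one burst every ~5 s).
   Each electrode joins an event with `participation_prob` (default 0.8);
   its burst onset is the event time plus Gaussian jitter
   (`onset_jitter_s`, default 20 ms); within-burst spike count is
   1 + Poisson(mean − 1) (default mean 8) with Exponential ISIs (default
   mean 20 ms, floored at the refractory period). Participation and jitter
   are the two synchrony knobs: raising participation raises the zero-lag
   correlation χ̄, raising jitter lowers it.
3. **Evoked spikes**: during stimulation blocks each pulse evokes a spike
   with probability `p_evoke` at an Exponential latency (mean 4 ms)
   truncated to [1, 10] ms — the physiological latency band for
   channelrhodopsin-driven firing.
4. **Post-stimulation modulation**: after each block,
   `g(t) = gain + (1 − gain)·(1 − exp(−(t − t_end)/τ))`, 1 elsewhere.
   `gain < 1` gives the quiescence-then-recovery phenomenology, `gain > 1`
   transient elevation. The modulation acts multiplicatively on background
   and burst rates via thinning — the simplest mechanism that produces the
   observed behavior. The recovery constants are free parameters for
   testing, not estimates of biology.

All spikes are merged, sorted, and thinned by a forward sweep enforcing a
2 ms absolute refractory period (the earlier spike wins; removed spikes are
logged). Ground truth labels every emitted spike (background / burst /
evoked) and records event times and per-event participation, so every
downstream metric can be checked against the configuration that produced the
data. RNG sub-streams are derived per electrode from the master seed via
`SeedSequence.spawn`, making results independent of electrode iteration
order.

**Raw traces** are synthesized by inserting a biphasic template (1.5 ms,
−60 µV trough, +20 µV rebound) with its trough at each spike sample, plus
white Gaussian noise (default SD 5 µV; trough 12× noise SD, comfortably
above the 5σ threshold at typical extracellular SNR), optional sub-200 Hz
drift sinusoids, and optional rectangular artifact pulses aligned to light
pulses. The ground electrode receives noise, drift, and artifacts but no
spikes.

What the generator does **not** emulate: electrode-specific waveforms or
amplitude variation, spike-sorting ambiguity (overlapping units), bursting
adaptation, non-stationary baseline drift of firing rates, or correlated
(shared) noise between electrodes. Passing tests therefore demonstrate that
the analysis chain measures what it claims on data with the assumed
statistical structure — not that real recordings satisfy those assumptions.

## Spike detection

Filtering is a 2nd-order Butterworth high-pass at 200 Hz applied
forward–backward (`sosfiltfilt`). Zero-phase filtering is chosen because it
preserves spike timing, which the cross-channel correlation depends on; the
effective magnitude response is the square of the single-pass response
(≈104 dB rejection at 10 Hz).

Noise SD defaults to `median(|x|)/0.6745` — the Gaussian-consistent robust
estimate — so spikes themselves barely inflate the threshold; the plain SD
is available by flag. Detection takes threshold crossings at
`multiplier × SD` (default 5, negative polarity: extracellular somatic
spikes are trough-first; positive and absolute modes exist), localizes each
at the extremum within the 1 ms dead time, and merges detections closer than
the dead time keeping the larger extremum.

Two false-positive filters follow:

- **Ground-electrode calibration** raises the multiplier in 0.5σ steps from
  5σ (never below it) until the ground channel yields zero validated
  detections, erroring at a 12σ cap. The silent-ground rule is standard
  practice; the upward 0.5σ search is this package's operationalization.
- **Waveform-phase validation** keeps a candidate only if, within a
  −1/+2 ms window: the extremum has the configured polarity; an
  opposite-phase rebound of at least 15 % of the extremum follows it; and no
  second suprathreshold same-polarity extremum occurs within the dead time
  after the rebound. This operationalizes the qualitative
  "depolarization / repolarization / refractory period" inspection; all
  three parameters are configurable.

Electrodes with ≥ 10 spikes/min (inclusive) are *active*; downstream
statistics run on active electrodes.

## Burst detection

Max-interval method: open a candidate when an ISI ≤ 50 ms (applied to the
first ISI only), extend while ISIs ≤ 50 ms, merge candidates separated by
less than 100 ms, then drop candidates shorter than 50 ms or with fewer than
4 spikes. Merge precedes filtering (the standard convention — it lets two
short cores that jointly satisfy the thresholds survive); a
filter-before-merge flag exists for sensitivity analysis. A burst spans its
first to last spike, not padded by ISI allowances. Note that merged bursts
can legitimately contain internal gaps up to the 100 ms minimum inter-burst
interval, larger than the 50 ms continuation ISI.

## Spectral profiling

Spikes are binned at 2.5 ms — a free choice; chosen so the
Nyquist frequency is exactly the 200 Hz analysis ceiling — and the count
series over the spontaneous segment (default first 4 min) is split into
non-overlapping 10 s windows. Each window is Fourier transformed without
mean subtraction or taper (a Hann option exists); power is the squared DFT
modulus at positive frequencies, restricted to 0.1–200 Hz (the 0.1 Hz lower
edge drops the DC component; frequency step 0.1 Hz from the 10 s window).

Each retained-band spectrum is smoothed with a centered 3-point moving
average and normalized to unit area (Σ power × Δf = 1). Two numerical
choices matter here:

- The final normalization is applied **after** smoothing in either smoothing
  order, so the unit-AUC contract holds exactly; a 3-point average is
  mass-preserving in the interior but not at band edges, and without the
  final renormalization the documented AUC invariant would be violated at
  the ~1e-3 level depending on edge power.
- Edge smoothing uses **reflect padding** rather than truncated kernels: a
  truncated 2-point edge average over-weights the band edges and can
  manufacture a spurious maximum at the Nyquist end of a flat harmonic
  series (e.g. a strictly periodic train, whose binned comb has equal-power
  harmonics). With reflection, all harmonics smooth identically. Smoothing
  still limits peak localization to ± one frequency bin (0.1 Hz).

All-zero windows are flagged missing (NaN) rather than normalized, and
propagate as missing through aggregation. Aggregation follows the
sum-within-culture / mean-across-cultures convention: per-electrode
normalized spectra are summed (a sum of k unit-AUC spectra has AUC k — no
re-normalization), and culture matrices are averaged element-wise. Band
power is a Riemann sum over all windows and the band's frequency samples;
band membership is half-open `[lo, hi)` with the top of the retained grid
included when `hi` reaches it, so disjoint bands partition exactly.

## Network synchrony

For binned spike-count series f and g, χ = Σ f[m]g[m] / √(Σf² Σg²) — the
zero-lag value of the discrete cross-correlation normalized so each
autocorrelation is 1 at zero lag. Counts are non-negative, so 0 ≤ χ ≤ 1 by
Cauchy–Schwarz, and because counts are integers the inner products are exact
in floating point: the vectorized matrix equals a direct evaluation of the
definition bit-for-bit.

The correlation bin width defaults to 50 ms, chosen to match the burst-onset timescale (the 50 ms max-interval
parameter), so that co-participation in network bursts rather than
millisecond coincidence drives χ. It is configurable and recorded in output
metadata. The raw (mean-unsubtracted) form follows the printed definition; a
mean-subtracted variant exists behind a flag.

All-zero trains give missing (NaN) χ, not 0, so silent electrodes do not
deflate averages. The per-electrode mean χ̄_e excludes self by default and
maps onto the array grid; the culture mean χ̄ averages off-diagonal pairs.
The time-resolved variant evaluates the matrix on consecutive 10 s segments;
χ̄_post/χ̄_pre averages segments wholly inside symmetric windows around a
stimulation block and is flagged undefined when the pre-window is silent or
zero. Note the per-segment χ̄ averages sit slightly below the full-recording
χ̄ for bursty networks (few burst events per 10 s segment), a small-sample
property of the normalization, not a bug.

## Evoked response

Per block, FR_pre / FR_stim / FR_post are spikes/s averaged over the
analyzed electrodes in the pre / stim / post epochs. Pre and post windows
default to the block length (20 s), matching the symmetric windows typically
displayed around stimulation; they are configurable free parameters.
Ratios are undefined (NaN, flagged) when FR_pre = 0. Spikes during light pulses count toward FR_stim; an
optional ±pulse-edge blanking exists for artifact-contaminated raw data
(default off).

Quiescence is measured on the pooled per-electrode network rate in 1 s bins
after block end: the time until the first bin whose rate reaches 50 % of
FR_pre (0 if the first bin qualifies), capped at the recording end or a
caller-supplied horizon with a flag. The 50 % threshold and 1 s bin are free
choices reported in output metadata. The estimate is quantized to the bin
width, and for strongly bursting baselines it reflects the wait for the next
burst-containing bin rather than the background recovery constant alone.

## Problem sizes and verification

The test suite and the acceptance script verify, at desk scale: the protocol
arithmetic (1,800 cycles/hour, 20 s blocks); bit-exact agreement of the
synchrony matrix with the printed definition (8 electrodes × 100 bins) and
the 60×60 shape on a full array; agreement of burst detection with
brute-force enumeration on 1,000 random trains of ≤ 12 spikes on a 5 ms
grid; the unit-AUC and band-additivity contracts and the 2 Hz dominance of a
periodic train; ≥ 95 % sensitivity and precision of the detection chain
against ground truth on a 60-electrode, 60 s rendered recording (±0.5 ms
matching); the Gaussian exceedance bound (≤ 5 threshold crossings per 10⁶
noise samples at 5σ); rank-perfect monotonicity of χ̄ in onset jitter and
participation (5 levels × 10 seeds); the low-band power excess of a 0.5 Hz
bursting network over a rate-matched Poisson control (10 paired seeds, sign
test); evoked ratio directions under p_evoke > 0 and neutral post-gain; and
the quiescence estimate against the analytic crossing time of the configured
recovery law. Simulation sizes (60–600 s, 15–60 electrodes, 10 seeds per
condition) were chosen as the smallest at which these statistics are stable;
all are parameters of the relevant configs.

## Known limitations

- No spike sorting: per-electrode multi-unit activity only.
- No lagged correlations, spike-distance metrics, or graph inference —
  only the zero-lag statistic.
- No Welch/multitaper estimation; the PSD is the plain windowed |DFT|².
- The simulator's phenomenological recovery law is not a biophysical model;
  quiescence comparisons against it validate the estimator, not biology.
- Statistical hypothesis testing across cultures/days is out of scope; the
  pipeline emits tidy tables for external statistics.
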