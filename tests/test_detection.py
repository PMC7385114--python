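import numpy as np
import pytest

from mea_trainer.detection import (
    DetectionConfig,
    active_electrodes,
    calibrate_threshold_on_ground,
    detect_spikes,
    estimate_noise,
    highpass_filter,
    validate_waveforms,
)
from mea_trainer.detection import NoiseEstimate
from mea_trainer.errors import ConfigurationError, ValidationError
from mea_trainer.simulate import WaveformTemplate, render_raw
from mea_trainer.types import ElectrodeLayout, RawRecording

FS = 10_000.0
CFG = DetectionConfig()


def one_channel(x, ground=False):
    layout = ElectrodeLayout(("E1",), ((0, 0),), ground_id="E1" if ground else None)
    return RawRecording(np.asarray(x, dtype=float)[:, None], FS, layout)


def butter2_hp_gain(f, fc=200.0):
    """Analytic 2nd-order Butterworth high-pass magnitude."""
    r = (f / fc) ** 2
    return r / np.sqrt(1 + r * r)


def test_dc_rejection():
    rec = one_channel(np.full(20_000, 100.0))
    out = highpass_filter(rec, CFG)
    core = out.samples[2000:-2000, 0]
    assert np.max(np.abs(core)) < 1e-6


def test_10hz_attenuated_at_least_40db():
    t = np.arange(int(FS * 10)) / FS
    rec = one_channel(np.sin(2 * np.pi * 10.0 * t))
    out = highpass_filter(rec, CFG)
    core = out.samples[int(FS) : -int(FS), 0]
    gain = np.max(np.abs(core))
    assert gain < 10 ** (-40 / 20)
    # forward-backward filtering squares the single-pass response
    assert gain == pytest.approx(butter2_hp_gain(10.0) ** 2, rel=0.2)


def test_1khz_passband_within_1db():
    t = np.arange(int(FS * 2)) / FS
    rec = one_channel(np.sin(2 * np.pi * 1000.0 * t))
    out = highpass_filter(rec, CFG)
    core = out.samples[2000:-2000, 0]
    gain = np.max(np.abs(core))
    assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)


def test_cutoff_above_nyquist_rejected():
    rec = one_channel(np.zeros(100))
    with pytest.raises(ValidationError):
        highpass_filter(rec, DetectionConfig(cutoff_hz=6000.0))


def test_noise_estimate_gaussian():
    rng = np.random.default_rng(0)
    rec = one_channel(rng.normal(0, 5.0, size=1_000_000))
    est = estimate_noise(rec)
    assert est["E1"] == pytest.approx(5.0, rel=0.02)


def test_noise_estimate_robust_to_spikes():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 5.0, size=500_000)
    idx = rng.choice(x.size, size=5000, replace=False)  # 1% large deflections
    x[idx] -= 80.0
    est = estimate_noise(one_channel(x))
    assert est["E1"] == pytest.approx(5.0, rel=0.05)
    # the plain SD estimator is inflated by the same spikes
    sd = estimate_noise(one_channel(x), estimator="sd")
    assert sd["E1"] > est["E1"] * 1.2


def test_noise_estimate_zero_channel_warns():
    with pytest.warns(UserWarning, match="constant"):
        est = estimate_noise(one_channel(np.zeros(1000)))
    assert est["E1"] == 0.0


def insert_template(x, tmpl, sample):
    i0 = sample - tmpl.trough_index
    x[i0 : i0 + tmpl.samples.size] += tmpl.samples
    return x


def test_detect_single_template_at_trough():
    tmpl = WaveformTemplate.default(FS)
    x = insert_template(np.zeros(10_000), tmpl, 5000)
    rec = one_channel(x)
    noise = NoiseEstimate(sd_uv={"E1": 5.0}, estimator="fixed")
    spikes = detect_spikes(rec, noise, CFG)
    assert spikes.trains["E1"].size == 1
    assert spikes.trains["E1"][0] == pytest.approx(0.5, abs=2e-4)


def test_gaussian_noise_exceedance_rate():
    # P(x < -5 sd) ~ 2.9e-7/sample -> expect <= 5 detections per 1e6 samples
    rng = np.random.default_rng(2)
    rec = one_channel(rng.normal(0, 5.0, size=1_000_000))
    noise = NoiseEstimate(sd_uv={"E1": 5.0}, estimator="fixed")
    spikes = detect_spikes(rec, noise, CFG)
    assert spikes.trains["E1"].size <= 5


def test_dead_time_merges_close_detections():
    tmpl = WaveformTemplate.default(FS)
    x = np.zeros(10_000)
    insert_template(x, tmpl, 5000)
    insert_template(x, tmpl, 5005)  # 0.5 ms apart, inside the 1 ms dead time
    rec = one_channel(x)
    noise = NoiseEstimate(sd_uv={"E1": 5.0}, estimator="fixed")
    spikes = detect_spikes(rec, noise, CFG)
    assert spikes.trains["E1"].size == 1


def test_threshold_monotonicity():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 5.0, size=200_000)
    tmpl = WaveformTemplate.default(FS)
    for s in range(1000, 199_000, 997):
        insert_template(x, tmpl, s)
    rec = one_channel(x)
    noise = estimate_noise(rec)
    counts = [
        detect_spikes(rec, noise, DetectionConfig(threshold_multiplier=m)).n_spikes
        for m in (4.0, 5.0, 6.0, 8.0, 11.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_validate_keeps_biphasic_rejects_monophasic():
    tmpl = WaveformTemplate.default(FS)
    x = insert_template(np.zeros(20_000), tmpl, 5000)
    x[15_000:15_010] = -60.0  # monophasic rectangular artifact, no rebound
    rec = one_channel(x)
    noise = NoiseEstimate(sd_uv={"E1": 5.0}, estimator="fixed")
    candidates = detect_spikes(rec, noise, CFG)
    assert candidates.trains["E1"].size == 2
    validated = validate_waveforms(rec, candidates, CFG, noise)
    assert validated.trains["E1"].size == 1
    assert validated.trains["E1"][0] == pytest.approx(0.5, abs=2e-4)


def test_validate_empty_candidates(layout2, trains_factory):
    rec = RawRecording(np.zeros((1000, 2)), FS, layout2)
    empty = trains_factory(layout2, 0.1)
    assert validate_waveforms(rec, empty, CFG).n_spikes == 0


def test_ground_calibration_stays_at_5_for_clean_ground():
    rng = np.random.default_rng(4)
    rec = one_channel(rng.normal(0, 5.0, size=100_000), ground=True)
    out = calibrate_threshold_on_ground(rec, CFG)
    assert out.threshold_multiplier == 5.0


def test_ground_calibration_raises_threshold_over_artifact():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 5.0, size=100_000)
    # biphasic artifact crossing 5 sd but not 6 sd on the ground electrode
    tmpl = WaveformTemplate.default(FS)
    scaled = tmpl.samples * (27.0 / 60.0)  # trough -27 uV: 5.4 sd
    x[50_000 : 50_000 + scaled.size] += scaled
    rec = one_channel(x, ground=True)
    out = calibrate_threshold_on_ground(rec, CFG)
    assert out.threshold_multiplier == 6.0


def test_ground_calibration_cap_errors():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 5.0, size=50_000)
    tmpl = WaveformTemplate.default(FS)
    for s in range(1000, 49_000, 500):
        x[s : s + tmpl.samples.size] += tmpl.samples * 3  # -180 uV: 36 sd
    rec = one_channel(x, ground=True)
    with pytest.raises(ConfigurationError):
        calibrate_threshold_on_ground(rec, CFG)


def test_missing_ground_errors():
    rec = one_channel(np.zeros(100))
    with pytest.raises(ConfigurationError):
        calibrate_threshold_on_ground(rec, CFG)


@pytest.mark.parametrize(
    "n_spikes,expected",
    [(200, True), (199, False), (0, False)],
)
def test_active_electrode_rule_inclusive(layout2, trains_factory, n_spikes, expected):
    # 200 spikes in 20 min is exactly 10/min: active (inclusive)
    t = np.linspace(1, 1199, n_spikes) if n_spikes else []
    s = trains_factory(layout2, 1200.0, E1=t)
    assert (("E1" in active_electrodes(s, CFG)) is expected)


def test_end_to_end_recovery_small():
    """Detection recovers injected spikes from rendered raw within 0.5 ms."""
    from mea_trainer.simulate import SyntheticNetworkConfig, simulate_spikes

    cfg = SyntheticNetworkConfig(
        n_electrodes=6, duration_s=20.0, background_rate_hz=2.0,
        network_burst_rate_hz=0.2, seed=21,
    )
    spikes, _ = simulate_spikes(cfg)
    raw = render_raw(spikes, WaveformTemplate.default(FS), noise_sd_uv=5.0, seed=22)
    filtered = highpass_filter(raw, CFG)
    noise = estimate_noise(filtered)
    detected = validate_waveforms(filtered, detect_spikes(filtered, noise, CFG), CFG)
    matched = 0
    n_true = n_det = 0
    for e in spikes.layout.electrode_ids:
        true_t, det_t = spikes.trains[e], detected.trains[e]
        n_true += true_t.size
        n_det += det_t.size
        used = np.zeros(det_t.size, dtype=bool)
        for t in true_t:
            d = np.abs(det_t - t)
            ok = np.flatnonzero((d <= 5e-4) & ~used)
            if ok.size:
                used[ok[0]] = True
                matched += 1
    assert matched / n_true >= 0.95
    assert matched / n_det >= 0.95
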