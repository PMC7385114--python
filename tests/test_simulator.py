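import numpy as np
import pytest

from mea_trainer.protocol import build_recording_plan
from mea_trainer.simulate import (
    SyntheticNetworkConfig,
    WaveformTemplate,
    render_raw,
    simulate_spikes,
)
from mea_trainer.types import standard_layout


def test_poisson_only_total_count_within_3sd():
    cfg = SyntheticNetworkConfig(
        n_electrodes=60,
        duration_s=1200.0,
        background_rate_hz=1.0,
        network_burst_rate_hz=0.0,
        participation_prob=0.0,
        seed=11,
    )
    spikes, truth = simulate_spikes(cfg)
    mean = 60 * 1200 * 1.0
    # refractory thinning removes ~rate*refractory ~0.2% of spikes
    assert abs(spikes.n_spikes - mean) < 3 * np.sqrt(mean) + 0.005 * mean
    assert truth.label_counts()["burst"] == 0


def test_degenerate_burst_shares_onsets():
    cfg = SyntheticNetworkConfig(
        n_electrodes=5,
        duration_s=10.0,
        background_rate_hz=0.0,
        network_burst_rate_hz=0.3,
        participation_prob=1.0,
        onset_jitter_s=0.0,
        seed=3,
    )
    spikes, truth = simulate_spikes(cfg)
    assert truth.burst_event_times.size > 0
    for ev in truth.burst_event_times:
        firsts = []
        for e in spikes.layout.electrode_ids:
            t = truth.times_with_label(e, "burst")
            t = t[(t >= ev - 1e-9)]
            if t.size:
                firsts.append(t[0])
        assert np.ptp(firsts) < 1e-9  # identical burst onsets with zero jitter


def test_determinism_same_seed():
    cfg = SyntheticNetworkConfig(n_electrodes=8, duration_s=30.0, seed=42)
    a, _ = simulate_spikes(cfg)
    b, _ = simulate_spikes(cfg)
    for e in a.layout.electrode_ids:
        assert np.array_equal(a.trains[e], b.trains[e])


def test_different_seed_differs():
    a, _ = simulate_spikes(SyntheticNetworkConfig(n_electrodes=4, duration_s=30.0, seed=1))
    b, _ = simulate_spikes(SyntheticNetworkConfig(n_electrodes=4, duration_s=30.0, seed=2))
    assert a.trains["E1"].size != b.trains["E1"].size or not np.array_equal(
        a.trains["E1"], b.trains["E1"]
    )


def test_refractory_enforced_and_logged():
    cfg = SyntheticNetworkConfig(
        n_electrodes=4,
        duration_s=20.0,
        background_rate_hz=50.0,  # dense: forces refractory collisions
        network_burst_rate_hz=0.5,
        refractory_s=0.005,
        seed=5,
    )
    spikes, truth = simulate_spikes(cfg)
    removed = sum(v.size for v in truth.removed_times.values())
    assert removed > 0
    for e in spikes.layout.electrode_ids:
        isis = np.diff(spikes.trains[e])
        assert np.all(isis >= cfg.refractory_s - 1e-12)


def test_truth_labels_partition_spikes():
    cfg = SyntheticNetworkConfig(n_electrodes=6, duration_s=60.0, seed=9)
    spikes, truth = simulate_spikes(cfg)
    for e in spikes.layout.electrode_ids:
        assert truth.spike_times[e].size == spikes.trains[e].size
        assert truth.spike_labels[e].size == spikes.trains[e].size
        assert np.array_equal(truth.spike_times[e], spikes.trains[e])


def test_evoked_spikes_follow_pulses():
    plan = build_recording_plan(120.0, n_blocks=1, cycles_per_block=10)
    cfg = SyntheticNetworkConfig(
        n_electrodes=4,
        duration_s=120.0,
        background_rate_hz=0.0,
        network_burst_rate_hz=0.0,
        stim_plan=plan,
        p_evoke=1.0,
        seed=12,
    )
    spikes, truth = simulate_spikes(cfg)
    pulses = plan.all_pulses()
    for e in spikes.layout.electrode_ids:
        ev = truth.times_with_label(e, "evoked")
        for t in ev:
            lat = t - pulses[:, 0]
            lat = lat[lat > 0]
            assert lat.min() >= 0.001 - 1e-9 and lat.min() <= 0.010 + 1e-9


def test_post_stim_suppression_lowers_rate():
    plan = build_recording_plan(200.0, n_blocks=1, cycles_per_block=10)
    base = dict(
        n_electrodes=20,
        duration_s=200.0,
        background_rate_hz=5.0,
        network_burst_rate_hz=0.0,
        participation_prob=0.0,
        stim_plan=plan,
        p_evoke=0.0,
        post_stim_tau_s=10.0,
        seed=7,
    )
    suppressed, _ = simulate_spikes(SyntheticNetworkConfig(post_stim_gain=0.05, **base))
    control, _ = simulate_spikes(SyntheticNetworkConfig(post_stim_gain=1.0, **base))
    (_, b1), = plan.block_intervals()

    def rate(s, lo, hi):
        return sum(
            np.count_nonzero((s.trains[e] >= lo) & (s.trains[e] < hi))
            for e in s.layout.electrode_ids
        ) / (hi - lo)

    assert rate(suppressed, b1, b1 + 5) < 0.5 * rate(control, b1, b1 + 5)
    # pre-stimulation rates are unaffected
    assert rate(suppressed, 0, 50) == pytest.approx(rate(control, 0, 50), rel=0.15)


def test_ground_electrode_is_silent():
    layout = standard_layout(10, ground_id="GND")
    cfg = SyntheticNetworkConfig(n_electrodes=10, duration_s=30.0, seed=2)
    spikes, _ = simulate_spikes(cfg, layout)
    assert spikes.trains["GND"].size == 0


def test_template_shape_valid():
    t = WaveformTemplate.default()
    assert t.trough_uv == pytest.approx(-60.0, rel=0.05)
    trough = np.argmin(t.samples)
    assert np.max(t.samples[trough:]) > 10.0  # opposite-sign rebound


def test_render_pure_drift(layout2, trains_factory):
    s = trains_factory(layout2, 1.0)
    raw = render_raw(
        s, WaveformTemplate.default(), noise_sd_uv=0.0,
        drift_components=[(1.0, 50.0)], seed=0,
    )
    t = raw.times()
    assert np.allclose(raw.samples[:, 0], 50.0 * np.sin(2 * np.pi * t), atol=1e-9)


def test_render_single_template(layout2, trains_factory):
    s = trains_factory(layout2, 1.0, E1=[0.5])
    tmpl = WaveformTemplate.default()
    raw = render_raw(s, tmpl, noise_sd_uv=0.0, seed=0)
    x = raw.samples[:, 0]
    assert np.argmin(x) == 5000  # trough lands exactly at the spike sample
    assert x.min() == pytest.approx(tmpl.trough_uv)
    assert np.all(raw.samples[:, 1] == 0)


def test_render_truncates_edge_spike_with_warning(layout2, trains_factory):
    s = trains_factory(layout2, 1.0, E1=[0.99995])
    with pytest.warns(UserWarning, match="truncated"):
        render_raw(s, WaveformTemplate.default(), noise_sd_uv=0.0, seed=0)
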