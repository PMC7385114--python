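import math

import numpy as np
import pytest

from mea_trainer.errors import ValidationError
from mea_trainer.simulate import SyntheticNetworkConfig, simulate_spikes
from mea_trainer.spectral import bin_spikes
from mea_trainer.synchrony import (
    SynchronyConfig,
    pre_post_ratio,
    spatial_map,
    synchrony_matrix,
    timecourse_synchrony,
    zero_lag_correlation,
)
from mea_trainer.types import ElectrodeLayout, SpikeTrainSet, standard_layout


def chi_oracle(f, g):
    """Direct evaluation of the zero-lag normalized cross-correlation."""
    num = sum(a * b for a, b in zip(f, g))
    na = sum(a * a for a in f)
    nb = sum(b * b for b in g)
    if na == 0 or nb == 0:
        return float("nan")
    return num / math.sqrt(na * nb)


def test_identical_vectors_give_unity():
    v = np.array([0, 2, 1, 0, 3], dtype=float)
    assert zero_lag_correlation(v, v) == 1.0


def test_disjoint_supports_give_zero():
    a = np.array([1, 1, 0, 0], dtype=float)
    b = np.array([0, 0, 1, 1], dtype=float)
    assert zero_lag_correlation(a, b) == 0.0


def test_worked_example():
    a = np.zeros(6)
    a[[1, 2, 3, 4]] = 1
    b = np.zeros(6)
    b[[1, 2]] = 1
    assert zero_lag_correlation(a, b) == pytest.approx(2 / math.sqrt(8), abs=1e-12)


def test_all_zero_is_missing_not_zero():
    assert np.isnan(zero_lag_correlation(np.zeros(5), np.ones(5)))


def test_length_mismatch():
    with pytest.raises(ValidationError):
        zero_lag_correlation(np.ones(3), np.ones(4))


def test_matrix_equals_bruteforce(trains_factory):
    rng = np.random.default_rng(0)
    layout = standard_layout(8)
    duration = 5.0  # 100 bins at 50 ms
    trains = {
        e: np.unique(rng.uniform(0, duration, size=rng.integers(5, 40)))
        for e in layout.electrode_ids
    }
    spikes = SpikeTrainSet(trains, duration, layout)
    cfg = SynchronyConfig()
    m = synchrony_matrix(spikes, config=cfg)
    binned = [
        bin_spikes(trains[e], cfg.bin_width_s, duration) for e in layout.electrode_ids
    ]
    assert binned[0].size == 100
    for i in range(8):
        for j in range(8):
            expected = 1.0 if i == j else chi_oracle(binned[i], binned[j])
            assert m.values[i, j] == expected  # integer counts: bit-exact


def test_60_electrode_matrix_shape():
    cfg = SyntheticNetworkConfig(n_electrodes=60, duration_s=60.0, seed=13)
    spikes, _ = simulate_spikes(cfg)
    m = synchrony_matrix(spikes)
    assert m.values.shape == (60, 60)
    active = [i for i, e in enumerate(m.electrode_ids) if spikes.trains[e].size]
    assert np.allclose(np.diag(m.values)[active], 1.0)
    finite = m.values[np.isfinite(m.values)]
    assert np.all(finite >= -1e-12) and np.all(finite <= 1 + 1e-12)
    assert m.values == pytest.approx(m.values.T, nan_ok=True)


def test_identical_trains_chi_bar_one(trains_factory, layout3):
    t = [0.1, 0.5, 0.9, 1.5]
    s = trains_factory(layout3, 2.0, E1=t, E2=t, E3=t)
    m = synchrony_matrix(s, config=SynchronyConfig(bin_width_s=0.1))
    assert m.mean == pytest.approx(1.0)
    assert np.allclose(m.mean_per_electrode, 1.0)


def test_silent_electrode_missing_not_deflating(trains_factory, layout3):
    t = [0.1, 0.5, 0.9]
    s = trains_factory(layout3, 2.0, E1=t, E2=t)  # E3 silent
    m = synchrony_matrix(s, config=SynchronyConfig(bin_width_s=0.1))
    i3 = m.electrode_ids.index("E3")
    assert np.isnan(m.values[i3]).all()
    assert m.mean == pytest.approx(1.0)  # silent pair excluded from the average


def test_poisson_chi_within_3sd_of_monte_carlo():
    """chi-bar of independent Poisson trains concentrates at its MC expectation."""
    rng = np.random.default_rng(42)
    rate, width, n_bins, n_el = 2.0, 0.05, 500, 8

    def chi_bar_once(r):
        counts = r.poisson(rate * width, size=(n_el, n_bins)).astype(float)
        sq = (counts**2).sum(axis=1)
        vals = []
        for i in range(n_el):
            for j in range(i + 1, n_el):
                if sq[i] > 0 and sq[j] > 0:
                    vals.append(counts[i] @ counts[j] / math.sqrt(sq[i] * sq[j]))
        return float(np.mean(vals))

    mc = np.array([chi_bar_once(rng) for _ in range(200)])
    layout = standard_layout(n_el)
    r2 = np.random.default_rng(7)
    duration = n_bins * width
    trains = {
        e: np.unique(r2.uniform(0, duration, size=r2.poisson(rate * duration)))
        for e in layout.electrode_ids
    }
    spikes = SpikeTrainSet(trains, duration, layout)
    m = synchrony_matrix(spikes, config=SynchronyConfig(bin_width_s=width))
    assert abs(m.mean - mc.mean()) < 3 * mc.std()


def test_permutation_invariance():
    cfg = SyntheticNetworkConfig(n_electrodes=6, duration_s=30.0, seed=3)
    spikes, _ = simulate_spikes(cfg)
    ids = list(spikes.layout.recording_ids())
    m1 = synchrony_matrix(spikes, ids)
    perm = ids[::-1]
    m2 = synchrony_matrix(spikes, perm)
    k = [perm.index(e) for e in ids]
    assert np.allclose(m2.values[np.ix_(k, k)], m1.values, equal_nan=True)
    assert m2.mean == pytest.approx(m1.mean)


def test_fewer_than_two_electrodes_rejected(trains_factory, layout2):
    s = trains_factory(layout2, 1.0, E1=[0.5])
    with pytest.raises(ValidationError):
        synchrony_matrix(s, ["E1"])


def test_spatial_map_is_row_means():
    cfg = SyntheticNetworkConfig(n_electrodes=6, duration_s=30.0, seed=4)
    spikes, _ = simulate_spikes(cfg)
    m = synchrony_matrix(spikes)
    grid = spatial_map(m, spikes.layout)
    for e, v in zip(m.electrode_ids, m.mean_per_electrode):
        r, c = spikes.layout.grid_positions[spikes.layout.index_of(e)]
        assert grid[r, c] == pytest.approx(v, nan_ok=True)


def test_spatial_map_unknown_electrode(trains_factory, layout2):
    s = trains_factory(layout2, 2.0, E1=[0.1], E2=[0.1])
    m = synchrony_matrix(s, config=SynchronyConfig(bin_width_s=0.1))
    other = ElectrodeLayout(("X1", "X2"), ((0, 0), (0, 1)))
    with pytest.raises(ValidationError):
        spatial_map(m, other)


def test_timecourse_segment_count():
    cfg = SyntheticNetworkConfig(n_electrodes=5, duration_s=1200.0, seed=5)
    spikes, _ = simulate_spikes(cfg)
    tc = timecourse_synchrony(spikes)
    assert tc["chi_series"].size == 120
    assert tc["chi_raster"].shape == (5, 120)


def test_timecourse_consistent_with_global():
    cfg = SyntheticNetworkConfig(
        n_electrodes=20,
        duration_s=1200.0,
        seed=6,
        participation_prob=0.9,
        network_burst_rate_hz=0.4,
    )
    spikes, _ = simulate_spikes(cfg)
    tc = timecourse_synchrony(spikes)
    m = synchrony_matrix(spikes)
    assert abs(np.nanmean(tc["chi_series"]) - m.mean) < 0.05


def test_silent_segment_missing(trains_factory, layout2):
    s = trains_factory(layout2, 30.0, E1=[1.0, 2.0], E2=[1.0, 2.5])
    tc = timecourse_synchrony(s, config=SynchronyConfig())
    assert np.isfinite(tc["chi_series"][0])
    assert np.isnan(tc["chi_series"][1:]).all()


def test_pre_post_ratio_identical_dynamics(trains_factory, layout2):
    t = np.concatenate([np.arange(0.05, 100, 0.11), np.arange(120.05, 220, 0.11)])
    s = trains_factory(layout2, 220.0, E1=np.unique(t), E2=np.unique(t))
    tc = timecourse_synchrony(s)
    out = pre_post_ratio(tc, (100.0, 120.0), window_s=50.0)
    assert out["defined"]
    assert out["ratio"] == pytest.approx(1.0, abs=1e-9)


def test_pre_post_ratio_silent_pre_flagged(trains_factory, layout2):
    s = trains_factory(
        layout2, 100.0, E1=np.arange(60.0, 99.0, 0.5), E2=np.arange(60.0, 99.0, 0.5)
    )
    tc = timecourse_synchrony(s)
    out = pre_post_ratio(tc, (40.0, 50.0), window_s=20.0)
    assert not out["defined"]
    assert np.isnan(out["ratio"])
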