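"""Synthetic session generator: determinism, Poisson structure, RF maps."""

import numpy as np
import pytest
from scipy import stats as sps

from onoffnet.markov import MarkovRates, episode_durations
from onoffnet.sessions import (
    RFGrid,
    RateDistribution,
    SessionConfig,
    generate_rf_map,
    generate_session,
    load_session,
    rf_center_of_mass,
    sample_rate_pairs,
    save_session,
)


def _cfg(**kw):
    base = dict(
        n_trials_per_condition=10,
        n_attention=2,
        n_orientations=2,
        seed=3,
    )
    base.update(kw)
    return SessionConfig(**base)


def test_same_config_same_seed_is_bit_identical():
    a = generate_session(_cfg())
    b = generate_session(_cfg())
    assert np.array_equal(a.counts, b.counts)
    assert np.array_equal(a.ground_truth["states"], b.ground_truth["states"])
    c = generate_session(_cfg(seed=4))
    assert not np.array_equal(a.counts, c.counts)


def test_counts_are_nonnegative_integers_with_condition_labels():
    rec = generate_session(_cfg())
    assert rec.counts.min() >= 0
    assert np.issubdtype(rec.counts.dtype, np.integer)
    conds = set(zip(rec.trial_meta.attention, rec.trial_meta.orientation))
    assert conds == {(a, o) for a in range(2) for o in range(2)}
    # windows within the configured range (plus the 0.4 s pre-period)
    w = rec.trial_meta.window.to_numpy()
    assert w.min() >= 0.2 - 1e-12 and w.max() <= 1.9 + 1e-12


def test_flat_channels_have_unit_fano_factor():
    """delta_r = 0 on all channels: per-channel counts are pure Poisson, so
    the Fano factor converges to 1 (within 3 SE at 2000 trials)."""
    cfg = _cfg(
        n_trials_per_condition=2000,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(0.5, 0.5),
        session_type="one_phase",
        seed=9,
    )
    rec = generate_session(cfg)
    counts = rec.counts[:, :, 40:90].sum(axis=2)  # 0.5 s window
    for c in range(rec.n_channels):
        x = counts[:, c]
        ff = x.var(ddof=1) / x.mean()
        se = np.sqrt(2.0 / (len(x) - 1))
        assert abs(ff - 1.0) < 3 * se


def test_on_fraction_matches_stationary_occupancy():
    cfg = _cfg(
        n_trials_per_condition=500,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(1.0, 1.0),
        rates_control=MarkovRates(10.0, 10.0),
        rates_attention=MarkovRates(10.0, 10.0),
        seed=13,
    )
    rec = generate_session(cfg)
    states = rec.ground_truth["states"]
    frac = states[states >= 0].mean()
    assert abs(frac - 0.5) < 0.02


def test_ground_truth_episodes_are_exponential_with_correct_means():
    """>= 1e4 interior episodes: means within 5% of 1/alpha and KS
    exponentiality not rejected at 1% (subtractive bin dither)."""
    cfg = _cfg(
        n_trials_per_condition=1200,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(1.9, 1.9),
        rates_control=MarkovRates(10.0, 10.0),
        rates_attention=MarkovRates(10.0, 10.0),
        seed=17,
    )
    rec = generate_session(cfg)
    states = rec.ground_truth["states"]
    dt = rec.bin_width
    rng = np.random.default_rng(0)
    on, off = episode_durations(np.where(states < 0, 0, states), dt)
    assert on.size >= 10_000
    assert abs(on.mean() - 0.1) / 0.1 < 0.05
    assert abs(off.mean() - 0.1) / 0.1 < 0.05
    for d in (on, off):
        dd = d - rng.random(d.size) * dt
        assert sps.kstest(dd, "expon", args=(0, dd.mean())).pvalue > 0.01


def test_counts_conditionally_poisson_given_state():
    """Conditional on the state sequence, bin counts have unit index of
    dispersion."""
    cfg = _cfg(
        n_trials_per_condition=1500,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(0.5, 0.5),
        seed=19,
    )
    rec = generate_session(cfg)
    states = rec.ground_truth["states"]
    ch = 3
    for s_val in (0, 1):
        mask = states == s_val
        vals = np.concatenate(
            [rec.counts[t, ch, mask[t]] for t in range(rec.n_trials)]
        )
        disp = vals.var(ddof=1) / vals.mean()
        assert abs(disp - 1.0) < 3 * np.sqrt(2.0 / (vals.size - 1))


def test_rate_pair_sampler_constraints_and_mean():
    dist = RateDistribution(median_delta=80.0, sigma_delta=0.6)
    pairs = sample_rate_pairs(100_000, dist, seed=0)
    r_on, r_off = pairs[:, 0], pairs[:, 1]
    assert np.all(r_on >= r_off) and np.all(r_off >= 0)
    dr = r_on - r_off
    assert abs(dr.mean() - dist.mean_delta) / dist.mean_delta < 0.02
    # degenerate distribution: all pairs identical
    degen = RateDistribution(sigma_off=0.0, sigma_delta=0.0)
    p2 = sample_rate_pairs(10, degen, seed=1)
    assert np.allclose(p2, p2[0])
    with pytest.raises(ValueError):
        sample_rate_pairs(0)


def test_rf_center_of_mass_point_mass_and_symmetry():
    grid = RFGrid()
    m = np.zeros((6, 6))
    m[2, 4] = 3.0
    assert rf_center_of_mass(m, grid) == (grid.xs[2], grid.ys[4])
    sym = np.ones((6, 6))
    cx, cy = rf_center_of_mass(sym, grid)
    assert cx == pytest.approx(grid.xs.mean())
    assert cy == pytest.approx(grid.ys.mean())
    with pytest.raises(ValueError):
        rf_center_of_mass(np.zeros((6, 6)), grid)


def test_rf_shift_accumulates_across_channels():
    """0.3 dva per channel step spans 4.5 dva over 16 channels."""
    c0 = generate_rf_map(0, rf_shift=0.3)
    c15 = generate_rf_map(15, rf_shift=0.3)
    d = np.hypot(c15[0] - c0[0], c15[1] - c0[1])
    assert d == pytest.approx(4.5, abs=0.15)
    rec = generate_session(_cfg(rf_shift=0.3))
    xs = rec.channel_meta.rf_x.to_numpy()
    assert np.all(np.diff(xs) > 0)  # monotone drift along the channel axis


def test_invalid_configs_name_the_offending_field():
    with pytest.raises(ValueError, match="bin_width"):
        SessionConfig(bin_width=0.0)
    with pytest.raises(ValueError, match="trial_window_range"):
        SessionConfig(trial_window_range=(0.5, 0.2))
    with pytest.raises(ValueError, match="alpha"):
        MarkovRates(-1.0, 2.0)
    with pytest.raises(ValueError, match="median_off"):
        RateDistribution(median_off=0.0)


def test_session_round_trip_through_hdf5(tmp_path):
    rec = generate_session(_cfg())
    path = str(tmp_path / "session.h5")
    save_session(rec, path)
    back = load_session(path)
    assert np.array_equal(back.counts, rec.counts)
    assert np.array_equal(back.ground_truth["states"], rec.ground_truth["states"])
    assert back.bin_width == rec.bin_width
    assert list(back.channel_meta.layer) == list(rec.channel_meta.layer)
    assert back.ground_truth["rates_control"] == rec.ground_truth["rates_control"]
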