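"""Bistable column dynamics: nullclines, metastable switching, doubly
stochastic spikes and the binary-unit reduction estimates."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from onoffnet.column import (
    CANONICAL,
    ColumnParams,
    F,
    estimate_effective_rates,
    generate_spikes,
    nullclines,
    simulate_column,
)
from onoffnet.markov import MarkovRates, episode_durations, sample_state_bins
from onoffnet.theory import CountMomentInputs, count_variance


@pytest.mark.parametrize(
    "r,expected",
    [(0.0, 0.0), (1.0, 0.0), (-0.75, -0.25), (0.25, 0.25), (-1.0, 0.0), (0.5, 0.5)],
)
def test_piecewise_linear_self_coupling(r, expected):
    assert F(r) == pytest.approx(expected)


def test_nullclines_canonical_bistable_with_saddle():
    nc = nullclines(CANONICAL)
    assert nc.bistable
    branches = {fp.branch for fp in nc.fixed_points}
    assert branches == {"on", "off", "middle"}
    saddle = [fp for fp in nc.fixed_points if fp.branch == "middle"][0]
    assert not saddle.stable
    # symmetric wells at f = 0, I = 0
    on = [fp for fp in nc.stable if fp.branch == "on"][0]
    off = [fp for fp in nc.stable if fp.branch == "off"][0]
    assert on.r == pytest.approx(-off.r)
    # a-nullcline passes through a = f at r = 0
    assert nc.a_nullcline(0.0, CANONICAL.g, CANONICAL.f) == CANONICAL.f


def test_strong_attention_removes_off_fixed_point():
    nc = nullclines(replace(CANONICAL, I_att=0.6))
    assert not nc.bistable
    assert all(fp.branch != "off" for fp in nc.fixed_points)


def test_deterministic_system_stays_at_fixed_point():
    p = replace(CANONICAL, Q=0.0)
    nc = nullclines(p)
    on_r = max(fp.r for fp in nc.stable)
    tr = simulate_column(p, duration=2.0, seed=0, initial="on")
    assert np.all(np.abs(tr.r - on_r) < 1e-6)
    assert tr.S.min() == 1  # no transitions


def test_integration_step_guard():
    with pytest.raises(ValueError, match="epsilon"):
        simulate_column(CANONICAL, duration=1.0, seed=0, substeps=1)


def test_canonical_rates_near_ten_per_second_and_exponential_durations():
    """The canonical column switches at ~10/s in both directions with
    exponentially distributed episode durations (KS at 1%)."""
    tr = simulate_column(CANONICAL, duration=1500.0, seed=2)
    ton, toff, rates = tr.episode_stats()
    assert abs(rates.alpha1 - 10.0) < 1.5
    assert abs(rates.alpha2 - 10.0) < 1.5
    rng = np.random.default_rng(0)
    on, off = episode_durations(tr.S, tr.dt)
    for d in (on, off):
        dd = d - rng.random(d.size) * tr.dt
        assert sps.kstest(dd, "expon", args=(0, dd.mean())).pvalue > 0.01


def test_attention_current_lengthens_on_shortens_off():
    base = simulate_column(CANONICAL, 800.0, seed=3).episode_stats()
    att = simulate_column(replace(CANONICAL, I_att=0.005), 800.0, seed=3).episode_stats()
    assert att[0] > base[0]  # tau_on longer under attention
    assert att[1] < base[1]  # tau_off shorter


def test_renewal_identity_for_occupancy():
    """Stationary On fraction equals tau_on / (tau_on + tau_off)."""
    tr = simulate_column(CANONICAL, 1000.0, seed=5)
    ton, toff, _ = tr.episode_stats()
    frac = tr.S.mean()
    assert abs(frac - ton / (ton + toff)) < 0.02


def test_noise_in_rate_equation_preserves_phenomenology():
    """Placing the white noise in the rate equation instead of the
    adaptation equation (with an intensity giving comparable dwell times)
    preserves the qualitative picture: symmetric metastable switching with
    near-exponential (CV ~ 1) episode durations."""
    p = replace(CANONICAL, Q=0.03)
    tr = simulate_column(p, 600.0, seed=11, noise_target="rate")
    on, off = episode_durations(tr.S, tr.dt)
    assert on.size > 200 and off.size > 200
    assert 0.75 < on.std() / on.mean() < 1.25
    assert 0.75 < off.std() / off.mean() < 1.25
    assert 0.35 < tr.S.mean() < 0.65


def test_spike_generation_homogeneous_limits():
    rng = np.random.default_rng(7)
    S0 = np.zeros((4000, 20), dtype=np.int8)
    counts = generate_spikes(S0, [(50.0, 20.0)], T=0.2, seed=rng, dt=0.01)
    mean = counts.mean()
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(mean - 20.0 * 0.2) < 3 * se
    # delta_r = 0: Fano factor -> 1 regardless of the state sequence
    S1 = (rng.random((4000, 20)) < 0.5).astype(np.int8)
    c2 = generate_spikes(S1, [(30.0, 30.0)], T=0.2, seed=rng, dt=0.01)[:, 0]
    ff = c2.var(ddof=1) / c2.mean()
    assert abs(ff - 1.0) < 3 * np.sqrt(2 / (len(c2) - 1))
    with pytest.raises(ValueError):
        generate_spikes(S0, [(10.0, -1.0)], T=0.2)
    with pytest.raises(ValueError):
        generate_spikes(S0, [(50.0, 20.0)], T=1.0, dt=0.01)  # window too long


def test_spike_count_variance_matches_closed_form():
    """Doubly stochastic counts over a 0.2 s window reproduce the predicted
    variance within 1% at 1e5 trials."""
    r = MarkovRates(10.0, 10.0)
    rng = np.random.default_rng(9)
    S = sample_state_bins(r, 200, 0.001, 100_000, rng)
    counts = generate_spikes(S, [(50.0, 10.0)], T=0.2, seed=rng, dt=0.001)[:, 0]
    pred = count_variance(CountMomentInputs(rates=r, r_on=50.0, r_off=10.0, T=0.2))
    assert abs(counts.var(ddof=1) - pred) / pred < 0.01


def test_effective_rates_uncoupled_and_zero_laplacian():
    """With W = 0 the coupling slopes vanish and the zero-Laplacian rates
    equal the isolated-unit rates."""
    p = replace(CANONICAL, W=0.0)
    er = estimate_effective_rates(p, duration=300.0, seed=1)
    assert abs(er.beta1) < 2 * max(er.beta1_se, 0.3)
    assert abs(er.beta2) < 2 * max(er.beta2_se, 0.3)
    iso = simulate_column(p, 600.0, seed=2).episode_stats()[2]
    assert abs(er.baseline.alpha1 - iso.alpha1) / iso.alpha1 < 0.2
    assert abs(er.baseline.alpha2 - iso.alpha2) / iso.alpha2 < 0.2


def test_effective_coupling_positive_and_on_side_falls_with_attention():
    """With lateral coupling the Off->On rate grows with On neighbors
    (beta1 > 0); an excitatory attentional current weakens the On->Off
    coupling efficacy (beta2 falls), the mechanism behind the shrinking
    correlation length."""
    base = estimate_effective_rates(CANONICAL, duration=300.0, seed=4)
    att = estimate_effective_rates(
        replace(CANONICAL, I_att=0.01), duration=300.0, seed=4
    )
    assert base.beta1 > 0 and base.beta2 > 0
    assert att.beta2 < base.beta2
    assert att.beta_eff < base.beta_eff
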