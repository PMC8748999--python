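"""Shared-state Poisson HMM: forward-backward oracle equivalence, EM
recovery, model selection and decoding."""

import numpy as np
import pytest

from onoffnet.hmm import (
    HMMFit,
    HMMParams,
    _forward_backward_fast,
    decode_states,
    fit_hmm,
    forward_backward,
    free_parameter_count,
    rates_from_transition_probs,
    select_n_phases,
    variance_explained,
)
from onoffnet.markov import MarkovRates
from onoffnet.sessions import RateDistribution, SessionConfig, generate_session


def _enumerate_posteriors(logB, logP, log_pi):
    """Brute-force posteriors by summing over all K^B state paths."""
    T, K = logB.shape
    paths = np.array(np.meshgrid(*[range(K)] * T, indexing="ij")).reshape(T, -1).T
    logw = log_pi[paths[:, 0]] + logB[0, paths[:, 0]]
    for t in range(1, T):
        logw = logw + logP[paths[:, t - 1], paths[:, t]] + logB[t, paths[:, t]]
    w = np.exp(logw - logw.max())
    w /= w.sum()
    gamma = np.zeros((T, K))
    for t in range(T):
        for k in range(K):
            gamma[t, k] = w[paths[:, t] == k].sum()
    ll = float(np.log(np.exp(logw - logw.max()).sum()) + logw.max())
    return gamma, ll


@pytest.mark.parametrize("K,T", [(2, 10), (2, 12), (3, 7)])
def test_forward_backward_matches_path_enumeration(K, T):
    """Posteriors and likelihood agree with exhaustive enumeration of all
    K^T paths to 1e-10."""
    rng = np.random.default_rng(K * 100 + T)
    logB = np.log(rng.uniform(0.05, 1.0, size=(T, K)))
    P = rng.uniform(0.1, 1.0, size=(K, K))
    P /= P.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.1, 1.0, K)
    pi /= pi.sum()
    gamma, xi, ll = forward_backward(logB, np.log(P), np.log(pi))
    gamma_ref, ll_ref = _enumerate_posteriors(logB, np.log(P), np.log(pi))
    assert np.allclose(gamma, gamma_ref, atol=1e-10)
    assert ll == pytest.approx(ll_ref, abs=1e-10)
    # the scaled fast path agrees with the log-space reference
    gamma_f, xi_f, ll_f = _forward_backward_fast(logB, P, pi)
    assert np.allclose(gamma_f, gamma, atol=1e-10)
    assert np.allclose(xi_f, xi, atol=1e-10)
    assert ll_f == pytest.approx(ll, abs=1e-8)


def test_free_parameter_count_two_phase_16_channels():
    """The two-phase, 16-channel model has exactly 34 free parameters."""
    assert free_parameter_count(2, 16) == 34
    assert free_parameter_count(1, 16) == 16
    assert free_parameter_count(3, 16) == 54


@pytest.mark.parametrize(
    "p_on,p_off,a1,a2",
    [(0.95, 0.9, 10.0, 5.0), (0.5, 1.0, 0.0, 50.0), (1.0, 0.99, 1.0, 0.0)],
)
def test_rates_from_transition_probs(p_on, p_off, a1, a2):
    r = rates_from_transition_probs(p_on, p_off, 0.01)
    assert r.alpha1 == pytest.approx(a1)
    assert r.alpha2 == pytest.approx(a2)


def test_rates_from_transition_probs_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rates_from_transition_probs(1.2, 0.5, 0.01)
    with pytest.raises(ValueError):
        rates_from_transition_probs(0.5, 0.5, 0.0)


def test_transition_matrix_rows_stochastic_and_loglik_monotone(
    small_two_phase_session,
):
    fit = fit_hmm(small_two_phase_session, condition=(0, 0), n_restarts=2, seed=0)
    P = fit.params.transition_matrix
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    ll = fit.loglik_trace
    drops = np.diff(ll)
    assert np.all(drops >= -1e-8 * np.abs(ll[:-1]))
    # posteriors are probabilities over phases
    for g in fit.posteriors:
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-8)


def test_single_phase_fit_is_mean_rate(small_two_phase_session):
    """The 1-phase M-step has the closed form total count / total time."""
    rec = small_two_phase_session
    fit = fit_hmm(rec, condition=(0, 0), n_phases=1, n_restarts=1, seed=0)
    start = fit.fit_start_bin
    tot = np.zeros(rec.n_channels)
    n_bins = 0
    for t in rec.trial_indices((0, 0)):
        c = rec.trial_counts(int(t))[start:]
        tot += c.sum(axis=0)
        n_bins += c.shape[0]
    expected = tot / (n_bins * rec.bin_width)
    assert np.allclose(fit.params.rates[0], expected, rtol=1e-10)


def test_em_recovers_generator_parameters(recovery_session):
    """EM on a 500-trial two-phase session recovers every channel rate and
    both transition rates within 10% relative error."""
    rec = recovery_session
    fit = fit_hmm(rec, condition=(0, 0), n_restarts=3, seed=1)
    gt = rec.ground_truth
    r_off_hat = fit.params.rates[0]
    r_on_hat = fit.params.rates[1]
    assert np.all(np.abs(r_on_hat - gt["r_on"]) / gt["r_on"] < 0.10)
    assert np.all(np.abs(r_off_hat - gt["r_off"]) / gt["r_off"] < 0.10)
    est = fit.params.markov_rates()
    assert abs(est.alpha1 - 10.0) / 10.0 < 0.10
    assert abs(est.alpha2 - 10.0) / 10.0 < 0.10


def test_phase_ordering_resolves_label_switching(recovery_session):
    fit = fit_hmm(recovery_session, condition=(0, 0), n_restarts=2, seed=3)
    pop = fit.params.rates.sum(axis=1)
    assert pop[1] > pop[0]  # On phase last


def _mini_session(session_type, seed, delta_median=120.0, n_trials=32):
    cfg = SessionConfig(
        n_trials_per_condition=n_trials,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(1.0, 1.0),
        session_type=session_type,
        rates_control=MarkovRates(10.0, 10.0),
        rates_attention=MarkovRates(10.0, 10.0),
        rate_distribution=RateDistribution(median_delta=delta_median),
        seed=seed,
    )
    return generate_session(cfg)


def test_model_selection_distinguishes_one_and_two_phase_sessions():
    """Cross-validated selection picks 2 phases for switching sessions and
    1 phase for flat ones; the n=1 error self-normalises to 1."""
    two = _mini_session("two_phase", seed=21)
    sel2 = select_n_phases(two, condition=(0, 0), candidates=range(1, 5), seed=0)
    assert sel2.cv_errors[0] == pytest.approx(1.0)
    assert sel2.n_phases == 2 and not sel2.is_one_phase

    one = _mini_session("one_phase", seed=22)
    sel1 = select_n_phases(one, condition=(0, 0), candidates=range(1, 5), seed=0)
    assert sel1.n_phases == 1 and sel1.is_one_phase


def test_decode_states_separable_rates_and_durations():
    """With delta_r >> r_off the Viterbi path equals the generator path and
    mean decoded On duration approaches 1/alpha2."""
    cfg = SessionConfig(
        n_trials_per_condition=200,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(1.0, 1.0),
        rates_control=MarkovRates(10.0, 10.0),
        rates_attention=MarkovRates(10.0, 10.0),
        rate_distribution=RateDistribution(
            median_off=20.0, sigma_off=0.0, median_delta=400.0, sigma_delta=0.0
        ),
        seed=31,
    )
    rec = generate_session(cfg)
    fit = fit_hmm(rec, condition=(0, 0), n_restarts=2, seed=0)
    dec = decode_states(fit, rec, condition=(0, 0))
    # decoded vs true state, bin by bin, over the fit window
    start = fit.fit_start_bin
    agree, total = 0, 0
    for k, t in enumerate(fit.trial_indices):
        truth = rec.ground_truth["states"][t, start : start + len(dec.states[k])]
        agree += int((dec.states[k] == truth).sum())
        total += len(truth)
    assert agree / total > 0.97
    interior = dec.on_durations[~dec.censored_on]
    assert abs(interior.mean() - 0.1) / 0.1 < 0.10


def test_decode_all_on_truth_is_single_censored_episode():
    rates = np.array([[5.0] * 4, [50.0] * 4])
    P = np.array([[0.99, 0.01], [0.01, 0.99]])
    params = HMMParams(
        rates=rates, transition_matrix=P, initial_distribution=np.array([0.5, 0.5])
    )

    class _Rec:
        bin_width = 0.01

        def __init__(self):
            rng = np.random.default_rng(0)
            self.counts = rng.poisson(0.5, size=(4, 4, 100))

        def trial_indices(self, condition):
            return np.arange(4)

        def trial_counts(self, t):
            return self.counts[t].T

        trial_meta = None

    rec = _Rec()
    fit = HMMFit(
        params=params,
        loglik_trace=np.array([0.0]),
        posteriors=[],
        trial_indices=np.arange(4),
        fit_start_bin=0,
        converged=True,
    )
    dec = decode_states(fit, rec, condition="all")
    # rate 0.5/bin = 50 Hz == the On rate: every trial decodes all-On
    assert dec.on_durations.size == 4
    assert dec.censored_on.all()
    assert dec.off_durations.size == 0


def test_decode_requires_two_phases(small_two_phase_session):
    fit1 = fit_hmm(
        small_two_phase_session, condition=(0, 0), n_phases=1, n_restarts=1, seed=0
    )
    with pytest.raises(ValueError):
        decode_states(fit1, small_two_phase_session, condition=(0, 0))


def test_variance_explained_extremes_and_monotonicity():
    """Noise-free counts give R^2 = 1; flat sessions give R^2 near 0; R^2
    grows with the generator's On-Off rate difference."""
    # noiseless: counts manufactured to equal the expected rates exactly
    import pandas as pd

    rng = np.random.default_rng(5)
    states = (rng.random((30, 100)) < 0.5).astype(np.int8)
    r_off_hz, dr_hz = 1000.0, 3000.0
    counts = (10 + 30 * states[:, None, :].repeat(4, axis=1)).astype(np.int64)
    rec = type(
        "R",
        (),
        {
            "counts": counts,
            "bin_width": 0.01,
            "trial_meta": pd.DataFrame(
                {"attention": 0, "orientation": 0, "n_bins": 100, "window": 1.0},
                index=range(30),
            ),
            "trial_indices": lambda self, c: np.arange(30),
            "trial_counts": lambda self, t: counts[t].T,
            "n_channels": 4,
            "n_trials": 30,
        },
    )()
    fit = fit_hmm(rec, condition="all", n_restarts=1, seed=0, fit_start=0.0)
    assert variance_explained(fit, rec, condition="all") > 0.999

    r2 = []
    for dm in (0.0, 60.0, 150.0):
        cfg = SessionConfig(
            n_trials_per_condition=40,
            n_attention=1,
            n_orientations=1,
            trial_window_range=(1.0, 1.0),
            rates_control=MarkovRates(10.0, 10.0),
            rates_attention=MarkovRates(10.0, 10.0),
            session_type="two_phase",
            rate_distribution=RateDistribution(
                median_off=40.0, sigma_off=0.2,
                median_delta=max(dm, 1e-3), sigma_delta=0.0,
            ),
            seed=41,
        )
        if dm == 0.0:
            cfg = SessionConfig(
                **{**cfg.__dict__, "session_type": "one_phase"}
            )
        rec2 = generate_session(cfg)
        f2 = fit_hmm(rec2, condition=(0, 0), n_restarts=2, seed=0)
        r2.append(variance_explained(f2, rec2, condition=(0, 0)))
    assert abs(r2[0]) < 0.05
    assert r2[0] < r2[1] < r2[2]
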