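"""Shared-latent-state Poisson HMM for columnar population spiking.

The model: one unobserved population state switches between ``n_phases``
phases following a first-order Markov chain in discrete 10 ms bins; given
the phase, every channel's bin count is an independent Poisson draw with a
phase- and channel-specific rate.  For the two-phase, 16-channel model this
gives 34 free parameters: an On and an Off rate per channel (32) plus the
two self-transition probabilities p_on and p_off (the initial distribution
is tied to the stationary distribution of the transition matrix).  Fitted
per task condition with EM (log-space forward-backward E-step, closed-form
M-step), with the number of phases chosen by 4-fold cross-validation.

Phase identity is resolved deterministically: phases are ordered by
population mean rate, so for two phases index 0 is Off and index 1 is On.

Transition probabilities convert to continuous-time rates as
``alpha1 = (1 - p_off) / dt`` and ``alpha2 = (1 - p_on) / dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln, logsumexp

from .markov import MarkovRates

__all__ = [
    "HMMParams",
    "HMMFit",
    "PhaseSelection",
    "fit_hmm",
    "select_n_phases",
    "decode_states",
    "rates_from_transition_probs",
    "variance_explained",
    "forward_backward",
    "free_parameter_count",
]


@dataclass
class HMMParams:
    """Rates (n_phases, n_channels) in Hz, row-stochastic transition matrix
    and initial distribution (stationary distribution of the transitions)."""

    rates: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    bin_width: float = 0.010

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if self.rates.min() < 0:
            raise ValueError("rates must be >= 0")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_phases(self) -> int:
        return self.rates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.rates.shape[1]

    @property
    def p_off(self) -> float:
        """Probability of staying in the Off phase for one bin (2 phases)."""
        if self.n_phases != 2:
            raise ValueError("p_off defined for the two-phase model only")
        return float(self.transition_matrix[0, 0])

    @property
    def p_on(self) -> float:
        if self.n_phases != 2:
            raise ValueError("p_on defined for the two-phase model only")
        return float(self.transition_matrix[1, 1])

    def markov_rates(self) -> MarkovRates:
        return rates_from_transition_probs(self.p_on, self.p_off, self.bin_width)


def free_parameter_count(n_phases: int, n_channels: int) -> int:
    """Free parameters: a rate per channel per phase plus the off-diagonal
    transition probabilities; the initial distribution is tied to the
    stationary distribution and adds none."""
    return n_phases * n_channels + n_phases * (n_phases - 1)


@dataclass
class HMMFit:
    params: HMMParams
    loglik_trace: np.ndarray
    posteriors: list[np.ndarray]
    trial_indices: np.ndarray
    fit_start_bin: int
    converged: bool
    cv_errors: np.ndarray | None = None

    @property
    def log_likelihood(self) -> float:
        return float(self.loglik_trace[-1])


def rates_from_transition_probs(
    p_on: float, p_off: float, bin_width: float
) -> MarkovRates:
    """alpha1 = (1 - p_off)/dt (Off->On), alpha2 = (1 - p_on)/dt (On->Off)."""
    if not (0.0 <= p_on <= 1.0 and 0.0 <= p_off <= 1.0):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return MarkovRates((1.0 - p_off) / bin_width, (1.0 - p_on) / bin_width)


def _stationary(P: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.abs(np.real(v[:, i]))
    return pi / pi.sum()


def _log_emissions(counts: np.ndarray, rates: np.ndarray, dt: float) -> np.ndarray:
    """log p(counts_t | phase k); counts (T, C), rates (K, C) -> (T, K)."""
    lam = np.maximum(rates * dt, 1e-12)  # (K, C)
    return (
        counts @ np.log(lam).T
        - lam.sum(axis=1)[None, :]
        - gammaln(counts + 1.0).sum(axis=1)[:, None]
    )


def forward_backward(
    logB: np.ndarray, logP: np.ndarray, log_pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log-space forward-backward for one trial.

    Returns (gamma, xi_sum, loglik): posteriors (T, K), summed pairwise
    posteriors (K, K) and the log-likelihood of the sequence.
    """
    T, K = logB.shape
    la = np.empty((T, K))
    lb = np.empty((T, K))
    la[0] = log_pi + logB[0]
    for t in range(1, T):
        la[t] = logB[t] + logsumexp(la[t - 1][:, None] + logP, axis=0)
    lb[-1] = 0.0
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(logP + (logB[t + 1] + lb[t + 1])[None, :], axis=1)
    ll = float(logsumexp(la[-1]))
    gamma = np.exp(la + lb - ll)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        lxi = la[t][:, None] + logP + (logB[t + 1] + lb[t + 1])[None, :] - ll
        xi_sum += np.exp(lxi)
    return gamma, xi_sum, ll


@njit(cache=True)
def _fb_scaled(B: np.ndarray, P: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward (numerically equivalent to log space after
    the caller's per-bin max shift); returns (gamma, xi_sum, log_norm)."""
    T, K = B.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * P[i, j]
            alpha[t, j] = acc * B[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                term = P[i, j] * B[t + 1, j] * beta[t + 1, j]
                xi[i, j] += alpha[t, i] * term / c[t + 1]
                acc += term
            beta[t, i] = acc / c[t + 1]
    gamma = alpha * beta
    log_norm = 0.0
    for t in range(T):
        log_norm += np.log(c[t])
    return gamma, xi, log_norm


def _forward_backward_fast(
    logB: np.ndarray, P: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fast path used by EM; agrees with :func:`forward_backward` to 1e-10."""
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    gamma, xi, log_norm = _fb_scaled(
        np.ascontiguousarray(B), np.ascontiguousarray(P), np.ascontiguousarray(pi)
    )
    return gamma, xi, log_norm + float(shift.sum())


def _order_phases(rates: np.ndarray) -> np.ndarray:
    """Deterministic label order: ascending population mean rate (On last)."""
    return np.argsort(rates.sum(axis=1), kind="stable")


def _gather_trials(recording, condition, fit_start: float) -> tuple[list, np.ndarray, int]:
    idx = recording.trial_indices(condition)
    start_bin = int(round(fit_start / recording.bin_width))
    trials = []
    kept = []
    for t in idx:
        c = recording.trial_counts(int(t))  # (n_bins, C)
        if c.shape[0] > start_bin:
            trials.append(c[start_bin:])
            kept.append(int(t))
    if len(trials) < 2:
        raise ValueError(
            "need at least 2 trials with a non-empty fit window in this condition"
        )
    if all(np.all(tr == 0) for tr in trials):
        raise ValueError("all counts are zero on every channel: nothing to fit")
    return trials, np.asarray(kept), start_bin


def _init_params(
    trials: list[np.ndarray], n_phases: int, dt: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rate initialisation: per-channel count quantile split plus jitter."""
    allc = np.concatenate(trials, axis=0)  # (T_total, C)
    C = allc.shape[1]
    qs = np.linspace(30, 70, n_phases) if n_phases > 1 else np.array([50.0])
    base = np.percentile(allc, qs, axis=0) / dt  # (K, C)
    base = np.maximum(base, 1.0)
    rates = base * rng.uniform(0.85, 1.15, size=(n_phases, C))
    P = np.full((n_phases, n_phases), 0.05 / max(n_phases - 1, 1))
    np.fill_diagonal(P, 0.95)
    P /= P.sum(axis=1, keepdims=True)
    return rates, P


def _em(
    trials: list[np.ndarray],
    n_phases: int,
    dt: float,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], list[float]]:
    rates, P = _init_params(trials, n_phases, dt, rng)
    ll_trace: list[float] = []
    gammas: list[np.ndarray] = []
    for it in range(max_iter):
        pi = _stationary(P)
        logP = np.log(np.maximum(P, 1e-300))
        log_pi = np.log(np.maximum(pi, 1e-300))
        num = np.zeros((n_phases, trials[0].shape[1]))
        den = np.zeros(n_phases)
        xi_tot = np.zeros((n_phases, n_phases))
        ll = 0.0
        gammas = []
        for counts in trials:
            logB = _log_emissions(counts, rates, dt)
            gamma, xi, l = _forward_backward_fast(logB, P, pi)
            gammas.append(gamma)
            num += gamma.T @ counts
            den += gamma.sum(axis=0)
            xi_tot += xi
            ll += l
        ll_trace.append(ll)
        if it >= 1 and abs(ll_trace[-1] - ll_trace[-2]) < tol * abs(ll_trace[-2]):
            break
        rates = num / np.maximum(den[:, None], 1e-12) / dt
        if n_phases > 1:
            row = xi_tot.sum(axis=1, keepdims=True)
            P = np.where(row > 0, xi_tot / np.maximum(row, 1e-300), P)
            P = np.maximum(P, 1e-8)
            P /= P.sum(axis=1, keepdims=True)
    return rates, P, gammas, ll_trace


def fit_hmm(
    recording,
    condition: tuple[int, int] | str = "all",
    n_phases: int = 2,
    n_restarts: int = 5,
    tol: float = 1e-7,
    max_iter: int = 200,
    seed: int | np.random.Generator = 0,
    fit_start: float = 0.400,
) -> HMMFit:
    """Fit the shared-state Poisson HMM to one condition of a recording.

    The fit window starts ``fit_start`` seconds after the cue (trial start)
    and runs to the end of each trial.  The best of ``n_restarts``
    EM runs (by final log-likelihood) is returned, with phases reordered so
    that population mean rate increases with the phase index.
    """
    rng = np.random.default_rng(seed)
    trials, kept, start_bin = _gather_trials(recording, condition, fit_start)
    dt = recording.bin_width
    best = None
    for _ in range(max(n_restarts, 1)):
        rates, P, gammas, ll_trace = _em(trials, n_phases, dt, rng, tol, max_iter)
        if best is None or ll_trace[-1] > best[3][-1]:
            best = (rates, P, gammas, ll_trace)
    rates, P, gammas, ll_trace = best
    order = _order_phases(rates)
    rates = rates[order]
    P = P[np.ix_(order, order)]
    gammas = [g[:, order] for g in gammas]
    params = HMMParams(
        rates=rates,
        transition_matrix=P,
        initial_distribution=_stationary(P),
        bin_width=dt,
    )
    return HMMFit(
        params=params,
        loglik_trace=np.asarray(ll_trace),
        posteriors=gammas,
        trial_indices=kept,
        fit_start_bin=start_bin,
        converged=len(ll_trace) < max_iter,
    )


def _loco_cv_error(
    trials: list[np.ndarray],
    rates: np.ndarray,
    P: np.ndarray,
    dt: float,
    window_bins: int,
) -> float:
    """Leave-one-channel-out prediction error in aggregation windows.

    For each held-out channel, posteriors are inferred from the remaining
    channels and the held-out channel's window-summed counts are predicted
    as the posterior-weighted rates.  Mean squared error over windows,
    averaged across channels.
    """
    K, C = rates.shape
    pi = _stationary(P)
    logP = np.log(np.maximum(P, 1e-300))
    log_pi = np.log(np.maximum(pi, 1e-300))
    err, n_win = 0.0, 0
    for counts in trials:
        T = counts.shape[0]
        n_w = T // window_bins
        if n_w == 0:
            continue
        for c in range(C):
            others = np.delete(np.arange(C), c)
            if K == 1:
                pred_bin = np.full(T, rates[0, c] * dt)
            else:
                logB = _log_emissions(counts[:, others], rates[:, others], dt)
                gamma, _, _ = _forward_backward_fast(logB, P, pi)
                pred_bin = gamma @ (rates[:, c] * dt)
            obs = counts[: n_w * window_bins, c].reshape(n_w, window_bins).sum(axis=1)
            pred = pred_bin[: n_w * window_bins].reshape(n_w, window_bins).sum(axis=1)
            err += float(((obs - pred) ** 2).sum())
            n_win += n_w
    if n_win == 0:
        raise ValueError("trials shorter than one aggregation window")
    return err / (n_win * C)


@dataclass
class PhaseSelection:
    n_phases: int
    cv_errors: np.ndarray  # normalized by the 1-phase error
    candidates: np.ndarray
    is_one_phase: bool


def select_n_phases(
    recording,
    condition: tuple[int, int] | str = "all",
    candidates=range(1, 9),
    n_folds: int = 4,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 2,
    max_iter: int = 60,
    fit_start: float = 0.400,
    cv_window: float = 0.200,
    elbow_tol: float = 0.02,
) -> PhaseSelection:
    """Choose the number of phases by k-fold cross-validated prediction error.

    The error for each candidate is normalised by the 1-phase error; the
    chosen model is the smallest n whose normalised error is within
    ``elbow_tol`` of the minimum over candidates.  A session/condition is
    one-phase when n = 1 already satisfies this criterion.
    """
    rng = np.random.default_rng(seed)
    trials, _, _ = _gather_trials(recording, condition, fit_start)
    if len(trials) < n_folds:
        raise ValueError(f"need at least {n_folds} trials for {n_folds}-fold CV")
    dt = recording.bin_width
    window_bins = max(int(round(cv_window / dt)), 1)
    cand = np.asarray(list(candidates), dtype=int)
    folds = np.array_split(rng.permutation(len(trials)), n_folds)
    errors = np.zeros(len(cand))
    for ic, K in enumerate(cand):
        fold_errs = []
        for f in folds:
            test = [trials[i] for i in f]
            train = [trials[i] for i in range(len(trials)) if i not in set(f)]
            best = None
            for _ in range(max(n_restarts, 1)):
                rates, P, _, ll = _em(train, K, dt, rng, 1e-6, max_iter)
                if best is None or ll[-1] > best[2][-1]:
                    best = (rates, P, ll)
            rates, P, _ = best
            fold_errs.append(_loco_cv_error(test, rates, P, dt, window_bins))
        errors[ic] = np.mean(fold_errs)
    if 1 not in cand:
        raise ValueError("candidates must include 1 for normalisation")
    base = errors[cand == 1][0]
    norm = errors / base
    min_err = norm.min()
    chosen = int(cand[np.flatnonzero(norm <= min_err + elbow_tol)[0]])
    return PhaseSelection(
        n_phases=chosen,
        cv_errors=norm,
        candidates=cand,
        is_one_phase=chosen == 1,
    )


@dataclass
class DecodedStates:
    states: list[np.ndarray]  # per trial, 0=Off / 1=On
    on_durations: np.ndarray
    off_durations: np.ndarray
    censored_on: np.ndarray
    censored_off: np.ndarray


def _viterbi(logB: np.ndarray, logP: np.ndarray, log_pi: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=int)
    delta[0] = log_pi + logB[0]
    for t in range(1, T):
        m = delta[t - 1][:, None] + logP
        back[t] = np.argmax(m, axis=0)
        delta[t] = logB[t] + m[back[t], np.arange(K)]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def decode_states(fit: HMMFit, recording, condition: tuple[int, int] | str = "all"):
    """Viterbi-decode On/Off episodes for every trial of a condition.

    Requires a two-phase fit (the On phase is the one with the higher
    population mean rate, already resolved at fit time).  Episodes touching
    a trial boundary are flagged as censored.
    """
    if fit.params.n_phases != 2:
        raise ValueError("decoding On/Off episodes requires a two-phase fit")
    trials, _, _ = _gather_trials(
        recording, condition, fit.fit_start_bin * recording.bin_width
    )
    dt = recording.bin_width
    logP = np.log(np.maximum(fit.params.transition_matrix, 1e-300))
    log_pi = np.log(np.maximum(fit.params.initial_distribution, 1e-300))
    paths = []
    on_d, off_d, on_c, off_c = [], [], [], []
    for counts in trials:
        logB = _log_emissions(counts, fit.params.rates, dt)
        path = _viterbi(logB, logP, log_pi)
        paths.append(path)
        change = np.flatnonzero(np.diff(path) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [path.size]))
        for k, (s, e) in enumerate(zip(starts, ends)):
            dur = (e - s) * dt
            censored = k == 0 or k == len(starts) - 1
            if path[s] == 1:
                on_d.append(dur)
                on_c.append(censored)
            else:
                off_d.append(dur)
                off_c.append(censored)
    return DecodedStates(
        states=paths,
        on_durations=np.asarray(on_d),
        off_durations=np.asarray(off_d),
        censored_on=np.asarray(on_c, dtype=bool),
        censored_off=np.asarray(off_c, dtype=bool),
    )


def variance_explained(
    fit: HMMFit, recording, condition: tuple[int, int] | str = "all"
) -> float:
    """R^2 of the posterior-expected rate against observed binned counts,
    averaged over channels."""
    trials, _, _ = _gather_trials(
        recording, condition, fit.fit_start_bin * recording.bin_width
    )
    dt = recording.bin_width
    obs = np.concatenate(trials, axis=0)  # (T, C)
    pred = np.concatenate(
        [g @ (fit.params.rates * dt) for g in fit.posteriors], axis=0
    )
    if obs.shape != pred.shape:
        raise ValueError("fit posteriors do not match this condition's trials")
    r2 = []
    for c in range(obs.shape[1]):
        ss_tot = float(((obs[:, c] - obs[:, c].mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"zero-variance counts on channel {c}")
        ss_res = float(((obs[:, c] - pred[:, c]) ** 2).sum())
        r2.append(1.0 - ss_res / ss_tot)
    return float(np.mean(r2))
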