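"""Closed-form predictions for On-Off driven count statistics.

For a population whose shared state S(t) follows a stationary two-state
Markov chain (Off->On rate alpha1, On->Off rate alpha2) and whose neurons
fire as doubly stochastic Poisson processes with rate
``r_off + Delta_r * S(t)``, the spike-count mean, variance, Fano factor and
pairwise noise correlations over a counting window T have exact closed
forms.  On a lattice of diffusively coupled On-Off units the equal-time
state correlation decays with lateral distance d as exp(-d/L) with
correlation length ``L = sqrt(beta1 / (alpha1 + alpha2))`` (in units of the
lattice constant), so the predicted noise correlation between neurons in
columns a distance d apart is the zero-distance amplitude times exp(-d/L).

All functions are pure; rates in Hz, times in seconds, distances in lattice
units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import MarkovRates

__all__ = [
    "CountMomentInputs",
    "CorrelationPrediction",
    "stationary_on_prob",
    "correlation_length",
    "pair_state_correlation",
    "on_time_variance",
    "count_mean",
    "count_variance",
    "noise_correlation_pred",
    "averaged_zero_distance_prediction",
    "fano_factor_pred",
]


@dataclass(frozen=True)
class CountMomentInputs:
    """Rates and counting window for one neuron's count moments."""

    rates: MarkovRates
    r_on: float
    r_off: float
    T: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("count window T must be positive")
        if self.r_off < 0 or self.r_on < self.r_off:
            raise ValueError(
                f"rates must satisfy r_on >= r_off >= 0, got r_on={self.r_on}, "
                f"r_off={self.r_off}"
            )

    @property
    def delta_r(self) -> float:
        return self.r_on - self.r_off


@dataclass(frozen=True)
class CorrelationPrediction:
    """Amplitude, correlation length and the r_sc(d) curve they imply."""

    amplitude: float
    correlation_length: float

    def curve(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, dtype=float)
        if self.correlation_length == 0:
            return np.where(d == 0, self.amplitude, 0.0)
        return self.amplitude * np.exp(-d / self.correlation_length)


def stationary_on_prob(rates: MarkovRates) -> float:
    """Stationary On probability S(inf) = alpha1 / (alpha1 + alpha2)."""
    return rates.stationary_on


def correlation_length(beta1: float, rates: MarkovRates) -> float:
    """Correlation length L = sqrt(beta1 / (alpha1 + alpha2)), lattice units."""
    if beta1 < 0:
        raise ValueError("beta1 must be >= 0")
    if rates.total == 0:
        raise ValueError("alpha1 + alpha2 must be positive")
    return float(np.sqrt(beta1 / rates.total))


def pair_state_correlation(d: float, rates: MarkovRates, beta1: float) -> float:
    """Steady-state pair moment G(d) = S^2 + S(1-S) exp(-d/L) for binary states.

    At d=0 this reduces to S (since S^2 = S for a binary variable) and for
    d -> inf to S^2 (independent units).
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    s = rates.stationary_on
    L = correlation_length(beta1, rates)
    if L == 0:
        decay = 1.0 if d == 0 else 0.0
    else:
        decay = float(np.exp(-d / L))
    return s * s + s * (1.0 - s) * decay


def on_time_variance(rates: MarkovRates, T: float) -> float:
    """Variance V(alpha1, alpha2) of the total On-time in a window T.

    V = 2 a1 a2 / (a1+a2)^3 * [T - (1 - exp(-(a1+a2) T)) / (a1+a2)].
    This is the kernel through which the On-Off switching inflates count
    variances and covariances.
    """
    if T <= 0:
        raise ValueError("count window T must be positive")
    k = rates.total
    if k == 0:
        raise ValueError("alpha1 + alpha2 must be positive")
    return float(
        2.0 * rates.alpha1 * rates.alpha2 / k**3 * (T - (-np.expm1(-k * T)) / k)
    )


def count_mean(inputs: CountMomentInputs) -> float:
    """Mean count (r_off + S(inf) * Delta_r) * T."""
    s = inputs.rates.stationary_on
    return (inputs.r_off + s * inputs.delta_r) * inputs.T


def count_variance(inputs: CountMomentInputs) -> float:
    """Count variance: Delta_r^2 V + r_off T + S(inf) T Delta_r.

    The first term is the On-Off switching contribution, the last two are
    the Poisson point-process variance at the mean rate.
    """
    v = on_time_variance(inputs.rates, inputs.T)
    s = inputs.rates.stationary_on
    return (
        inputs.delta_r**2 * v
        + inputs.r_off * inputs.T
        + s * inputs.T * inputs.delta_r
    )


def noise_correlation_pred(
    inputs_i: CountMomentInputs,
    inputs_j: CountMomentInputs,
    beta1: float = 0.0,
    d: float = 0.0,
) -> float:
    """Predicted noise correlation for a pair at lateral distance d.

    Both neurons must share the chain statistics (same alpha1, alpha2, T);
    pairs with different rates are rejected rather than silently averaged.
    At d=0 the value is the amplitude
    ``A = V * Delta_r_i * Delta_r_j / sqrt(Var_i * Var_j)``.
    """
    if inputs_i.rates != inputs_j.rates or inputs_i.T != inputs_j.T:
        raise ValueError("pair members must share (alpha1, alpha2) and T")
    if d < 0:
        raise ValueError("distance must be >= 0")
    var_i = count_variance(inputs_i)
    var_j = count_variance(inputs_j)
    if var_i == 0 or var_j == 0:
        raise ValueError("zero count variance: noise correlation undefined")
    v = on_time_variance(inputs_i.rates, inputs_i.T)
    amp = v * inputs_i.delta_r * inputs_j.delta_r / np.sqrt(var_i * var_j)
    if d == 0:
        return float(amp)
    L = correlation_length(beta1, inputs_i.rates)
    if L == 0:
        return 0.0
    return float(amp * np.exp(-d / L))


def averaged_zero_distance_prediction(
    rate_pairs: np.ndarray,
    rates: MarkovRates,
    T: float,
) -> float:
    """Mean zero-distance amplitude over sampled (r_on, r_off) rate pairs.

    ``rate_pairs`` has shape (n, 2, 2): n neuron pairs, each member a
    (r_on, r_off) tuple, as produced by ``sessions.sample_rate_pairs``
    reshaped into pairs; or shape (n, 2) for n neurons paired consecutively.
    Vectorised equivalent of ``noise_correlation_pred`` at d=0.
    """
    rp = np.asarray(rate_pairs, dtype=float)
    if rp.ndim == 2 and rp.shape[1] == 2:
        if rp.shape[0] % 2:
            raise ValueError("need an even number of neurons to form pairs")
        rp = rp.reshape(-1, 2, 2)
    if rp.ndim != 3 or rp.shape[1:] != (2, 2):
        raise ValueError("rate_pairs must have shape (n, 2, 2) or (2n, 2)")
    if rp.shape[0] < 1:
        raise ValueError("need at least one rate pair")
    r_on = rp[:, :, 0]
    r_off = rp[:, :, 1]
    dr = r_on - r_off
    v = on_time_variance(rates, T)
    s = rates.stationary_on
    var = dr**2 * v + r_off * T + s * T * dr
    if np.any(var <= 0):
        raise ValueError("zero count variance in a sampled pair")
    amp = v * dr[:, 0] * dr[:, 1] / np.sqrt(var[:, 0] * var[:, 1])
    return float(amp.mean())


def fano_factor_pred(inputs: CountMomentInputs) -> float:
    """Predicted Fano factor Var[N]/E[N]; >= 1, and growing with Delta_r.

    In the regime where the switching term dominates, FF - 1 is directly
    proportional to Delta_r at fixed transition rates and window.
    """
    mean = count_mean(inputs)
    if mean <= 0:
        raise ValueError("mean count must be positive for a Fano factor")
    return count_variance(inputs) / mean
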