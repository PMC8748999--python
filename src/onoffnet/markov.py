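"""Two-state (On/Off) Markov chain utilities.

The population state underlying On-Off dynamics is a continuous-time
two-state Markov process with Off->On rate ``alpha1`` and On->Off rate
``alpha2`` (both in 1/s).  Mean episode durations are ``tau_on = 1/alpha2``
and ``tau_off = 1/alpha1``.  These rates are the common currency linking the
HMM fits, the binary lattice network and the closed-form theory, so the
container and the exact chain samplers live in this small shared module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkovRates",
    "sample_state_bins",
    "sample_on_time",
    "episode_durations",
]


@dataclass(frozen=True)
class MarkovRates:
    """Off->On rate ``alpha1`` and On->Off rate ``alpha2``, in 1/s."""

    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError(
                f"transition rates must be >= 0, got alpha1={self.alpha1}, "
                f"alpha2={self.alpha2}"
            )

    @property
    def total(self) -> float:
        return self.alpha1 + self.alpha2

    @property
    def stationary_on(self) -> float:
        """Stationary probability of the On state, alpha1/(alpha1+alpha2)."""
        if self.total == 0:
            raise ValueError("alpha1 + alpha2 must be positive")
        return self.alpha1 / self.total


def _switch_probs(rates: MarkovRates, dt: float) -> tuple[float, float]:
    # Per-bin switch probabilities 1 - exp(-alpha * dt): exact for the
    # embedded chain observed on a grid, and never outside [0, 1].
    return float(-np.expm1(-rates.alpha1 * dt)), float(-np.expm1(-rates.alpha2 * dt))


def sample_state_bins(
    rates: MarkovRates,
    n_bins: int,
    dt: float,
    n_trials: int,
    rng: np.random.Generator,
    initial: str = "stationary",
) -> np.ndarray:
    """Sample the chain on a regular grid of ``n_bins`` bins of width ``dt``.

    Returns an int8 array of shape ``(n_trials, n_bins)`` with 1 = On.
    ``initial`` is ``"stationary"``, ``"on"`` or ``"off"``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_bins <= 0 or n_trials <= 0:
        raise ValueError("n_bins and n_trials must be positive")
    p_up, p_down = _switch_probs(rates, dt)
    out = np.empty((n_trials, n_bins), dtype=np.int8)
    if initial == "stationary":
        state = (rng.random(n_trials) < rates.stationary_on).astype(np.int8)
    elif initial == "on":
        state = np.ones(n_trials, dtype=np.int8)
    elif initial == "off":
        state = np.zeros(n_trials, dtype=np.int8)
    else:
        raise ValueError(f"unknown initial condition {initial!r}")
    for b in range(n_bins):
        out[:, b] = state
        u = rng.random(n_trials)
        flip_up = (state == 0) & (u < p_up)
        flip_down = (state == 1) & (u < p_down)
        state = np.where(flip_up, 1, np.where(flip_down, 0, state)).astype(np.int8)
    return out


def sample_on_time(
    rates: MarkovRates,
    window: float,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact total On-time in a window of length ``window`` seconds.

    Simulates the continuous-time chain (exponential dwell times, stationary
    initial state) and returns, per trial, the total time spent On.  Used as
    the doubly stochastic intensity integral for spike-count generation.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    a1, a2 = rates.alpha1, rates.alpha2
    state = (rng.random(n_trials) < rates.stationary_on).astype(np.int8)
    t = np.zeros(n_trials)
    on_time = np.zeros(n_trials)
    active = np.ones(n_trials, dtype=bool)
    while np.any(active):
        rate = np.where(state == 1, a2, a1).astype(float)
        dwell = np.full(n_trials, np.inf)
        pos = active & (rate > 0)
        dwell[pos] = rng.standard_exponential(int(pos.sum())) / rate[pos]
        remaining = window - t
        seg = np.minimum(dwell, remaining)
        seg[~active] = 0.0
        on_time += np.where(state == 1, seg, 0.0)
        t += seg
        flip = active & (dwell < remaining)  # dwell ended inside the window
        state[flip] = 1 - state[flip]
        active = flip
    return on_time


def episode_durations(states: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Run-length durations (seconds) of On and Off episodes, censored excluded.

    ``states`` is (n_trials, n_bins) or (n_bins,); episodes touching a trial
    boundary are dropped so the means estimate 1/alpha2 and 1/alpha1 without
    censoring bias on the interior episodes.
    """
    states = np.atleast_2d(np.asarray(states))
    on, off = [], []
    for row in states:
        if row.size == 0:
            continue
        change = np.flatnonzero(np.diff(row) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [row.size]))
        for k in range(1, len(starts) - 1):  # interior runs only
            dur = (ends[k] - starts[k]) * dt
            (on if row[starts[k]] else off).append(dur)
    return np.asarray(on), np.asarray(off)
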