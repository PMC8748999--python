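"""Single-column bistable rate-adaptation dynamics and doubly stochastic
spike generation.

Each column is a two-variable stochastic dynamical system in dimensionless
model time tau (converted to seconds by ``tau_a``, the adaptation
timescale):

    epsilon * dr/dtau = F(r) - a + W * Lap(r) + I_stim + I_att
    da/dtau           = g r - a + f + sqrt(2 Q) xi(tau)

with the piecewise-linear self-coupling F(r) approximating the inverted-N
rate nullcline.  For the canonical parameters the deterministic system has
two stable fixed points (On, high r; Off, low r) separated by a saddle on
the middle branch; the white noise in the adaptation variable drives
metastable transitions between them, producing exponentially distributed On
and Off episode durations.  The binary state is S(t) = Theta[r(t)] (r = 0
counts as Off).  An excitatory attentional current I_att > 0 shifts the
r-nullcline, stabilising On and destabilising Off.

Spikes are generated as inhomogeneous Poisson processes with rate
``r_off + delta_r * S(t)`` shared across all neurons of the column.

The printed form of the equations leaves the adaptation relaxation rate at
one per unit time; ``tau_a`` makes that unit explicit so that the isolated
column's transition rates land at the empirical ~10 per second.  The
canonical (epsilon, g, f, Q, tau_a) set was calibrated once with
``scripts/calibrate_column.py`` and is frozen here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .markov import MarkovRates, episode_durations

__all__ = [
    "ColumnParams",
    "ColumnTrace",
    "FixedPoint",
    "Nullclines",
    "CANONICAL",
    "F",
    "nullclines",
    "simulate_column",
    "generate_spikes",
    "estimate_effective_rates",
    "EffectiveRates",
]


@dataclass(frozen=True)
class ColumnParams:
    """Parameters of the column dynamical system.

    epsilon: timescale separation of r vs a (dimensionless, << 1)
    g, f:    adaptation gain and offset (a-nullcline a = g r + f)
    Q:       noise intensity driving the adaptation variable
    W:       lateral interaction strength (diffusive coupling)
    I_stim, I_att: external currents (stimulus, attention)
    tau_a:   seconds per unit of model time (adaptation timescale)
    dt:      output sampling step in seconds
    """

    epsilon: float = 0.2
    g: float = 0.5
    f: float = 0.0
    Q: float = 0.0070
    W: float = 0.02
    I_stim: float = 0.0
    I_att: float = 0.0
    tau_a: float = 0.0005
    dt: float = 0.005

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.Q < 0:
            raise ValueError("Q must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_a <= 0:
            raise ValueError("tau_a must be positive")

    @property
    def I_total(self) -> float:
        return self.I_stim + self.I_att


#: canonical bistable parameter set: symmetric On/Off wells at I = 0 with
#: isolated-unit transition rates alpha1 ~ alpha2 ~ 10 per second
CANONICAL = ColumnParams()


def F(r):
    """Piecewise-linear self-coupling: -1-r (r <= -1/2), r (|r| < 1/2),
    1-r (r >= 1/2)."""
    r = np.asarray(r, dtype=float)
    out = np.where(r <= -0.5, -1.0 - r, np.where(r < 0.5, r, 1.0 - r))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FixedPoint:
    r: float
    a: float
    branch: str
    stable: bool


@dataclass(frozen=True)
class Nullclines:
    fixed_points: tuple[FixedPoint, ...]
    I: float

    @property
    def stable(self) -> tuple[FixedPoint, ...]:
        return tuple(fp for fp in self.fixed_points if fp.stable)

    @property
    def bistable(self) -> bool:
        return len(self.stable) == 2

    def r_nullcline(self, r: np.ndarray) -> np.ndarray:
        return F(r) + self.I

    def a_nullcline(self, r, g: float, f: float) -> np.ndarray:
        return g * np.asarray(r, float) + f


def nullclines(
    params: ColumnParams,
    clamp_sum: float = 0.0,
    clamp_z: int = 0,
) -> Nullclines:
    """Branch-wise fixed points of the deterministic system and stability.

    The r-nullcline is a = F(r) + W*(clamp_sum - clamp_z * r) + I (the clamp
    terms describe a unit embedded among neighbors with a frozen summed rate
    ``clamp_sum``); the a-nullcline is a = g r + f.  An attentional current
    shifts the r-nullcline vertically, moving the knees relative to the
    a-nullcline and thereby the stability of the On and Off points.
    """
    g, f = params.g, params.f
    C = params.I_total + params.W * clamp_sum
    wz = params.W * clamp_z
    pts = []
    # upper branch: a = 1 - (1+wz) r + C, r >= 1/2
    r_up = (1.0 + C - f) / (1.0 + g + wz)
    if r_up >= 0.5:
        pts.append(FixedPoint(r_up, g * r_up + f, "on", True))
    # middle branch: a = (1-wz) r + C, |r| < 1/2  (saddle when slope > g)
    denom = 1.0 - wz - g
    if denom != 0:
        r_mid = (f - C) / denom
        if -0.5 < r_mid < 0.5:
            pts.append(FixedPoint(r_mid, g * r_mid + f, "middle", denom < 0))
    # lower branch: a = -1 - (1+wz) r + C, r <= -1/2
    r_lo = (C - 1.0 - f) / (1.0 + g + wz)
    if r_lo <= -0.5:
        pts.append(FixedPoint(r_lo, g * r_lo + f, "off", True))
    return Nullclines(fixed_points=tuple(pts), I=params.I_total)


@dataclass
class ColumnTrace:
    r: np.ndarray
    a: np.ndarray
    dt: float
    seed: int | None = None

    @property
    def S(self) -> np.ndarray:
        """Binary state Theta[r]; r = 0 counts as Off."""
        return (self.r > 0).astype(np.int8)

    @property
    def duration(self) -> float:
        return self.r.size * self.dt

    def episode_stats(self) -> tuple[float, float, MarkovRates]:
        """(mean_tau_on, mean_tau_off, estimated MarkovRates), censored
        episodes excluded from the means."""
        on, off = episode_durations(self.S, self.dt)
        if on.size == 0 or off.size == 0:
            raise ValueError("no complete episodes: lengthen the simulation")
        return float(on.mean()), float(off.mean()), MarkovRates(
            1.0 / off.mean(), 1.0 / on.mean()
        )


@njit(cache=True)
def _integrate(
    r0, a0, n_out, substeps, h, eps, g, f, q_step, drive, clamp_w, clamp_sum,
    clamp_z, fp_on, fp_off, binarize, noise_on_r, seed,
):
    np.random.seed(seed)
    r_out = np.empty(n_out)
    a_out = np.empty(n_out)
    r, a = r0, a0
    for i in range(n_out):
        for s in range(substeps):
            if r <= -0.5:
                fr = -1.0 - r
            elif r < 0.5:
                fr = r
            else:
                fr = 1.0 - r
            if binarize:
                own = fp_on if r > 0 else fp_off
            else:
                own = r
            lat = clamp_w * (clamp_sum - clamp_z * own)
            xi = q_step * np.random.normal()
            dr = h * (fr - a + lat + drive[i]) / eps
            da = h * (g * r - a + f)
            if noise_on_r:
                r += dr + xi
            else:
                r += dr
                a += da + xi
                continue
            a += da
        r_out[i] = r
        a_out[i] = a
    return r_out, a_out


def simulate_column(
    params: ColumnParams,
    duration: float,
    seed: int | np.random.Generator = 0,
    neighbor_input: float | np.ndarray = 0.0,
    clamp_sum: float | None = None,
    clamp_z: int = 0,
    clamp_binarized: bool = True,
    substeps: int | None = None,
    initial: str = "off",
    noise_target: str = "adaptation",
) -> ColumnTrace:
    """Euler-Maruyama integration of one column for ``duration`` seconds.

    ``neighbor_input`` is an external additive drive on the r-equation
    (scalar or per-output-sample array), used e.g. to feed a recorded
    neighbor Laplacian.  ``clamp_sum``/``clamp_z`` instead embed the unit
    among frozen neighbors: the coupling W*(clamp_sum - clamp_z*r) is then
    integrated self-consistently with the unit's own rate.

    The internal step is ``dt / substeps``; by default substeps is chosen so
    the model-time step is at most epsilon/4.  An explicitly requested
    coarser step than epsilon/2 (in model time) raises, as the stiff
    r-equation would be unstable.
    """
    rng = np.random.default_rng(seed)
    dt_m = params.dt / params.tau_a  # output step in model time
    if substeps is None:
        substeps = max(int(np.ceil(dt_m / (params.epsilon / 4.0))), 1)
    h = dt_m / substeps
    if h > params.epsilon / 2.0:
        raise ValueError(
            f"integration step {h:.4g} (model time) exceeds epsilon/2 = "
            f"{params.epsilon / 2:.4g}: increase substeps or reduce dt"
        )
    n_out = int(round(duration / params.dt))
    if n_out < 1:
        raise ValueError("duration shorter than one output step")
    drive = np.broadcast_to(
        np.asarray(neighbor_input, dtype=float), (n_out,)
    ).copy() if np.ndim(neighbor_input) else np.full(n_out, float(neighbor_input))
    drive += params.I_total
    nc = nullclines(params, clamp_sum or 0.0, clamp_z)
    stable = nc.stable
    if initial == "off":
        r0 = min(fp.r for fp in stable) if stable else -1.0
    elif initial == "on":
        r0 = max(fp.r for fp in stable) if stable else 1.0
    else:
        r0 = float(initial)
    a0 = params.g * r0 + params.f
    q_step = float(np.sqrt(2.0 * params.Q * h))
    cw = params.W if (clamp_sum is not None or clamp_z) else 0.0
    iso = nullclines(params)
    fp_on = max((fp.r for fp in iso.stable), default=1.0)
    fp_off = min((fp.r for fp in iso.stable), default=-1.0)
    if noise_target not in ("adaptation", "rate"):
        raise ValueError("noise_target must be 'adaptation' or 'rate'")
    kernel_seed = int(rng.integers(2**31))
    r, a = _integrate(
        r0, a0, n_out, substeps, h, params.epsilon, params.g, params.f,
        q_step, drive, cw, clamp_sum or 0.0, clamp_z, fp_on, fp_off,
        clamp_binarized, noise_target == "rate", kernel_seed,
    )
    return ColumnTrace(r=r, a=a, dt=params.dt)


def generate_spikes(
    S: np.ndarray,
    neuron_rates,
    T: float | None = None,
    seed: int | np.random.Generator = 0,
    dt: float = 0.010,
) -> np.ndarray:
    """Doubly stochastic Poisson counts given a shared binary state.

    ``S`` is (n_trials, n_bins) (or 1-D for a single trial) at bin width
    ``dt``; ``neuron_rates`` is a sequence of (r_on, r_off) pairs in Hz.
    Counts are accumulated over the first ``T`` seconds of each trial
    (default: the whole trial).  Returns (n_trials, n_neurons) counts; all
    neurons share the same state sequence, independent Poisson otherwise.
    """
    rng = np.random.default_rng(seed)
    S = np.atleast_2d(np.asarray(S))
    rates = np.asarray(neuron_rates, dtype=float).reshape(-1, 2)
    r_on, r_off = rates[:, 0], rates[:, 1]
    if np.any(r_off < 0) or np.any(r_on < 0):
        raise ValueError("firing rates must be >= 0")
    if np.any(r_on < r_off):
        raise ValueError("r_on must be >= r_off")
    n_bins = S.shape[1]
    if T is None:
        nT = n_bins
    else:
        nT = int(round(T / dt))
        if nT > n_bins:
            raise ValueError("count window T exceeds the state duration")
        if nT < 1:
            raise ValueError("count window T shorter than one bin")
    on_time = S[:, :nT].sum(axis=1) * dt  # (n_trials,)
    window = nT * dt
    lam = r_off[None, :] * window + (r_on - r_off)[None, :] * on_time[:, None]
    return rng.poisson(lam)


@dataclass
class EffectiveRates:
    """Clamped-neighbor estimates of the binary-unit reduction."""

    k_levels: np.ndarray
    alpha1_k: np.ndarray  # Off->On rate with k of 4 neighbors clamped On
    alpha2_k: np.ndarray
    baseline: MarkovRates  # zero-Laplacian rates (Off side k=0, On side k=4)
    beta1: float
    beta2: float
    beta1_se: float
    beta2_se: float

    @property
    def beta_eff(self) -> float:
        """Mean-field effective coupling (1-S) beta1 + S beta2 at the
        baseline stationary occupancy."""
        s = self.baseline.stationary_on
        return (1.0 - s) * self.beta1 + s * self.beta2


def estimate_effective_rates(
    params: ColumnParams,
    duration: float = 400.0,
    seed: int | np.random.Generator = 0,
    k_levels=(0, 1, 2, 3, 4),
    min_transitions: int = 50,
) -> EffectiveRates:
    """Estimate the binary-unit transition rates and coupling slopes.

    A single column is simulated with its four lattice neighbors clamped:
    k neighbors frozen at the On fixed point and 4-k at the Off fixed
    point.  Transition rates are estimated from episode counts; ``beta1``
    is the slope of the Off->On rate versus the Off-state Laplacian (= k)
    and ``beta2`` the (sign-flipped) slope of the On->Off rate versus the
    On-state Laplacian (= k - 4), matching the binary-unit rate forms
    alpha1 + beta1*Lap and alpha2 - beta2*Lap.
    """
    rng = np.random.default_rng(seed)
    nc = nullclines(params)
    if not nc.bistable:
        raise ValueError("parameters are not bistable: cannot clamp neighbors")
    r_on_fp = max(fp.r for fp in nc.stable)
    r_off_fp = min(fp.r for fp in nc.stable)
    k_levels = np.asarray(list(k_levels), dtype=int)
    a1_k = np.empty(len(k_levels))
    a2_k = np.empty(len(k_levels))
    # fine output sampling so that the short opposite-state episodes at
    # extreme clamp levels are not missed between samples
    fine = replace(params, dt=min(params.dt, 0.001))
    for i, k in enumerate(k_levels):
        csum = k * r_on_fp + (4 - k) * r_off_fp
        trace = simulate_column(
            fine, duration, rng, clamp_sum=csum, clamp_z=4,
            initial="off" if k <= 2 else "on",
        )
        S = trace.S
        flips = np.diff(S.astype(int))
        n_up = int(np.sum(flips == 1))
        n_down = int(np.sum(flips == -1))
        t_on = float(S.sum()) * trace.dt
        t_off = float((1 - S).sum()) * trace.dt
        if min(n_up, n_down) < min_transitions:
            raise ValueError(
                f"only {min(n_up, n_down)} transitions at clamp level k={k}; "
                "lengthen the simulation duration"
            )
        a1_k[i] = n_up / t_off
        a2_k[i] = n_down / t_on
    # Off-state Laplacian at clamp k is +k; On-state Laplacian is k-4.
    # The reduction is leading order in the Laplacian, and the measured rate
    # response is convex in k, so the slopes are fitted locally around zero
    # Laplacian (small k for the Off side, k near 4 for the On side).
    def _slope(x, y):
        slope, intercept = np.polyfit(x, y, 1)
        res = y - (slope * x + intercept)
        dof = max(len(x) - 2, 1)
        se = float(
            np.sqrt(res @ res / dof / ((x - x.mean()) @ (x - x.mean())))
        )
        return float(slope), se

    lo = k_levels <= 2
    hi = k_levels >= 2
    b1, b1_se = _slope(k_levels[lo].astype(float), a1_k[lo])
    mb2, b2_se = _slope((k_levels[hi] - 4).astype(float), a2_k[hi])
    base1 = float(a1_k[k_levels == 0][0]) if np.any(k_levels == 0) else max(
        float(a1_k[lo][0]), 0.0
    )
    base2 = float(a2_k[k_levels == 4][0]) if np.any(k_levels == 4) else max(
        float(a2_k[hi][-1]), 0.0
    )
    return EffectiveRates(
        k_levels=k_levels,
        alpha1_k=a1_k,
        alpha2_k=a2_k,
        baseline=MarkovRates(base1, base2),
        beta1=float(b1),
        beta2=float(-mb2),
        beta1_se=b1_se,
        beta2_se=b2_se,
    )
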