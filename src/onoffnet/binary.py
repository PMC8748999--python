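"""Reduced network of binary On/Off units with Glauber-type dynamics.

Each lattice unit carries a binary state S_i; the Off->On transition rate is
``alpha1 + beta1 * Lap_i`` and the On->Off rate is ``alpha2 - beta2 * Lap_i``
where ``Lap_i = sum_neighbors S - z S_i`` is the discrete Laplacian of the
binary field (z = number of neighbors).  Because Lap_i >= 0 whenever
S_i = 0 and Lap_i <= 0 whenever S_i = 1, both instantaneous rates are
non-negative for beta >= 0; a clip at zero is kept as a guard.  Detailed
balance does not hold in general, so this is not an equilibrium Ising
model even though the update rule looks Glauber-like.

The module provides a lattice simulator (synchronous per-bin updates, with a
random-sequential option), an exact master-equation solver for small systems
(the test oracle), and the first/second moment ODEs whose steady state gives
the exponential spatial correlation law.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

from .fields import StateField
from .markov import MarkovRates

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryNetParams",
    "MomentState",
    "discrete_laplacian",
    "neighbor_sum",
    "simulate_binary",
    "lattice_adjacency",
    "solve_master_equation",
    "integrate_moments",
    "moment_steady_state",
]


@dataclass(frozen=True)
class BinaryNetParams:
    """Baseline rates, coupling rates and lattice geometry.

    ``shape`` is (n,) for a 1-D ring or (h, w) for a 2-D periodic lattice.
    ``update_bin`` is the synchronous update step in seconds.
    """

    rates: MarkovRates
    beta1: float = 0.0
    beta2: float = 0.0
    shape: tuple[int, ...] = (64, 64)
    update_bin: float = 0.010

    def __post_init__(self) -> None:
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("beta1 and beta2 must be >= 0")
        if self.update_bin <= 0:
            raise ValueError("update_bin must be positive")
        if len(self.shape) not in (1, 2) or any(n < 2 for n in self.shape):
            raise ValueError("shape must be a 1-D or 2-D lattice with sides >= 2")

    @property
    def n_neighbors(self) -> int:
        return 2 * len(self.shape)


@dataclass
class MomentState:
    """First moment (scalar, translation-invariant) and pair-moment map.

    ``pair`` is indexed by lattice displacement on the periodic grid;
    ``pair[0, ...]`` (zero displacement) equals ``first`` for a binary field.
    """

    first: float
    pair: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.first <= 1.0:
            raise ValueError("first moment must be in [0, 1]")


def neighbor_sum(S: np.ndarray) -> np.ndarray:
    """Sum of the 2*ndim periodic nearest-neighbor states at every site."""
    out = np.zeros(S.shape, dtype=np.int64 if S.dtype.kind in "iub" else float)
    for ax in range(S.ndim):
        out += np.roll(S, 1, axis=ax)
        out += np.roll(S, -1, axis=ax)
    return out


def discrete_laplacian(S: np.ndarray, site: tuple[int, ...] | None = None):
    """Discrete Laplacian sum_nb S - z * S_site, per site or at one site."""
    S = np.asarray(S)
    lap = neighbor_sum(S) - 2 * S.ndim * S
    if site is None:
        return lap
    return int(lap[tuple(site)])


def simulate_binary(
    params: BinaryNetParams,
    duration: float,
    seed: int | np.random.Generator,
    initial: str = "stationary",
    scheme: str = "synchronous",
    record_stride: int = 1,
) -> StateField:
    """Simulate the binary-unit lattice for ``duration`` seconds.

    Per-bin flip probability is ``clip(w * update_bin, 0, 1)`` with w from
    the neighbor-dependent transition rates.  A warning is emitted when the
    baseline rates alone make ``w * update_bin > 0.5`` (coarse discretisation
    of the continuous-time process).  ``scheme`` is "synchronous" (all units
    per bin, mirroring the 10 ms binned update) or "asynchronous"
    (random-sequential single-site updates, N per bin) for checking that
    stationary statistics do not depend on the update scheme.
    """
    rng = np.random.default_rng(seed)
    a1, a2 = params.rates.alpha1, params.rates.alpha2
    b1, b2, dt = params.beta1, params.beta2, params.update_bin
    if max(a1, a2) * dt > 0.5:
        warnings.warn(
            "baseline rate * update_bin exceeds 0.5: the binned update is a "
            "coarse approximation of the continuous-time dynamics",
            stacklevel=2,
        )
    n_bins = int(round(duration / dt))
    if n_bins < 1:
        raise ValueError("duration shorter than one update bin")
    z = params.n_neighbors
    if initial == "stationary":
        S = (rng.random(params.shape) < params.rates.stationary_on).astype(np.int8)
    elif initial == "on":
        S = np.ones(params.shape, dtype=np.int8)
    elif initial == "off":
        S = np.zeros(params.shape, dtype=np.int8)
    else:
        raise ValueError(f"unknown initial condition {initial!r}")

    n_rec = (n_bins + record_stride - 1) // record_stride
    out = np.empty((n_rec, *params.shape), dtype=np.int8)
    clipped = 0
    if scheme == "synchronous":
        kernel_seed = int(rng.integers(2**31))
        if len(params.shape) == 2:
            out, clipped = _sim_sync_2d(
                S, n_bins, a1, a2, b1, b2, dt, record_stride, kernel_seed
            )
        else:
            out, clipped = _sim_sync_1d(
                S, n_bins, a1, a2, b1, b2, dt, record_stride, kernel_seed
            )
    elif scheme == "asynchronous":
        flat = S.reshape(-1)
        n_sites = flat.size
        idx_shape = params.shape
        for b in range(n_bins):
            if b % record_stride == 0:
                out[b // record_stride] = S
            sites = rng.integers(0, n_sites, n_sites)
            u = rng.random(n_sites)
            for s_lin, uu in zip(sites, u):
                site = np.unravel_index(s_lin, idx_shape)
                lap = discrete_laplacian(S, site)
                w = a1 + b1 * lap if S[site] == 0 else a2 - b2 * lap
                if w < 0:
                    clipped += 1
                    w = 0.0
                if uu < min(w * dt, 1.0):
                    S[site] = 1 - S[site]
    else:
        raise ValueError(f"unknown update scheme {scheme!r}")
    if clipped:
        logger.warning("clipped %d negative instantaneous rates to 0", clipped)
    return StateField(
        S=out[None, ...],
        dt=dt * record_stride,
        meta={"scheme": scheme, "clipped": clipped, "params": params},
    )


@njit(cache=True)
def _sim_sync_2d(S, n_bins, a1, a2, b1, b2, dt, stride, seed):
    np.random.seed(seed)
    H, W = S.shape
    n_rec = (n_bins + stride - 1) // stride
    out = np.empty((n_rec, H, W), dtype=np.int8)
    Sn = np.empty_like(S)
    clipped = 0
    for b in range(n_bins):
        if b % stride == 0:
            out[b // stride] = S
        u = np.random.random(H * W)
        for y in range(H):
            yu = H - 1 if y == 0 else y - 1
            yd = 0 if y == H - 1 else y + 1
            for x in range(W):
                xl = W - 1 if x == 0 else x - 1
                xr = 0 if x == W - 1 else x + 1
                lap = S[yu, x] + S[yd, x] + S[y, xl] + S[y, xr] - 4 * S[y, x]
                if S[y, x] == 0:
                    w = a1 + b1 * lap
                else:
                    w = a2 - b2 * lap
                if w < 0:
                    clipped += 1
                    w = 0.0
                p = w * dt
                if p > 1.0:
                    p = 1.0
                if u[y * W + x] < p:
                    Sn[y, x] = 1 - S[y, x]
                else:
                    Sn[y, x] = S[y, x]
        tmp = S
        S = Sn
        Sn = tmp
    return out, clipped


@njit(cache=True)
def _sim_sync_1d(S, n_bins, a1, a2, b1, b2, dt, stride, seed):
    np.random.seed(seed)
    N = S.shape[0]
    n_rec = (n_bins + stride - 1) // stride
    out = np.empty((n_rec, N), dtype=np.int8)
    Sn = np.empty_like(S)
    clipped = 0
    for b in range(n_bins):
        if b % stride == 0:
            out[b // stride] = S
        u = np.random.random(N)
        for x in range(N):
            xl = N - 1 if x == 0 else x - 1
            xr = 0 if x == N - 1 else x + 1
            lap = S[xl] + S[xr] - 2 * S[x]
            if S[x] == 0:
                w = a1 + b1 * lap
            else:
                w = a2 - b2 * lap
            if w < 0:
                clipped += 1
                w = 0.0
            p = w * dt
            if p > 1.0:
                p = 1.0
            if u[x] < p:
                Sn[x] = 1 - S[x]
            else:
                Sn[x] = S[x]
        tmp = S
        S = Sn
        Sn = tmp
    return out, clipped


def lattice_adjacency(shape: tuple[int, ...]) -> np.ndarray:
    """Neighbor multiplicity matrix of a periodic lattice with N = prod(shape).

    Entry (i, j) counts how many of i's 2*ndim neighbor slots point at j
    (on a side of length 2 the two directions coincide, giving weight 2 --
    exactly the topology the simulator's periodic roll implements).
    """
    n = int(np.prod(shape))
    A = np.zeros((n, n), dtype=int)
    for lin in range(n):
        idx = np.array(np.unravel_index(lin, shape))
        for ax in range(len(shape)):
            for step in (-1, 1):
                nb = idx.copy()
                nb[ax] = (nb[ax] + step) % shape[ax]
                A[lin, np.ravel_multi_index(tuple(nb), shape)] += 1
    return A


def _transition_rate(s, lap, a1, a2, b1, b2):
    w = a1 + b1 * lap if s == 0 else a2 - b2 * lap
    return max(w, 0.0)


def solve_master_equation(
    params: BinaryNetParams | None = None,
    adjacency: np.ndarray | None = None,
    rates: MarkovRates | None = None,
    beta1: float | None = None,
    beta2: float | None = None,
) -> np.ndarray:
    """Exact stationary distribution of the N-unit master equation.

    The generator over all 2^N configurations is built from the
    neighbor-dependent single-spin-flip rates; its transpose's null space is
    the stationary distribution.  ``adjacency`` is the neighbor multiplicity
    matrix (``lattice_adjacency(params.shape)`` when omitted).  Systems with
    several ergodic classes (e.g. an absorbing all-Off state when
    alpha1 = 0) raise with the classes reported.

    Only N <= 12 units are enumerable in reasonable time/memory.
    """
    if params is not None:
        rates = params.rates
        beta1 = params.beta1 if beta1 is None else beta1
        beta2 = params.beta2 if beta2 is None else beta2
        if adjacency is None:
            adjacency = lattice_adjacency(params.shape)
    if rates is None or adjacency is None:
        raise ValueError("provide params or (rates, adjacency)")
    beta1 = beta1 or 0.0
    beta2 = beta2 or 0.0
    A = np.asarray(adjacency)
    n = A.shape[0]
    if n > 12:
        raise ValueError("master equation solver limited to <= 12 units")
    z = A.sum(axis=1)
    a1, a2 = rates.alpha1, rates.alpha2
    n_states = 1 << n
    states = ((np.arange(n_states)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    rows, cols, vals = [], [], []
    lap_all = states @ A.T - z[None, :] * states  # (n_states, n)
    for i in range(n):
        s_i = states[:, i]
        w = np.where(s_i == 0, a1 + beta1 * lap_all[:, i], a2 - beta2 * lap_all[:, i])
        w = np.maximum(w, 0.0)
        target = np.arange(n_states) ^ (1 << i)
        rows.append(target)
        cols.append(np.arange(n_states))
        vals.append(w)
        rows.append(np.arange(n_states))
        cols.append(np.arange(n_states))
        vals.append(-w)
    G = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_states, n_states),
    ).tocsc()
    # stationary: G p = 0 with columns as source states (G[t, s] = rate s->t)
    w_eig, v_eig = np.linalg.eig(G.toarray())
    null_idx = np.flatnonzero(np.abs(w_eig) < 1e-9)
    if len(null_idx) == 0:
        raise RuntimeError("no stationary distribution found")
    if len(null_idx) > 1:
        classes = []
        for k in null_idx:
            vec = np.real(v_eig[:, k])
            classes.append(np.flatnonzero(np.abs(vec) > 1e-9).tolist())
        raise ValueError(
            f"generator has {len(null_idx)} ergodic classes with supports "
            f"{classes}; stationary distribution is not unique"
        )
    p = np.real(v_eig[:, null_idx[0]])
    p = np.abs(p)
    return p / p.sum()


def _pair_rhs(t, y, shape, a1, a2, b1):
    k = a1 + a2
    m = y[0]
    G = y[1:].reshape(shape)
    dm = a1 - k * m
    lapG = np.zeros_like(G)
    for ax in range(G.ndim):
        lapG += np.roll(G, 1, axis=ax) + np.roll(G, -1, axis=ax)
    lapG -= 2 * G.ndim * G
    dG = 2 * a1 * m - 2 * k * G + 2 * b1 * lapG
    # zero displacement is pinned to the first moment (S^2 = S)
    dG.reshape(-1)[0] = dm
    return np.concatenate(([dm], dG.reshape(-1)))


def integrate_moments(
    params: BinaryNetParams,
    initial: MomentState | None = None,
    duration: float = 2.0,
    n_report: int = 50,
):
    """Integrate the first- and pair-moment ODEs on the periodic lattice.

    The pair equation is the translation-invariant closure of the master
    equation's second-moment dynamics (exact when beta1 == beta2); the zero
    displacement entry is pinned to the first moment since S^2 = S for a
    binary variable.  Returns (times, trajectory) where trajectory is a list
    of MomentState.
    """
    from scipy.integrate import solve_ivp

    shape = params.shape
    if initial is None:
        m0 = params.rates.stationary_on
        G0 = np.full(shape, m0 * m0)
        G0.reshape(-1)[0] = m0
        initial = MomentState(first=m0, pair=G0)
    y0 = np.concatenate(([initial.first], np.asarray(initial.pair, float).reshape(-1)))
    t_eval = np.linspace(0.0, duration, n_report)
    sol = solve_ivp(
        _pair_rhs,
        (0.0, duration),
        y0,
        t_eval=t_eval,
        args=(shape, params.rates.alpha1, params.rates.alpha2, params.beta1),
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
    )
    traj = [
        MomentState(first=float(sol.y[0, i]), pair=sol.y[1:, i].reshape(shape))
        for i in range(sol.y.shape[1])
    ]
    return sol.t, traj


def moment_steady_state(params: BinaryNetParams) -> MomentState:
    """Exact steady state of the moment equations by sparse linear solve.

    For displacement e != 0:  k G(e) - beta1 * Lap_e G(e) = alpha1 * m,
    with G(0) = m = alpha1/(alpha1+alpha2).  The resulting covariance
    G(d) - m^2 decays (approximately) exponentially with |e| with decay
    constant L = sqrt(beta1 / (alpha1 + alpha2)).
    """
    shape = params.shape
    n = int(np.prod(shape))
    k = params.rates.total
    m = params.rates.stationary_on
    b1 = params.beta1
    z = 2 * len(shape)
    diag = np.full(n, k + b1 * z)
    A = sp.lil_matrix((n, n))
    A.setdiag(diag)
    for lin in range(n):
        idx = np.array(np.unravel_index(lin, shape))
        for ax in range(len(shape)):
            for step in (-1, 1):
                nb = idx.copy()
                nb[ax] = (nb[ax] + step) % shape[ax]
                A[lin, np.ravel_multi_index(tuple(nb), shape)] -= b1
    b = np.full(n, params.rates.alpha1 * m)
    # pin G(0) = m
    A[0, :] = 0.0
    A[0, 0] = 1.0
    b[0] = m
    G = spla.spsolve(A.tocsr(), b).reshape(shape)
    return MomentState(first=m, pair=G)
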