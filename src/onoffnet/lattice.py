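"""Two-dimensional lattice network of coupled bistable columns.

Every lattice site integrates the column rate-adaptation dynamics with a
diffusive nearest-neighbor coupling W * Lap(r); bottom-up stimulus currents
target rectangular patches of sites and a top-down attentional current
targets one of those patches during the cue period.  The binary occupancy
S = Theta[r] forms propagating On/Off clusters whose spatial extent sets
the lateral decay of noise correlations.

A trial follows the task protocol: spontaneous period (no external input),
stimulus period (I_stim on the stimulus patches), then the attention-cue
period (I_stim still on, plus I_att on the attended patch).  Analyses use
the cue-period samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .column import ColumnParams
from .fields import StateField, open_region_covariance, radial_covariance
from .markov import MarkovRates, episode_durations
from .stats import CorrelationLengthFit, fit_correlation_length

__all__ = [
    "Patch",
    "TrialProtocol",
    "LatticeConfig",
    "simulate_lattice",
    "field_noise_correlations",
    "attention_contrast",
    "AttentionContrast",
    "save_snapshot",
]


@dataclass(frozen=True)
class Patch:
    """Rectangular site set [y0, y1) x [x0, x1)."""

    y0: int
    y1: int
    x0: int
    x1: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y1 - self.y0, self.x1 - self.x0)

    def inside(self, shape: tuple[int, int]) -> bool:
        return (
            0 <= self.y0 < self.y1 <= shape[0]
            and 0 <= self.x0 < self.x1 <= shape[1]
        )


@dataclass(frozen=True)
class TrialProtocol:
    """Durations (s) of the spontaneous, stimulus and attention-cue periods."""

    spontaneous: float = 0.2
    stimulus: float = 0.2
    cue: float = 1.0

    @property
    def total(self) -> float:
        return self.spontaneous + self.stimulus + self.cue


def _default_patches(size: int) -> tuple[Patch, Patch]:
    # two laterally separated square patches (50x50 at the full 256 scale)
    m = min(max(int(round(size * 50 / 256)), 6), size // 2)
    y0 = max(size // 2 - m // 2, 0)
    x1 = max(size // 4 - m // 2, 0)
    x2 = min(3 * size // 4 - m // 2, size - m)
    return (
        Patch(y0, y0 + m, x1, x1 + m),
        Patch(y0, y0 + m, x2, x2 + m),
    )


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice geometry, column parameters, input patches and protocol.

    ``size`` defaults to the full 256-lattice scale; tests and desk use
    use 32-64.  ``attention_patch`` indexes into ``stimulus_patches``.
    """

    size: int = 256
    column_params: ColumnParams = field(default_factory=ColumnParams)
    stimulus_patches: tuple[Patch, ...] = ()
    attention_patch: int = 0
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    n_trials: int = 100
    boundary: str = "periodic"
    I_stim: float = 0.0
    I_att: float = 0.005
    seed: int = 0
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError("boundary must be 'periodic' or 'reflecting'")
        patches = self.stimulus_patches or _default_patches(self.size)
        for p in patches:
            if not p.inside((self.size, self.size)):
                raise ValueError(f"patch {p} lies outside the {self.size}^2 lattice")
        if not 0 <= self.attention_patch < len(patches):
            raise ValueError("attention_patch must index a stimulus patch")

    @property
    def patches(self) -> tuple[Patch, ...]:
        return self.stimulus_patches or _default_patches(self.size)


@njit(cache=True, fastmath=True)
def _integrate_lattice(
    r, a, n_out, substeps, h, eps, g, f, q_step, W, I_ext, phase_idx,
    periodic, stride, seed,
):
    np.random.seed(seed)
    H, Wd = r.shape
    n_rec = (n_out + stride - 1) // stride
    S_out = np.empty((n_rec, H, Wd), dtype=np.int8)
    rn = np.empty((H, Wd))
    for i in range(n_out):
        I_cur = I_ext[phase_idx[i]]
        for s in range(substeps):
            noise = np.random.standard_normal(H * Wd)
            for y in range(H):
                if periodic:
                    yu = H - 1 if y == 0 else y - 1
                    yd = 0 if y == H - 1 else y + 1
                else:
                    yu = y if y == 0 else y - 1
                    yd = y if y == H - 1 else y + 1
                for x in range(Wd):
                    if periodic:
                        xl = Wd - 1 if x == 0 else x - 1
                        xr = 0 if x == Wd - 1 else x + 1
                    else:
                        xl = x if x == 0 else x - 1
                        xr = x if x == Wd - 1 else x + 1
                    rv = r[y, x]
                    lap = r[yu, x] + r[yd, x] + r[y, xl] + r[y, xr] - 4.0 * rv
                    if rv <= -0.5:
                        fr = -1.0 - rv
                    elif rv < 0.5:
                        fr = rv
                    else:
                        fr = 1.0 - rv
                    drift = (fr - a[y, x] + W * lap + I_cur[y, x]) / eps
                    rn[y, x] = rv + h * drift
                    a[y, x] += h * (g * rv - a[y, x] + f) + q_step * noise[
                        y * Wd + x
                    ]
            tmp = r
            r = rn
            rn = tmp
        if i % stride == 0:
            for y in range(H):
                for x in range(Wd):
                    S_out[i // stride, y, x] = 1 if r[y, x] > 0 else 0
    return S_out, r, a


def simulate_lattice(config: LatticeConfig) -> StateField:
    """Simulate ``n_trials`` trials of the lattice network.

    Each trial re-randomises the initial unit activities (uniform over the
    bistable range) and runs the three-period protocol.  Returns the binary
    occupancy at the output sampling ``column_params.dt * record_stride``
    with per-period sample indices in ``meta``.
    """
    cp = config.column_params
    rng = np.random.default_rng(config.seed)
    n = config.size
    dt_m = cp.dt / cp.tau_a
    # lattice integration runs at the epsilon/2 step (half the single-column
    # accuracy step): within-run contrasts are insensitive to the residual
    # discretisation bias and the cost halves
    substeps = max(int(np.ceil(dt_m / (cp.epsilon / 2.0))), 1)
    h = dt_m / substeps
    q_step = float(np.sqrt(2.0 * cp.Q * h))
    prot = config.protocol
    n_sp = int(round(prot.spontaneous / cp.dt))
    n_st = int(round(prot.stimulus / cp.dt))
    n_cue = int(round(prot.cue / cp.dt))
    n_out = n_sp + n_st + n_cue
    if n_out < 1:
        raise ValueError("protocol has zero total duration")
    phase_idx = np.concatenate(
        [
            np.zeros(n_sp, dtype=np.int64),
            np.ones(n_st, dtype=np.int64),
            np.full(n_cue, 2, dtype=np.int64),
        ]
    )
    I_ext = np.zeros((3, n, n))
    for p in config.patches:
        sl = p.slices()
        I_ext[1][sl] += config.I_stim
        I_ext[2][sl] += config.I_stim
    att = config.patches[config.attention_patch]
    I_ext[2][att.slices()] += config.I_att
    I_ext += cp.I_stim + cp.I_att  # any globally applied currents

    trials = []
    for _ in range(config.n_trials):
        r0 = rng.uniform(-1.0, 1.0, size=(n, n))
        a0 = cp.g * r0 + cp.f
        S, _, _ = _integrate_lattice(
            r0,
            a0,
            n_out,
            substeps,
            h,
            cp.epsilon,
            cp.g,
            cp.f,
            q_step,
            cp.W,
            I_ext,
            phase_idx,
            config.boundary == "periodic",
            config.record_stride,
            int(rng.integers(2**31)),
        )
        trials.append(S)
    stride = config.record_stride
    meta = {
        "config": config,
        "cue_start": (n_sp + n_st) // stride,
        "n_spontaneous": n_sp // stride,
        "n_stimulus": n_st // stride,
    }
    return StateField(S=np.stack(trials), dt=cp.dt * stride, meta=meta)


def field_noise_correlations(
    field: StateField,
    neuron_rates,
    T: float = 0.2,
    region: Patch | None = None,
    max_distance: float | None = None,
    seed: int | np.random.Generator = 0,
    offset: int | None = None,
    neurons_per_site: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Empirical noise correlation versus lattice distance.

    One doubly stochastic Poisson pseudo-neuron is attached to every site of
    ``region`` (rates drawn from ``neuron_rates``: an (n, 2) array of
    (r_on, r_off) rows, cycled as needed, or a callable(n, rng)).  Counts
    are taken over the first ``T`` seconds of the cue period of each trial;
    the Pearson correlation of every site pair is binned by Euclidean
    distance.  Returns (distances, mean r_sc, pair distances, pair r_sc).
    """
    if field.n_trials < 2:
        raise ValueError("need >= 2 trials to measure noise correlations")
    rng = np.random.default_rng(seed)
    S = field.S
    start = offset if offset is not None else field.meta.get("cue_start", 0)
    nT = int(round(T / field.dt))
    if start + nT > field.n_bins:
        raise ValueError("count window T exceeds the available cue period")
    if region is None:
        region = Patch(0, S.shape[2], 0, S.shape[3])
    sl = region.slices()
    sub = S[:, start : start + nT, sl[0], sl[1]]  # (trials, nT, h, w)
    h, w = sub.shape[2:]
    site_on = sub.sum(axis=1).reshape(field.n_trials, h * w) * field.dt
    n_sites = h * w
    nps = max(int(neurons_per_site), 1)
    n_neur = n_sites * nps
    on_time = np.repeat(site_on, nps, axis=1)  # same state path per site
    if callable(neuron_rates):
        rates = np.asarray(neuron_rates(n_neur, rng), float)
    else:
        rates = np.asarray(neuron_rates, float).reshape(-1, 2)
        reps = int(np.ceil(n_neur / rates.shape[0]))
        rates = np.tile(rates, (reps, 1))[:n_neur]
    r_on, r_off = rates[:, 0], rates[:, 1]
    lam = r_off[None, :] * (nT * field.dt) + (r_on - r_off)[None, :] * on_time
    counts = rng.poisson(lam)  # (trials, neurons)
    c = counts - counts.mean(axis=0, keepdims=True)
    sd = counts.std(axis=0)
    ok = sd > 0
    site_of = np.arange(n_neur) // nps
    yy, xx = np.divmod(site_of, w)
    if max_distance is None:
        max_distance = min(h, w) / 2.0
    pd_list, pr_list = [], []
    corr = np.corrcoef(counts.T) if n_neur <= 4000 else None
    for i in range(n_neur):
        if not ok[i]:
            continue
        for j in range(i + 1, n_neur):
            if not ok[j]:
                continue
            d = float(np.hypot(yy[i] - yy[j], xx[i] - xx[j]))
            if d > max_distance:
                continue
            if corr is not None:
                r = corr[i, j]
            else:
                r = float(c[:, i] @ c[:, j] / (len(c) * sd[i] * sd[j]))
            pd_list.append(d)
            pr_list.append(r)
    pair_d = np.asarray(pd_list)
    pair_r = np.asarray(pr_list)
    keys = np.round(pair_d).astype(int)
    ds, ms = [], []
    for k in np.unique(keys):
        sel = keys == k
        ds.append(pair_d[sel].mean())
        ms.append(pair_r[sel].mean())
    return np.asarray(ds), np.asarray(ms), pair_d, pair_r


@dataclass
class AttentionContrast:
    tau_on: dict[str, float]
    tau_off: dict[str, float]
    L: dict[str, CorrelationLengthFit]
    covariance_curves: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def L_att(self) -> float:
        return self.L["attention"].length

    @property
    def L_ctl(self) -> float:
        return self.L["control"].length


def attention_contrast(
    field: StateField,
    attention_patch: Patch | None = None,
    control_patch: Patch | None = None,
    burn_in: float = 0.2,
) -> AttentionContrast:
    """Episode statistics and correlation lengths of the attended versus
    control patches of one simulated run.

    Both patches must come from the same run (same ``field``).  The state
    covariance within each patch is averaged over displacements (open
    boundaries, no wrap) and fit with an exponential decay.
    """
    cfg = field.meta.get("config")
    if attention_patch is None or control_patch is None:
        if cfg is None:
            raise ValueError("patches not given and field carries no config")
        patches = cfg.patches
        attention_patch = patches[cfg.attention_patch]
        control_patch = patches[1 - cfg.attention_patch]
    start = field.meta.get("cue_start", 0) + int(round(burn_in / field.dt))
    out: dict[str, dict] = {}
    result = AttentionContrast({}, {}, {}, {})
    for name, patch in (("attention", attention_patch), ("control", control_patch)):
        sl = patch.slices()
        sub = field.S[:, start:, sl[0], sl[1]]
        if sub.shape[1] < 2:
            raise ValueError("cue period too short after burn-in")
        n_tr, n_bins, h, w = sub.shape
        site_series = sub.transpose(0, 2, 3, 1).reshape(n_tr * h * w, n_bins)
        on_d, off_d = episode_durations(site_series, field.dt)
        if on_d.size == 0 or off_d.size == 0:
            raise ValueError(f"no complete episodes in the {name} patch")
        result.tau_on[name] = float(on_d.mean())
        result.tau_off[name] = float(off_d.mean())
        frames = sub.reshape(n_tr * n_bins, h, w)
        cov = open_region_covariance(frames)
        # fixed fit window up to half the patch size: the short-range bias of
        # an exponential fit on a 2-D field is common to both patches, so a
        # shared window gives the cleanest attended-vs-control contrast
        d, c = radial_covariance(cov, max_distance=min(h, w) / 2.0, periodic=False)
        n_pair_bins = int((c > 0).sum())
        if n_pair_bins < 4:
            raise ValueError(f"too few usable distance bins in the {name} patch")
        result.covariance_curves[name] = (d, c)
        result.L[name] = fit_correlation_length(d, c, adaptive_window=False)
    return result


def save_snapshot(
    field: StateField, path: str, trial: int = 0, time_bin: int = -1
) -> None:
    """Write one binary On/Off frame as a PNG image (On = bright)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = field.S[trial, time_bin]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(frame, cmap="cividis", interpolation="nearest", vmin=0, vmax=1)
    ax.set_xticks([])
    ax.set_yticks([])
    t = (time_bin if time_bin >= 0 else field.n_bins + time_bin) * field.dt
    ax.set_title(f"On/Off occupancy at t = {t:.2f} s")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
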