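"""Synthetic laminar-recording sessions with known On-Off ground truth.

A session emulates a 16-channel linear-array recording from one cortical
column during a cued attention task: spike counts in 10 ms bins on every
channel, 4 attention x 8 orientation task conditions, per-trial analysis
windows of variable duration, channel layer labels, and receptive-field
(RF) centers that drift laterally across channels.  In a two-phase session
every trial carries one shared two-state Markov population state S(t) and
channel c fires Poisson with rate ``r_off[c] + delta_r[c] * S(t)``; in a
one-phase session delta_r = 0 on all channels, so there is no detectable
switching (each channel fires at its condition-independent mean rate).

The generator's returns carry the full ground truth (state sequences, true
rates), so every downstream stage -- HMM fitting, model selection, count
statistics, distance regressions -- is testable without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .markov import MarkovRates, sample_state_bins

__all__ = [
    "RateDistribution",
    "RFGrid",
    "SessionConfig",
    "SessionRecording",
    "sample_rate_pairs",
    "generate_rf_map",
    "rf_center_of_mass",
    "generate_session",
    "save_session",
    "load_session",
]


@dataclass(frozen=True)
class RateDistribution:
    """Lognormal sampler for per-channel (r_on, r_off) firing-rate pairs.

    r_off ~ Lognormal(ln median_off, sigma_off) and the On-Off difference
    delta_r ~ Lognormal(ln median_delta, sigma_delta), independently, so
    r_on = r_off + delta_r >= r_off by construction.  Defaults give a median
    multi-unit rate near 100 Hz with a broad delta_r spread, emulating the
    heterogeneous On/Off rate histograms of columnar multi-unit recordings.
    """

    median_off: float = 60.0
    sigma_off: float = 0.5
    median_delta: float = 80.0
    sigma_delta: float = 0.6

    def __post_init__(self) -> None:
        for name in ("median_off", "median_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma_off", "sigma_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def mean_delta(self) -> float:
        """Closed-form lognormal mean of delta_r."""
        return self.median_delta * float(np.exp(self.sigma_delta**2 / 2))

    @property
    def mean_off(self) -> float:
        return self.median_off * float(np.exp(self.sigma_off**2 / 2))


def sample_rate_pairs(
    n: int,
    rate_distribution: RateDistribution | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` (r_on, r_off) pairs; returns array of shape (n, 2).

    Every draw satisfies r_on >= r_off >= 0 because r_on is constructed as
    r_off + delta_r with delta_r >= 0.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    dist = rate_distribution or RateDistribution()
    rng = np.random.default_rng(seed)
    r_off = dist.median_off * np.exp(dist.sigma_off * rng.standard_normal(n))
    delta = dist.median_delta * np.exp(dist.sigma_delta * rng.standard_normal(n))
    return np.column_stack([r_off + delta, r_off])


@dataclass(frozen=True)
class RFGrid:
    """Geometry of the 6x6 RF-mapping stimulus grid, in degrees of visual
    angle (dva).  The grid covers a patch of the lower-left visual field."""

    x0: float = -8.5
    y0: float = -8.5
    spacing: float = 1.7
    n: int = 6

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + self.spacing * np.arange(self.n)

    @property
    def ys(self) -> np.ndarray:
        return self.y0 + self.spacing * np.arange(self.n)


def rf_center_of_mass(response_map: np.ndarray, grid: RFGrid) -> tuple[float, float]:
    """Center of mass of a response map on the stimulus grid, in dva."""
    m = np.asarray(response_map, dtype=float)
    if m.shape != (grid.n, grid.n):
        raise ValueError(f"response map must be {grid.n}x{grid.n}")
    total = m.sum()
    if total <= 0:
        raise ValueError("all-zero response map: center of mass undefined")
    x = float((m.sum(axis=1) * grid.xs).sum() / total)
    y = float((m.sum(axis=0) * grid.ys).sum() / total)
    return x, y


def generate_rf_map(
    channel_index: int,
    rf_shift: float,
    grid: RFGrid | None = None,
    seed: int | np.random.Generator = 0,
    rf_width: float = 1.0,
    noise: float = 0.0,
) -> tuple[float, float]:
    """RF center of a synthetic channel, as the center of mass of a 6x6
    response map whose Gaussian peak drifts along x by ``rf_shift`` dva per
    channel step (emulating a slightly oblique penetration)."""
    grid = grid or RFGrid()
    rng = np.random.default_rng(seed)
    base_x = grid.x0 + grid.spacing * (grid.n - 1) / 2.0 - rf_shift * 7.5
    base_y = grid.y0 + grid.spacing * (grid.n - 1) / 2.0
    cx = base_x + rf_shift * channel_index
    cy = base_y
    xx, yy = np.meshgrid(grid.xs, grid.ys, indexing="ij")
    resp = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * rf_width**2))
    if noise > 0:
        resp = np.maximum(resp + noise * rng.standard_normal(resp.shape), 0.0)
    return rf_center_of_mass(resp, grid)


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to generate one synthetic session.

    Trial time axis: each trial starts at the attention-cue onset; the first
    ``pre_window`` seconds precede the analysis window used for HMM fitting,
    and the analysis window itself has a duration drawn uniformly from
    ``trial_window_range`` (so total trial duration is pre_window + window).
    The first attention condition (index 0) is the attend-in condition and
    uses ``rates_attention``; the others use ``rates_control``.
    """

    n_channels: int = 16
    bin_width: float = 0.010
    n_trials_per_condition: int = 20
    n_attention: int = 4
    n_orientations: int = 8
    trial_window_range: tuple[float, float] = (0.200, 1.900)
    pre_window: float = 0.400
    session_type: str = "two_phase"
    rates_control: MarkovRates = field(default_factory=lambda: MarkovRates(10.2, 9.8))
    rates_attention: MarkovRates = field(default_factory=lambda: MarkovRates(11.4, 8.8))
    rate_distribution: RateDistribution = field(default_factory=RateDistribution)
    attention_rate_gain_sigma: float = 0.0
    rf_shift: float = 0.3
    rf_grid: RFGrid = field(default_factory=RFGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_channels <= 0:
            raise ValueError("n_channels must be positive")
        if self.n_trials_per_condition <= 0:
            raise ValueError("n_trials_per_condition must be positive")
        lo, hi = self.trial_window_range
        if not (0 < lo <= hi):
            raise ValueError("trial_window_range must satisfy 0 < min <= max")
        if self.session_type not in ("two_phase", "one_phase"):
            raise ValueError("session_type must be 'two_phase' or 'one_phase'")
        for nm in ("rates_control", "rates_attention"):
            r = getattr(self, nm)
            if r.total <= 0:
                raise ValueError(f"{nm}: alpha1 + alpha2 must be positive")

    @property
    def conditions(self) -> list[tuple[int, int]]:
        return [
            (a, o)
            for a in range(self.n_attention)
            for o in range(self.n_orientations)
        ]

    def rates_for(self, attention: int) -> MarkovRates:
        return self.rates_attention if attention == 0 else self.rates_control


@dataclass
class SessionRecording:
    """Spike counts and metadata for one synthetic (or loaded) session.

    ``counts`` is (n_trials, n_channels, max_bins), zero-padded beyond each
    trial's ``n_bins`` (see ``trial_meta.n_bins``).  ``trial_meta`` carries
    per-trial attention / orientation labels and window durations;
    ``channel_meta`` carries layer labels and RF centers.  ``ground_truth``
    (optional) holds the state sequences and true parameters.
    """

    counts: np.ndarray
    bin_width: float
    trial_meta: pd.DataFrame
    channel_meta: pd.DataFrame
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be (n_trials, n_channels, max_bins)")
        if c.min() < 0 or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]

    def trial_indices(self, condition: tuple[int, int] | str = "all") -> np.ndarray:
        """Indices of trials in one (attention, orientation) condition."""
        if condition == "all":
            return np.arange(self.n_trials)
        a, o = condition
        sel = (self.trial_meta.attention == a) & (self.trial_meta.orientation == o)
        return np.flatnonzero(sel.to_numpy())

    def trial_counts(self, t: int) -> np.ndarray:
        """Unpadded (n_bins, n_channels) counts of trial t."""
        nb = int(self.trial_meta.n_bins.iloc[t])
        return self.counts[t, :, :nb].T


def generate_session(config: SessionConfig) -> SessionRecording:
    """Generate one synthetic session (deterministic under config.seed)."""
    rng = np.random.default_rng(config.seed)
    dt = config.bin_width
    pre_bins = int(round(config.pre_window / dt))
    pairs = sample_rate_pairs(config.n_channels, config.rate_distribution, rng)
    r_on, r_off = pairs[:, 0], pairs[:, 1]
    if config.session_type == "one_phase":
        # flat sessions: every channel fires at its state-averaged mean rate
        s_bar = config.rates_control.stationary_on
        mean_rate = r_off + s_bar * (r_on - r_off)
        r_on = r_off = mean_rate
    delta_r = r_on - r_off
    # attention can modulate each channel's On-Off rate difference by a
    # heterogeneous lognormal gain (off by default)
    if config.attention_rate_gain_sigma > 0:
        sig = config.attention_rate_gain_sigma
        # mean-one lognormal gains: heterogeneous modulation that leaves the
        # population-average On-Off rate difference unchanged
        gains = np.exp(sig * rng.standard_normal(config.n_channels) - sig**2 / 2)
    else:
        gains = np.ones(config.n_channels)
    delta_att = delta_r * gains
    r_on_att = r_off + delta_att

    rows = []
    counts_list = []
    states_list = []
    for att, ori in config.conditions:
        rates = config.rates_for(att)
        for _ in range(config.n_trials_per_condition):
            window = rng.uniform(*config.trial_window_range)
            n_bins = pre_bins + int(round(window / dt))
            if config.session_type == "two_phase":
                states = sample_state_bins(rates, n_bins, dt, 1, rng)[0]
            else:
                states = np.zeros(n_bins, dtype=np.int8)
            dr_cond = delta_att if att == 0 else delta_r
            lam = (r_off[None, :] + np.outer(states, dr_cond)) * dt
            counts_list.append(rng.poisson(lam))  # (n_bins, n_channels)
            states_list.append(states)
            rows.append(
                {
                    "attention": att,
                    "orientation": ori,
                    "window": window,
                    "n_bins": n_bins,
                    "attended": att == 0,
                }
            )
    trial_meta = pd.DataFrame(rows)
    max_bins = int(trial_meta.n_bins.max())
    n_trials = len(rows)
    counts = np.zeros((n_trials, config.n_channels, max_bins), dtype=np.int64)
    states = np.full((n_trials, max_bins), -1, dtype=np.int8)
    for t, (c, s) in enumerate(zip(counts_list, states_list)):
        counts[t, :, : c.shape[0]] = c.T
        states[t, : s.size] = s

    centers = [
        generate_rf_map(c, config.rf_shift, config.rf_grid, seed=rng)
        for c in range(config.n_channels)
    ]
    channel_meta = pd.DataFrame(
        {
            "channel": np.arange(config.n_channels),
            "layer": [
                "superficial" if c < config.n_channels // 2 else "deep"
                for c in range(config.n_channels)
            ],
            "rf_x": [c[0] for c in centers],
            "rf_y": [c[1] for c in centers],
        }
    )
    ground_truth = {
        "states": states,
        "r_on": r_on,
        "r_on_attention": r_on_att,
        "r_off": r_off,
        "rates_control": config.rates_control,
        "rates_attention": config.rates_attention,
        "pre_bins": pre_bins,
        "session_type": config.session_type,
    }
    return SessionRecording(
        counts=counts,
        bin_width=dt,
        trial_meta=trial_meta,
        channel_meta=channel_meta,
        ground_truth=ground_truth,
    )


def save_session(rec: SessionRecording, path: str) -> None:
    """Write a session to an HDF5 container."""
    with h5py.File(path, "w") as h:
        h.create_dataset("counts", data=rec.counts, compression="gzip")
        h.attrs["bin_width"] = rec.bin_width
        for col in rec.trial_meta.columns:
            h.create_dataset(f"trial_meta/{col}", data=rec.trial_meta[col].to_numpy())
        h.create_dataset("channel_meta/channel", data=rec.channel_meta.channel)
        h.create_dataset(
            "channel_meta/layer",
            data=np.array(rec.channel_meta.layer, dtype="S16"),
        )
        h.create_dataset("channel_meta/rf_x", data=rec.channel_meta.rf_x)
        h.create_dataset("channel_meta/rf_y", data=rec.channel_meta.rf_y)
        if rec.ground_truth is not None:
            gt = rec.ground_truth
            g = h.create_group("ground_truth")
            g.create_dataset("states", data=gt["states"], compression="gzip")
            g.create_dataset("r_on", data=gt["r_on"])
            g.create_dataset("r_off", data=gt["r_off"])
            g.attrs["pre_bins"] = gt["pre_bins"]
            g.attrs["session_type"] = gt["session_type"]
            for nm in ("rates_control", "rates_attention"):
                g.attrs[f"{nm}_alpha1"] = gt[nm].alpha1
                g.attrs[f"{nm}_alpha2"] = gt[nm].alpha2


def load_session(path: str) -> SessionRecording:
    with h5py.File(path, "r") as h:
        counts = h["counts"][...]
        trial_meta = pd.DataFrame(
            {k: h[f"trial_meta/{k}"][...] for k in h["trial_meta"]}
        )
        channel_meta = pd.DataFrame(
            {
                "channel": h["channel_meta/channel"][...],
                "layer": [s.decode() for s in h["channel_meta/layer"][...]],
                "rf_x": h["channel_meta/rf_x"][...],
                "rf_y": h["channel_meta/rf_y"][...],
            }
        )
        ground_truth = None
        if "ground_truth" in h:
            g = h["ground_truth"]
            ground_truth = {
                "states": g["states"][...],
                "r_on": g["r_on"][...],
                "r_off": g["r_off"][...],
                "pre_bins": int(g.attrs["pre_bins"]),
                "session_type": str(g.attrs["session_type"]),
                "rates_control": MarkovRates(
                    float(g.attrs["rates_control_alpha1"]),
                    float(g.attrs["rates_control_alpha2"]),
                ),
                "rates_attention": MarkovRates(
                    float(g.attrs["rates_attention_alpha1"]),
                    float(g.attrs["rates_attention_alpha2"]),
                ),
            }
        return SessionRecording(
            counts=counts,
            bin_width=float(h.attrs["bin_width"]),
            trial_meta=trial_meta,
            channel_meta=channel_meta,
            ground_truth=ground_truth,
        )
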