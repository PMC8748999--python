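"""Binary On/Off occupancy fields and spatial statistics shared by the
lattice and binary-network simulators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateField",
    "spatial_covariance",
    "open_region_covariance",
    "radial_covariance",
]


@dataclass
class StateField:
    """Binary occupancy over lattice sites and time bins.

    ``S`` has shape ``(n_trials, n_bins, *lattice_shape)`` with values in
    {0, 1}.  ``dt`` is the bin width in seconds.  ``r_field`` optionally
    carries the underlying continuous rate variable at the same sampling.
    """

    S: np.ndarray
    dt: float
    r_field: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S)
        uniq = np.unique(self.S)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("state field must be binary {0, 1}")
        if self.S.ndim < 3:
            raise ValueError("S must be (n_trials, n_bins, *lattice_shape)")

    @property
    def lattice_shape(self) -> tuple[int, ...]:
        return self.S.shape[2:]

    @property
    def n_trials(self) -> int:
        return self.S.shape[0]

    @property
    def n_bins(self) -> int:
        return self.S.shape[1]


def spatial_covariance(
    field: StateField | np.ndarray,
    burn_in_bins: int = 0,
    stride: int = 1,
) -> np.ndarray:
    """Equal-time spatial autocovariance over displacements, FFT-accumulated.

    Returns an array of the lattice shape: entry ``e`` is
    ``<S(x) S(x+e)> - <S>^2`` averaged over sites, sampled time bins and
    trials (periodic wrap-around).
    """
    S = field.S if isinstance(field, StateField) else np.asarray(field)
    if S.ndim < 3:
        raise ValueError("need (n_trials, n_bins, *lattice_shape)")
    lat_shape = S.shape[2:]
    n_sites = int(np.prod(lat_shape))
    sub = S[:, burn_in_bins::stride]
    n_frames = sub.shape[0] * sub.shape[1]
    if n_frames == 0:
        raise ValueError("no frames left after burn-in")
    flat = sub.reshape(n_frames, *lat_shape)
    # subtract the per-site temporal mean so that a spatially inhomogeneous
    # occupancy profile (e.g. input patches) does not masquerade as
    # long-range covariance; accumulate the power spectrum in chunks to
    # bound memory
    site_mean = flat.mean(axis=0)
    axes = tuple(range(1, 1 + len(lat_shape)))
    power = np.zeros(lat_shape)
    chunk = max(1, int(2e7 // n_sites))
    for k in range(0, n_frames, chunk):
        f = np.fft.fftn(flat[k : k + chunk] - site_mean[None], axes=axes)
        power += (f * np.conj(f)).real.sum(axis=0)
    raw = np.fft.ifftn(power / n_frames, axes=tuple(range(len(lat_shape)))).real
    return raw / n_sites


def open_region_covariance(frames: np.ndarray) -> np.ndarray:
    """Displacement covariance of a rectangular (non-periodic) region.

    ``frames`` is (n_frames, h, w).  Returns an (h, w) map whose entry
    (dy, dx), dy, dx >= 0, is the covariance ``<S(x) S(x+e)> - <S>^2``
    averaged over all valid site pairs, frames, and the two diagonal
    orientations (e and its x-mirror), computed with zero-padded FFTs.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, h, w)")
    n, h, w = frames.shape
    # per-site mean subtraction: occupancy gradients inside the region
    # (patch edges) must not contribute to the displacement covariance
    frames = frames - frames.mean(axis=0, keepdims=True)
    ph, pw = 2 * h, 2 * w
    f = np.fft.rfftn(frames, s=(ph, pw), axes=(1, 2))
    raw = np.fft.irfftn((f * np.conj(f)), s=(ph, pw), axes=(1, 2)).real.sum(axis=0)
    ones = np.fft.rfftn(np.ones((h, w)), s=(ph, pw), axes=(0, 1))
    counts = np.fft.irfftn(ones * np.conj(ones), s=(ph, pw), axes=(0, 1)).real
    counts = np.maximum(np.round(counts), 1.0)
    # average the (dy, +dx) and (dy, -dx) orientations (e and -e coincide)
    cols = (-np.arange(w)) % (2 * w)
    pos = raw[:h, :w] / (n * counts[:h, :w])
    neg = raw[:h][:, cols] / (n * counts[:h][:, cols])
    return 0.5 * (pos + neg)


def radial_covariance(
    cov: np.ndarray,
    max_distance: float | None = None,
    n_bins: int | None = None,
    periodic: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Radially average a displacement covariance map.

    With ``periodic`` (default) distances follow the minimum-image
    convention of a periodic lattice; otherwise the map is taken as direct
    non-negative displacements.  Returns (distances, covariance) with
    integer-rounded distance bins by default; distance 0 is included.
    """
    shape = cov.shape
    if periodic:
        grids = np.meshgrid(
            *[np.minimum(np.arange(n), n - np.arange(n)) for n in shape],
            indexing="ij",
        )
    else:
        grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    dist = np.sqrt(sum(g.astype(float) ** 2 for g in grids))
    if max_distance is None:
        max_distance = min(shape) / 2.0
    mask = dist <= max_distance
    d = dist[mask]
    c = cov[mask]
    if n_bins is None:
        # bin at integer-rounded distances
        keys = np.round(d).astype(int)
    else:
        keys = np.digitize(d, np.linspace(0, max_distance, n_bins + 1)) - 1
    out_d, out_c = [], []
    for k in np.unique(keys):
        sel = keys == k
        out_d.append(d[sel].mean())
        out_c.append(c[sel].mean())
    return np.asarray(out_d), np.asarray(out_c)
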