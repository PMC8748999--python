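"""Configuration handling, seeding and scripted end-to-end experiments.

Experiments are plain functions keyed by name; ``run_experiment`` executes
one under a scale profile ("test", "desk" or "full"), derives a recorded
sub-seed for every stochastic stage from the global seed, writes its
numeric outputs as JSON and returns a manifest with content hashes.  The
importable functions (plus the scripts in ``examples/``) are the command
surface of the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import column, lattice, sessions
from .hmm import fit_hmm, select_n_phases
from .markov import MarkovRates
from .stats import fit_correlation_length

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SCALE_PROFILES",
    "validate_config",
    "run_experiment",
    "available_experiments",
]

#: problem sizes per scale profile: lattice side, trials, sim duration (s)
SCALE_PROFILES = {
    "test": {"lattice_size": 32, "n_trials": 20, "duration": 30.0},
    "desk": {"lattice_size": 64, "n_trials": 100, "duration": 120.0},
    "full": {"lattice_size": 256, "n_trials": 100, "duration": 300.0},
}


@dataclass
class RunConfig:
    experiment: str = "session-recovery"
    out_dir: str = "runs"
    seed: int = 0
    profile: str = "desk"
    options: dict = field(default_factory=dict)

    def subseed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)


_SCHEMA = {
    "experiment": str,
    "out_dir": str,
    "seed": int,
    "profile": str,
    "options": dict,
}


def validate_config(source) -> RunConfig:
    """Normalise a config mapping / JSON / YAML file into a RunConfig.

    Unknown keys produce a warning (forward compatibility); violations are
    collected and reported together, each naming the offending field.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
    elif source is None:
        data = {}
    else:
        data = dict(source)
    errors = []
    clean = {}
    for key, value in data.items():
        if key not in _SCHEMA:
            logger.warning("validate_config: unknown key %r ignored", key)
            continue
        want = _SCHEMA[key]
        if not isinstance(value, want):
            errors.append(f"{key}: expected {want.__name__}, got {type(value).__name__}")
            continue
        clean[key] = value
    cfg = RunConfig(**clean)
    if cfg.profile not in SCALE_PROFILES:
        errors.append(f"profile: must be one of {sorted(SCALE_PROFILES)}")
    if cfg.seed < 0:
        errors.append("seed: must be >= 0")
    for key, value in cfg.options.items():
        if key in ("Q", "W", "duration", "n_trials") and (
            not isinstance(value, (int, float)) or value < 0
        ):
            errors.append(f"options.{key}: must be a non-negative number")
    if cfg.experiment not in _EXPERIMENTS:
        errors.append(
            f"experiment: unknown name {cfg.experiment!r}; available: "
            f"{sorted(_EXPERIMENTS)}"
        )
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _exp_session_recovery(cfg: RunConfig) -> dict:
    """Generate a two-phase session, fit the HMM, report recovered rates."""
    prof = SCALE_PROFILES[cfg.profile]
    scfg = sessions.SessionConfig(
        n_trials_per_condition=cfg.options.get("n_trials", prof["n_trials"]),
        n_attention=1,
        n_orientations=1,
        trial_window_range=(1.0, 1.0),
        rates_control=MarkovRates(10.0, 10.0),
        rates_attention=MarkovRates(10.0, 10.0),
        seed=cfg.subseed("session"),
    )
    rec = sessions.generate_session(scfg)
    fit = fit_hmm(rec, condition=(0, 0), seed=cfg.subseed("em"))
    rates = fit.params.markov_rates()
    return {
        "alpha1_true": 10.0,
        "alpha2_true": 10.0,
        "alpha1_hat": rates.alpha1,
        "alpha2_hat": rates.alpha2,
        "n_trials": int(rec.n_trials),
    }


def _exp_phase_selection(cfg: RunConfig) -> dict:
    """Cross-validated phase count on a two-phase and a one-phase session."""
    out = {}
    for kind in ("two_phase", "one_phase"):
        scfg = sessions.SessionConfig(
            n_trials_per_condition=40,
            n_attention=1,
            n_orientations=1,
            trial_window_range=(1.0, 1.0),
            session_type=kind,
            seed=cfg.subseed(f"sess-{kind}"),
        )
        rec = sessions.generate_session(scfg)
        sel = select_n_phases(
            rec, condition=(0, 0), candidates=range(1, 5),
            seed=cfg.subseed(f"cv-{kind}"),
        )
        out[f"{kind}_chosen"] = int(sel.n_phases)
        out[f"{kind}_cv"] = [float(x) for x in sel.cv_errors]
    return out


def _exp_zero_distance_agreement(cfg: RunConfig) -> dict:
    """Mean analytic zero-distance noise correlation vs direct simulation."""
    from .validation import zero_distance_agreement

    res = zero_distance_agreement(
        seed=cfg.subseed("zero-d"),
        n_pairs=cfg.options.get("n_pairs", 10_000),
        n_trials=cfg.options.get("n_trials", 20_000),
    )
    return res


def _exp_binary_correlation_length(cfg: RunConfig) -> dict:
    """Binary lattice simulation vs the closed-form correlation length."""
    from .binary import BinaryNetParams, simulate_binary
    from .fields import radial_covariance, spatial_covariance

    prof = SCALE_PROFILES[cfg.profile]
    rates = MarkovRates(10.0, 10.0)
    L_target = cfg.options.get("L", 1.0)
    beta = L_target**2 * rates.total
    params = BinaryNetParams(
        rates=rates, beta1=beta, beta2=beta,
        shape=(prof["lattice_size"],) * 2, update_bin=0.001,
    )
    fld = simulate_binary(
        params, duration=prof["duration"], seed=cfg.subseed("binary"),
        record_stride=20,
    )
    cov = spatial_covariance(fld, burn_in_bins=fld.n_bins // 10)
    d, c = radial_covariance(cov, max_distance=min(6 * L_target, 16))
    fit = fit_correlation_length(d, c)
    return {
        "L_theory": float(L_target),
        "L_fit": float(fit.length),
        "relative_error": float(abs(fit.length - L_target) / L_target),
    }


def _exp_lattice_attention(cfg: RunConfig) -> dict:
    """Attended vs control patch: episode durations and correlation length."""
    prof = SCALE_PROFILES[cfg.profile]
    size = cfg.options.get("lattice_size", prof["lattice_size"])
    lcfg = lattice.LatticeConfig(
        size=size,
        column_params=column.CANONICAL,
        protocol=lattice.TrialProtocol(0.0, 0.0, cfg.options.get("duration", prof["duration"])),
        n_trials=1,
        I_att=cfg.options.get("I_att", 0.004),
        seed=cfg.subseed("lattice"),
    )
    field = lattice.simulate_lattice(lcfg)
    ac = lattice.attention_contrast(field, burn_in=0.5)
    return {
        "tau_on_att": ac.tau_on["attention"],
        "tau_on_ctl": ac.tau_on["control"],
        "tau_off_att": ac.tau_off["attention"],
        "tau_off_ctl": ac.tau_off["control"],
        "L_att": float(ac.L_att),
        "L_ctl": float(ac.L_ctl),
    }


_EXPERIMENTS = {
    "session-recovery": _exp_session_recovery,
    "phase-selection": _exp_phase_selection,
    "zero-distance-agreement": _exp_zero_distance_agreement,
    "binary-correlation-length": _exp_binary_correlation_length,
    "lattice-attention-contrast": _exp_lattice_attention,
}


def available_experiments() -> list[str]:
    return sorted(_EXPERIMENTS)


def run_experiment(config: RunConfig | dict | str | None) -> dict:
    """Run one named experiment and write results + manifest JSON.

    Returns the manifest: experiment name, seed, profile, result file path
    and its SHA-256 content hash.  Re-running with the same config gives
    identical hashes.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    if cfg.experiment not in _EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; available: "
            f"{available_experiments()}"
        )
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = _EXPERIMENTS[cfg.experiment](cfg)
    payload = json.dumps(result, indent=2, sort_keys=True, default=float)
    result_path = out_dir / f"{cfg.experiment}.json"
    result_path.write_text(payload)
    manifest = {
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "profile": cfg.profile,
        "result_file": str(result_path),
        "sha256": hashlib.sha256(payload.encode()).hexdigest(),
    }
    (out_dir / f"{cfg.experiment}.manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
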