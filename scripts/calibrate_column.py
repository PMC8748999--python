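"""Calibration sweep for the canonical column parameters.

Scans the noise intensity Q (at the frozen epsilon, g, f, tau_a) and
reports the isolated column's Off->On and On->Off switching rates plus an
exponentiality check of the episode durations, then scans the attentional
current to show the resulting rate modulation.  The canonical set shipped
in ``onoffnet.column.CANONICAL`` was frozen from this sweep at the point
where both rates sit at ~10 per second with cleanly exponential episodes.

Run:  python scripts/calibrate_column.py [--duration 1500]
"""

import argparse
from dataclasses import replace

import numpy as np
from scipy import stats as sps

from onoffnet.column import CANONICAL, simulate_column
from onoffnet.markov import episode_durations


def summarize(params, duration, seed, label):
    tr = simulate_column(params, duration, seed=seed)
    ton, toff, rates = tr.episode_stats()
    on, off = episode_durations(tr.S, tr.dt)
    rng = np.random.default_rng(0)
    don = on - rng.random(on.size) * tr.dt
    p_ks = sps.kstest(don, "expon", args=(0, don.mean())).pvalue
    print(
        f"{label}: alpha1={rates.alpha1:6.2f}/s alpha2={rates.alpha2:6.2f}/s "
        f"tau_on={ton * 1e3:6.1f} ms tau_off={toff * 1e3:6.1f} ms "
        f"KS(exp) p={p_ks:.3f}  (n={on.size})"
    )


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--duration", type=float, default=1500.0)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    print("# noise sweep at I_att = 0")
    for q in (0.0060, 0.0065, 0.0070, 0.0075, 0.0080):
        summarize(replace(CANONICAL, Q=q), args.duration, args.seed, f"Q={q:.4f}")

    print("\n# attentional current sweep at the canonical Q")
    for i_att in (-0.005, 0.0, 0.005, 0.010):
        summarize(
            replace(CANONICAL, I_att=i_att),
            args.duration,
            args.seed,
            f"I_att={i_att:+.3f}",
        )


if __name__ == "__main__":
    main()
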