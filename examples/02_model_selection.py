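"""Cross-validated choice of the number of population phases.

Fits HMMs with 1..4 phases to a switching (two-phase) and a flat
(one-phase) synthetic session and prints the normalised cross-validation
error curves.  The elbow at 2 for the switching session, and the absence
of any improvement beyond 1 for the flat session, is how recordings are
classified as two-phase or one-phase.
"""

from onoffnet.hmm import select_n_phases
from onoffnet.markov import MarkovRates
from onoffnet.sessions import SessionConfig, generate_session

for kind in ("two_phase", "one_phase"):
    cfg = SessionConfig(
        n_trials_per_condition=40,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(1.0, 1.0),
        session_type=kind,
        rates_control=MarkovRates(10.0, 10.0),
        rates_attention=MarkovRates(10.0, 10.0),
        seed=2,
    )
    rec = generate_session(cfg)
    sel = select_n_phases(rec, condition=(0, 0), candidates=range(1, 5), seed=0)
    curve = ", ".join(
        f"n={n}: {e:.3f}" for n, e in zip(sel.candidates, sel.cv_errors)
    )
    print(f"{kind:9s} session -> CV error (normalised to n=1): {curve}")
    print(f"          chosen number of phases: {sel.n_phases}")
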