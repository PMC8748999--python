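"""Attention on the lattice: episode durations and correlation length.

Simulates a small coupled-column lattice with two patches, one receiving
an excitatory attentional current, and prints each patch's mean episode
durations and fitted spatial correlation length.  Attention lengthens On
episodes within the attended patch and shortens the distance over which
On/Off fluctuations are shared across columns.
"""

from onoffnet.column import CANONICAL
from onoffnet.lattice import (
    LatticeConfig,
    Patch,
    TrialProtocol,
    attention_contrast,
    simulate_lattice,
)

cfg = LatticeConfig(
    size=24,
    column_params=CANONICAL,
    protocol=TrialProtocol(0.0, 0.0, 40.0),
    n_trials=1,
    I_att=0.002,
    seed=1,
    stimulus_patches=(Patch(7, 17, 1, 11), Patch(7, 17, 13, 23)),
)
field = simulate_lattice(cfg)
ac = attention_contrast(field, burn_in=0.5)
for name in ("attention", "control"):
    print(
        f"{name:9s} patch: tau_on = {ac.tau_on[name] * 1e3:5.1f} ms, "
        f"tau_off = {ac.tau_off[name] * 1e3:5.1f} ms, "
        f"L = {ac.L[name].length:.2f} lattice units"
    )
print("the attended patch dwells longer in the On phase and its On/Off")
print("clusters are spatially tighter (shorter correlation length).")
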