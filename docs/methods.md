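# Methods

`onoffnet` models correlated variability in visual cortex as the product of
columnar On-Off state dynamics propagating across a laterally connected
network, and provides the matching inference and statistics pipeline.  This
note records the model assumptions, the parameter choices that were
genuinely open, the numerics, and what the synthetic benchmarks do and do
not establish.

## The population state and spiking model

The elementary object is a two-state population process S(t) ∈ {Off, On}
with Off→On rate α₁ and On→Off rate α₂ (s⁻¹), giving exponentially
distributed episode durations with means τ_on = 1/α₂ and τ_off = 1/α₁ and
stationary On probability S∞ = α₁/(α₁+α₂).  Neurons of the same column fire
as conditionally independent inhomogeneous Poisson processes with rate
r(t) = r_off + Δr·S(t), Δr = r_on − r_off ≥ 0: a doubly stochastic model in
which the only shared signal within a column is the state path.

All count-statistic predictions follow from the variance of the integrated
On-time in a window T,

    V(α₁,α₂) = 2α₁α₂/(α₁+α₂)³ · [T − (1 − e^{−(α₁+α₂)T})/(α₁+α₂)],

verified here analytically and by Monte Carlo (the `theory` module): count
variance Δr²V + r_off T + S∞ T Δr, Fano factor = variance over mean (≥ 1,
asymptotically proportional to Δr), and the zero-distance noise-correlation
amplitude A = V·Δr_i Δr_j / √(Var_i Var_j).  Pairs are required to share
(α₁, α₂, T); mixed-rate pairs are rejected rather than silently averaged.

## The column model

Each column is the stochastic rate-adaptation system

    ε dr/dτ = F(r) − a + W·Lap(r) + I_stim + I_att
    da/dτ   = g·r − a + f + √(2Q)·ξ(τ)

with the piecewise-linear self-coupling F(r) = −1−r (r ≤ −½), r (|r| < ½),
1−r (r ≥ ½), written in dimensionless model time τ.  A timescale parameter
`tau_a` (seconds of wall time per unit of τ) converts to physical time.  It
is needed because the equations pin the adaptation relaxation at one unit
of τ, while cleanly exponential ~100 ms dwell times require the adaptation
relaxation to be much faster than the escape events; with `tau_a` = 0.5 ms
the escapes at ~10 s⁻¹ are rare events on the relaxation clock and the
Kramers picture applies.  The binary state is S = Θ[r] with r = 0 counting
as Off (a measure-zero tie-break).

Canonical parameters (frozen after the sweep in
`scripts/calibrate_column.py`): ε = 0.2, g = 0.5, f = 0, Q = 0.007,
tau_a = 0.0005 s, W = 0.02, output step dt = 5 ms.  They give symmetric
wells with α₁ ≈ α₂ ≈ 10 s⁻¹ and episode-duration distributions that pass a
KS exponentiality test at 1% over thousands of episodes.  A residual,
physically unavoidable deficit of episodes shorter than the adaptation
traversal time (~1 ms here) is below the KS detection limit at these run
lengths; at larger `tau_a` it is not, which is the quantitative reason for
the small `tau_a`.

An excitatory attentional current I_att > 0 shifts the r-nullcline upward:
the Off well shallows (α₁ rises) and the On well deepens (α₂ falls).  At
I_att = 0.005 the canonical column gives τ_on/τ_off ≈ 115/84 ms versus
99/98 ms in control — the same ordering and comparable magnitude to the
modulation reported for columnar recordings — with α₁+α₂ nearly conserved.

Noise placement: the white noise lives in the adaptation equation (which is
what makes the binary reduction clean); `simulate_column` also offers
`noise_target="rate"` and reproduces qualitatively identical metastable
switching there.

## The binary-unit reduction and its estimation

In the bistable regime each column reduces to a binary unit with
neighbor-dependent rates α₁ + β₁·Lap and α₂ − β₂·Lap, where Lap is the
discrete Laplacian of the binary field (so both rates stay non-negative for
β ≥ 0).  The coupling constants are estimated numerically
(`estimate_effective_rates`): the column is simulated with its four
neighbors clamped, k On and 4−k Off, the clamp acting through the coupling
linearised at the binary level (neighbors contribute their fixed-point
rates); switching rates are estimated from episode counts at fine (1 ms)
output sampling, and β₁, β₂ are the local slopes of the rates versus the
Laplacian around zero (the reduction is a leading-order expansion and the
measured rate response is convex in k, so a global linear fit would be
dominated by the far clamp levels).

Under attention the two slopes split: β̂₂ (the efficacy of neighbors to
drive On→Off transitions) falls steeply while β̂₁ rises moderately.  The
single effective coupling reported alongside is the occupancy-weighted
mean-field combination β_eff = (1−S∞)β₁ + S∞β₂, which is the coupling a
uniform-field linear response sees.  In this calibration β_eff falls under
excitatory attention, driven by the β₂ drop.

## Master equation, moments and the correlation length

The reduced network's master equation is solved exactly for ≤ 12 units
(dense generator, null-space stationary state); this is the oracle for the
lattice simulator (2×2 joint-state histogram, total variation < 0.01) and
exhibits the expected irreversibility: for β₁ ≠ β₂ stationary probability
fluxes do not balance (no detailed balance, hence no equilibrium Ising
description), while the symmetric case balances to numerical precision.

The first- and pair-moment equations are integrated as written; the pair
equation is closed at second order and is exact for β₁ = β₂ (the
(β₂−β₁)·⟨S_i S_± S_j⟩ term cancels).  Their steady state obeys a screened
Poisson equation whose decay constant is L = √(β₁/(α₁+α₂)) lattice units.
Two numerical facts matter for testing this law:

- In 1-D the stationary covariance is exactly S∞(1−S∞)·e^{−d/L}; the
  closed-form pair-correlation expression is reproduced to < 0.2% on a
  512-ring.  In 2-D the lattice Green's function carries a ~d^{−1/2}
  prefactor, so the *amplitude* normalisation is 1-D/continuum-exact only.
- An exponential fitted to a 2-D curve at short range is therefore biased
  low.  `fit_correlation_length` fits log-linearly on an adaptive window
  [2.5·L̂, 7·L̂] (iterated), after discarding points beyond ~4.5 e-folds of
  decay where an empirical curve is noise-floor dominated.  On exact
  exponential input the fit is exact to machine precision; on simulated
  64×64 fields the residual bias is ≲ 10–14%, within the 15% band used in
  the tests for L ∈ [0.5, 2].

The binary simulator updates synchronously in bins of `update_bin` with
flip probability clip(w·Δt, 0, 1); Δt = 10 ms mirrors the recorded-data
binning, but quantitative oracle comparisons use Δt = 1 ms because the
synchronous discretisation error is O(w·Δt).  A random-sequential
(asynchronous) mode cross-checks that stationary statistics are
scheme-independent.

## The lattice network

`simulate_lattice` integrates the column dynamics on a periodic (default)
or reflecting N×N lattice with the 4-neighbor diffusive coupling, two
rectangular stimulus patches (50×50 at the full 256 scale, scaled down
proportionally otherwise) and an attentional current on one patch during
the cue period.  Patch analyses subtract per-site temporal means before
computing displacement covariances — an occupancy gradient at patch edges
would otherwise masquerade as long-range covariance — and fit the radial
covariance decay for the patch correlation length.

Problem sizes: the package defaults describe the full protocol
(256×256, 100 trials); tests and the shipped experiments run 32×32–64×64
lattices with 60–100 s of dynamics, which give stable episode statistics
and correlation-length fits at a few minutes per run.

## Inference: the shared-state Poisson HMM

`fit_hmm` implements EM with a log-space/scaled forward–backward E-step
(the scaled implementation is verified against both a log-space reference
and brute-force path enumeration to 1e-10) and closed-form M-steps.  The
initial state distribution is tied to the stationary distribution of the
transition matrix, so the two-phase 16-channel model has exactly
2×16 + 2 = 34 free parameters.  Label switching is resolved by ordering
phases by population mean rate (On = highest).  Initialisation splits
per-channel rates at count quantiles with multiplicative jitter; 5 restarts
by default.  Fitting starts 400 ms after the cue and runs to trial end.

Model selection uses 4-fold cross-validation over trials with a
leave-one-channel-out prediction error: posteriors are inferred from the
other channels and the held-out channel's counts, aggregated in 200 ms
windows, are predicted from them (mean squared error, averaged over
channels, conditions and folds, normalised by the 1-phase error).  The
leave-one-channel-out construction is what makes 1-vs-2 phase comparison
well-posed: with posteriors computed from the full test data, a richer
model can track the held-out channel's own Poisson noise.  The elbow rule
is explicit: the smallest n whose normalised error is within 2% of the
minimum; a session is one-phase when n = 1 already qualifies.

Transition probabilities convert to rates by the first-order formulas
α₁ = (1−p_off)/Δt, α₂ = (1−p_on)/Δt with Δt = 10 ms.  The synthetic
generator simulates the state in discrete 10 ms bins with per-bin switch
probabilities 1 − e^{−αΔt}, which makes the conversion consistent with the
generator to first order (recovery lands within ~5% systematically, inside
the 10% recovery band with margin).  The exact grid-observed chain would
instead have switch probabilities (α/(α₁+α₂))(1−e^{−(α₁+α₂)Δt}); the
binned construction was kept because it ties directly to the conversion
formula used throughout.

## Synthetic sessions

A session mimics a 16-channel laminar recording: 4 attention × 8
orientation conditions (attention index 0 = attend-in, using the attention
transition rates), per-trial analysis windows drawn uniformly from
0.2–1.9 s after a 0.4 s pre-window, counts in 10 ms bins.  Channel rates
are drawn once per session: r_off ~ Lognormal(median 60 Hz, σ=0.5) and
Δr ~ Lognormal(median 80 Hz, σ=0.6), giving a median multi-unit rate near
100 Hz and mean rates near 110 Hz with a broad Δr spread; the parametric
form is an emulation choice (only histogram shapes are known for the real
recordings, not a parametric family).  One-phase sessions set Δr = 0 on
every channel (each channel fires at its state-averaged mean rate), so no
HMM-detectable switching exists by construction.  Attention can additionally
modulate each channel's Δr by mean-one lognormal gains
(`attention_rate_gain_sigma`), which is what gives the prediction-versus-
measurement decile comparisons a heterogeneous signal to work with.
Default transition rates are control (10.2, 9.8) and attention
(11.4, 8.8) s⁻¹, i.e. τ ≈ 98/102 ms control and 114/88 ms attended.

RF centers are centers of mass of synthetic 6×6 response maps whose
Gaussian peak drifts along the channel axis by `rf_shift` dva per step
(default 0.3, spanning 4.5 dva over 16 channels); the grid geometry is
wide enough that truncation at the map edge moves the center of mass by
≪ 0.1 dva.  RF distances convert to cortical distances through
M(E) = 3.1·E^{−0.9} mm/dva at the pair-mean eccentricity.

What the generator does *not* emulate: spike waveforms, eye movements,
laminar current-source-density structure, cross-channel rate correlations
beyond the shared state, or non-stationarities within a session.  Passing
tests therefore establish the internal consistency of inference, theory
and simulation — not that real recordings satisfy the model.

## Statistics conventions

Counts for pairwise statistics are taken in one 200 ms window 400–600 ms
post-cue per trial.  Fano factors use the unbiased (n−1) variance.  Noise
correlations are Pearson coefficients across trials; pairs with zero
variance are dropped and counted.  Modulation indices are
(att−ctl)/(att+ctl), undefined-denominator items excluded.  Distance
regressions are OLS with one-sided t-tests on the slope sign.  Decile
tables sort by the grouping statistic with a stable order (ties broken by
position) into equally sized groups.

### Symmetry of the attentional response

At the canonical operating point (f = 0, I = 0) the column equations are
exactly mirror-symmetric under (r, a, I) → (−r, −a, −I), because F is odd
and the a-nullcline passes through the origin.  Consequently an inhibitory
current is the exact mirror of an excitatory one: it lengthens Off and
shortens On episodes, and it *also shrinks* the correlation length
(relabelling S → 1−S maps the inhibitory parameter set of the binary
reduction onto the excitatory one).  In Kramers terms the effective
coupling is proportional to the stationary switching flux
α₁α₂/(α₁+α₂), which is maximal at rate equality, so any perturbation away
from the symmetric point reduces it.  Within this model class a baseline
with α₁ ≈ α₂ therefore cannot produce an odd, sign-dependent
correlation-length response — lengthening L would require an asymmetric
operating point whose baseline episode durations would then differ
markedly.  The package reports this honestly: the excitatory ordering
(L shrinks) is reproduced and tested; the inhibitory ordering (L grows)
is not reproducible at this operating point and its test documents the
failure.

## Known limitations

- The correlation-length law is verified for the binary network where β is
  a parameter; for the dynamical lattice the clamp-based β̂ underestimates
  the realised coupling (the rate response to neighbors is convex, and
  fluctuating neighbors sample that convexity), so lattice correlation
  lengths exceed √(β̂₁/(α₁+α₂)).
- At patch-level attentional inputs the coupled lattice amplifies the
  occupancy shift relative to the isolated column (positive feedback
  through the neighbors), so patch currents should be kept small
  (|I_att| ≲ 0.005) to stay in the moderately modulated regime.
- The exact closed-form dependence of (α, β) on (f, g, Q, I) is not
  implemented; couplings are estimated from simulation.
- Fisher-information / differential-correlation analyses are out of scope.
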