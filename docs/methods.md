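# Methods

## Model

Two excitatory pools (A, B) compete through self-excitation and mutual
inhibition; their slow dynamics are carried entirely by NMDA gating
variables `S_A, S_B` (the standard two-variable reduction of the recurrent
cortical decision circuit).  Firing rates are algebraic functions of the
instantaneous synaptic current through the F–I curve
`φ(I) = (c_E I − I_th)/(1 − e^{−g_E (c_E I − I_th)})`; they are never
integrated.  At the removable singularity `c_E I = I_th` the implementation
evaluates the first-order expansion `1/g_E + x/2`, which is exact to
`O(x²)`.

The confidence pool C receives `J_dc (r_A + r_B)`, recurrent drive
`J_C S_C`, background `I_0c`, and an activity-dependent negative feedback
that implements the slope detection:

* **adaptation variant** (default): a current `J_a·a` with
  `da/dt = −a/τ_a + A_1 r_C + A_0`.  `A_1` scales spike-driven adaptation,
  `A_0` sub-threshold adaptation; τ_a = 0.25 s.
* **std variant**: a depression factor `x` multiplying the
  decision→confidence drive, `dx/dt = (1−x)/τ_d − U_0 x r_in`, with the
  presynaptic rate `r_in = r_A + r_B` driving depletion (Tsodyks–Markram
  form) and τ_d = 1 s.  A `std_site="recurrent"` switch instead depresses
  the recurrent term `J_C S_C x` with depletion driven by `r_C`; in that
  configuration the depression has at most ~0.14 nA of leverage and cannot
  overcome the feedforward input, so the confidence–coherence relation
  inverts — it is retained for comparison, not as the default.
* **none**: the adaptation formula with `a ≡ 0`, as a control.

The confidence rate relaxes to its transfer function,
`dr_C/dt = (φ_C − r_C)/τ_r` with τ_r = 2 ms.  A literal "leaky" form
`dr_C/dt = −r_C/τ_r + φ_C` is available behind `rate_eq_mode="literal"`;
its fixed point is `τ_r φ_C` (≈ 0.05 Hz scale), dimensionally a
rate·time, so the relaxation form is the default — it is the standard
firing-rate-model reading and the only one under which the confidence pool
reaches the tens of hertz that make a readable report.

## Parameters and the open choices

All circuit constants default to the model's standard operating point
(τ_NMDA = 0.1 s, γ = 0.641, J_ii = 0.2609 nA, J_ij = 0.0497 nA,
I_0 = 0.3255 nA, c_E = 270 Hz/nA, I_th = 108 Hz, g_E = 0.154 s, θ = 25 Hz,
J_C = 0.15 nA, J_dc = 0.015 nA/Hz, J_fc = 2·10⁻⁴ nA/Hz, I_0c = 0.2 nA,
μ0 = 30 Hz, A_1 = 0.05, A_0 = 0.03, U_0 = 10⁻⁴, dt = 5·10⁻⁵ s).  Four
quantities required a decision:

**Stimulus coupling J_ext.**  Implemented in units of nA/Hz (like J_dc),
default 5.2·10⁻⁴ nA/Hz — the canonical value of the reduced decision model
this circuit builds on.  With μ0 = 30 Hz this gives a 0.0156 nA stimulus
current, the regime in which the pools ramp over hundreds of milliseconds.
A coupling of order 0.15 nA would inject a current ~300× the stimulus scale
and drive both pools across threshold at the first post-onset sample,
abolishing ramping, psychometric and chronometric behavior alike.

**Noise.**  The noise currents are independent Ornstein–Uhlenbeck processes
per pool, updated once per step with the exact discrete transition
(`decay = e^{−dt/τ}`, innovation SD `σ√(1−decay²)`), so their statistics are
step-size-robust; they are initialized from the stationary distribution.
τ_noise = 2 ms.  The amplitude defaults to σ = 0.01 nA: at σ ≈ 0.02 the
first crossing of the instantaneous rate `φ(I + I_noise)` sampled every
0.05 ms is dominated by fast noise excursions — choices fire before the
attractor has separated, and the still-active losing pool feeds the
confidence pool enough current to invert the confidence–coherence relation.
At σ = 0.01 decisions are drift-dominated and the behavioral signatures
hold; both σ and τ are configurable.

**Adaptation and depression gain scales.**  Taken literally, J_a = 0.001
with `a ~ τ_a A_1 r_C ≈ 0.1` yields an adaptation current below 10⁻³ nA —
three orders of magnitude under every other term, leaving the slope
detector inert.  The package therefore exposes `adaptation_scale`
(multiplying J_a; default 2600, i.e. an effective gain of 2.6 nA per unit
`a`, adaptation currents of order 0.1 nA) and `std_scale` (multiplying U_0;
default 1000, i.e. an effective release fraction of 0.1, the physiological
range for depressing cortical synapses).  The defaults are the operating
point at which mean rc rises strictly across the six-level coherence ladder
for both variants; setting both scales to 1 recovers the literal constants.

**Trial protocol.**  t ∈ [−0.2 s, 1.5 s], stimulus in [0 s, 1 s); threshold
crossings are accepted through the end of the trial because the slow NMDA
dynamics can carry a pool over θ shortly after stimulus offset
(`detect_until` restricts this).  The coherence ladder defaults to the
classical {0, 3.2, 6.4, 12.8, 25.6, 51.2} %.  Ties at the crossing sample go
to the larger rate, then to pool A.  rc is the mean of r_C over the 10 ms
before the crossing (window clipped at stimulus onset for very early
decisions; `rc_window` below one step gives a point sample); the alternative
readouts r_A + r_B, |r_A − r_B| and the total decision-pool input are
averaged over the same window.  No-decision trials are retained in the trial
table with `choice = "none"` and are excluded from the statistics by default
(`undecided="error"` scores them as errors instead).

## Integration

Midpoint second-order Runge–Kutta on the deterministic state
(S_A, S_B, S_C, r_C, a, x) with the noise currents frozen at their
start-of-step values, followed by the exact OU update.  After every step the
gating variables are clamped to [0, 1], x to (0, 1], r_C to ≥ 0 — the NMDA
equation can overshoot its invariant range at finite dt.  Because clamping
and the algebraic rates are deterministic, a trial is bit-exact across runs
and across batch compositions: every trial owns an RNG seeded by hashing
(master_seed, session, trial) — plus the grid indices inside a sweep —
through `SeedSequence`, and noise is drawn in fixed 2000-step chunks so the
stream does not depend on when other trials in a batch finish.  Sessions
differ only by their RNG streams; they are resampling units for error bars
(all error bars are standard errors over session means).

Fixed points of the midpoint map coincide with the roots of the vector
field, so noise-free trajectories relax onto equilibria that an independent
root-finder confirms (the test suite checks agreement to 10⁻⁶ and a
residual below 10⁻⁸, plus the expected fourfold error reduction when dt is
halved).

## Analysis defaults

* Accuracy-by-confidence: quantile bins pooled across coherences (default
  5); ties broken by first occurrence so bins are equal-count.
* Psychometric split: within-coherence median of the readout (a global
  median would confound the split with the readout–coherence correlation);
  values at the median go to the low half.
* Folded X: trial-level Spearman correlations of readout with coherence per
  branch.  Significance targets the *fold* — the statistic
  ρ_correct − ρ_error under permutation of correct/error labels within
  coherence.  A branch-marginal null is degenerate here: any readout
  correlated with coherence keeps both branches trending under label
  exchange, so only the branch difference is informative.
* Coding slope: OLS slope of baseline-subtracted (c = 0) mean rc on
  coherence in percent, in Hz/%.

## Problem sizes

The default experiment is 10 sessions × 500 trials (≈ 830 trials per
coherence level).  The coding-capacity map runs 96 trials per (A_0, A_1)
cell on a ±50 % grid around the default — enough to sign the slope
(standard error ≈ 0.015 Hz/%) while keeping a 9-cell sweep to about a
minute per cell on one CPU.

## What the simulation does and does not emulate

The generator produces the task structure of a reaction-time random-dot
experiment: balanced preferred directions, a fixed coherence ladder,
independent trials, session-level resampling.  It does not emulate
sequential dependencies, lapses, motor or non-decision time (decision times
are threshold crossings, not full reaction times), stimulus fluctuations
beyond stationary OU currents, or spiking variability.  Passing the
signature tests therefore shows the *circuit mechanism* produces
confidence-like statistics under idealized conditions, not that it fits any
particular data set.

## Known limitations

* **Error-branch flatness under adaptation.**  At the default operating
  point, error decisions take ≳ 0.75 s ≈ 3 τ_a; by then the confidence pool
  sits at its input-determined equilibrium and the adaptation variable has
  forgotten trial history, so the error branch of the folded X is only
  weakly decreasing for the adaptation variant (its trial-level correlation
  hovers near zero, though the fold interaction is strongly significant).
  The depression variant, whose resource variable integrates the *input*
  over τ_d = 1 s, shows the full folded X robustly.  Raising the noise to
  push errors into the adaptation-sensitive window destroys the strict rc
  ordering at low coherence — the two signatures compete for the noise
  amplitude under τ_a = 0.25 s.
* The psychometric function is steeper than typical primate data (accuracy
  saturates by ~13 % coherence), a known property of this parameter set
  under low noise.
* The coding-slope map has a boundary: at A_0 ≈ +50 % with A_1 ≈ −50 % the
  slope approaches zero — beyond it (e.g. doubled A_0 with halved A_1)
  coding fails, which is the point of mapping (A_0, A_1) at all.
* The model makes no contact with change-of-mind or post-decision
  re-evaluation; confidence is frozen at the moment of commitment.
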