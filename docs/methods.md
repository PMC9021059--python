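# Methods

## Model

The adaptive-response probability rate after a short dose pulse is
p_AR(D, t) = α₀ D² t² e^(−α₁D − α₂t) [h⁻¹], the product of a gamma-like
dose kernel and time kernel, both with shape exponent 2 (the simplest
hunchbacked forms; the amplitudes of the two kernels are absorbed into a
single α₀).  All three α are strictly positive.  The model's assumptions:

* a pulse is instantaneous relative to the intervals between pulses;
* repair triggered by distinct pulses is additive — two pulses separated by
  Δt contribute p_AR(D₁, t) + p_AR(D₂, t − Δt), and simultaneous pulses
  (Δt = 0) are treated as one pulse of the summed dose;
* lesion disappearance follows dN = −N p_AR dt, i.e. adaptive-response
  repair is the only removal channel, giving the closed-form survival
  N(T) = N₀ e^(f(D,T) − f(D,0)) with f the (negative) antiderivative of
  p_AR.  Since f(D, ∞) = 0, a fraction e^(−ξ_D) of lesions is never
  repaired;
* lesion induction is linear in dose, N = μ₀ + μ₁D, with a small metabolic
  background μ₀ ≪ μ₁ that the δ expressions neglect (the μ-dependent form
  is available and agrees exactly when μ₀ = 0);
* mutations are the T → ∞ limit of lesions: whatever is unrepaired when
  repair has run its course is permanent.

The effect size δ = 1 − N₁₊₂/N₂ compares the priming+challenge arm with
the challenge-only arm whose clock starts at the challenge instant; the
challenge's own repair factor is common to both arms and cancels.  δ < 1
always; δ → δ_min = −(D₁/D₂)e^(−ξ_D₁) < 0 as Δt → ∞.  The boundary
interval at which δ crosses zero is found by bracketed root search on the
monotone function f(D₁, ·).

Multi-priming schemes are evaluated by a survival recursion rather than a
printed nested expression: walking the pulse sequence, the unrepaired pool
S gains D_j at each pulse and decays between pulses under the summed
repair integrals of every pulse already delivered; after the challenge all
signals integrate to infinity.  The recursion reproduces the single- and
two-priming closed forms exactly at n = 1, 2, which fixes the otherwise
ambiguous nesting for larger n.  Its Δt → 0, n → ∞ limit is *not* chronic
exposure — that regime saturates at the rate P_c = ξ(Ḋ) and is provided
separately (`chronic_saturation`, and as the τ → ∞ limit of the continuous
integral form).

## Units and numerics

Internal units are Gy and hours; data printed in mGy are converted at load
(the worked examples in abstract units work unchanged — the equations carry
units only through the α).  t = ∞ is a first-class sentinel with f ≡ 0.
Every exponent of the form f(D, b) − f(D, a) with b ≥ a is mathematically
≤ 0 (f is nonincreasing in time) and is clipped at 0 before
exponentiation: at extreme parameter values the two f can be enormous and
their floating-point difference loses its sign, and the clip is exact, not
an approximation.  In the multi-priming recursion the challenge's lifetime
factor e^(−ξ) is cancelled analytically against the reference arm to avoid
0/0 underflow at strong-repair parameters.  Quadrature (for the continuous
dose-rate form and for test oracles) is adaptive with absolute tolerance
1e−10; closed forms are used everywhere else.  Strong repair can round δ
to exactly 1.0 in double precision; δ values are returned unclamped, with
a `yonezawa_effect = (δ > 0)` flag, and negative values are kept because
they carry calibration information.  A non-fatal warning is emitted when
α₁·D₂ > 10, a heuristic marker of challenge doses outside the model's
stated domain of validity (very large challenges recruit different repair
machinery that the single p_AR form does not describe).

## Estimation

Both estimators minimise the sum of squared residuals between observed and
model δ, in log-parameter space (the α are positive and span orders of
magnitude), inside the bounds α₀ ∈ [1e−6, 1e6] Gy⁻²h⁻³, α₁ ∈ [1e−3, 1e4]
Gy⁻¹, α₂ ∈ [1e−8, 10] h⁻¹ — at least two orders of magnitude around every
estimate obtained from the bundled data.

* **L-BFGS-B multistart**: started from a log-spaced grid (default 5 per
  axis, 125 starts); deterministic.  The lesion-endpoint δ (with each
  record's printed observation time) is used for all lymphocyte records,
  including the aberration rows in the pooled fit, which treats the three
  studies as one meta-dataset; the inversion records use the mutation
  endpoint.
* **Simplified genetic algorithm**: population of 99 triplets,
  fitness-proportional selection with fitness 1/SSR, no crossover, and
  multiplicative log-normal mutation whose scale anneals geometrically
  from 0.5 to 0.01 over the run (the concrete operator and schedule are
  this package's choices).  The incumbent best re-enters each generation
  unperturbed.  Restarts whose final fitness is > 1% below the best
  restart are discarded as stuck; the winner is polished by a local
  brute-force grid.  The config defaults mirror the published budget
  (2×10⁵ generations, 50 restarts); the test suite runs desk-scale budgets
  (≈3×10³ generations, 4–6 restarts), which already land within the
  reported uncertainty ranges on the bundled data.

Uncertainty uses the Poisson worst-case (upper–lower bound) method: each
event count k is shifted by ±√k, coherently in the directions that push
every δ up (challenge-only counts up, combined counts down) and then down,
the two extreme datasets are refitted, and per-parameter offsets that
bracket the central estimate are reported.  The ±1σ coherent-shift
construction is this package's concrete reading of the method; it
reproduces the order of magnitude of the published ranges, which is the
only property asserted.  Frequency-only records without denominators are
rejected.

A 2-record fit (mouse spleen) against 3 parameters is underdetermined: a
manifold of exact optima exists, and only objective-value equivalence with
published parameters is meaningful (a denser, 9-per-axis multistart is
needed to land on the manifold).

The δ-versus-interval trend is ordinary least squares (closed form via
`scipy.stats.linregress`).  On the 16 interval-series lymphocyte records
it gives slope −0.00523 h⁻¹, intercept 0.484, R² 0.607.

## Synthetic data

The generator emulates the bundled experiments' design: for each condition
(D₁, D₂, Δt, T) with a scoring denominator (cells examined, 200–300 in the
emulated design) and baseline challenge-only event frequency (0.29–0.96
per cell, taken from the bundled records), the expected combined-arm
frequency is baseline × (1 − δ_model) at known true α, and the observed
counts are independent Poisson draws — counts are the only noise source;
doses and times are exact, mirroring how the experiments are reported.
Rows whose model δ would reach 1 are refused as degenerate.  What the
generator does *not* emulate: the sharing of a single challenge-only
measurement across table rows in the real studies (real δ values in a
block are correlated), donor-to-donor variability, and any model
misspecification — so recovery results characterise the estimator under
the model, not the model's adequacy.

A consequence worth stating plainly: at this design's noise level
(δ standard error ≈ 0.1, comparable to the real data's residual RMS of
0.095), the amplitude parameters are poorly identified.  The likelihood
has a flat ridge along which α₀ and α₁ rise together (ξ depends on them
only through α₀e^(−α₁D₁), and most design rows share one small D₁); in
roughly a third of noisy replicates the global least-squares optimum sits
far up that ridge — with strictly lower SSR than the truth, so this is a
property of the estimator under noise, not a search failure.  The time
constant α₂ is recovered well (median relative error ≈ 12% over 20
replicates); α₁ scatters at ≈ 24% and α₀ at ≈ 96% median relative error.
Increasing the denominators tenfold shrinks all three errors sharply,
which the tests assert.

## Known limitations

* The model is for pulse schemes with challenge doses of order 2/α₁ to a
  few Gy; very large challenges are outside its validity (warned).
* The lesion/mutation distinction collapses for T ≫ Δt; fits of
  short-observation aberration data under the lesion form inherit the
  pooled-analysis assumption above.
* Parameter uncertainties from 2-to-3-record datasets are not meaningful;
  the package will warn and fit anyway.
* The genetic algorithm at full published budget is slow by design; the
  deterministic multistart reaches the same optima on the bundled data and
  is the default everywhere.
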