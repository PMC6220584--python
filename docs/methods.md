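# Methods

## Stimulus generative model

A trial is a sequence of `n_pulses` (default 7) motion pulses of
`pulse_duration_ms` (default 150 ms; 100 ms supported) shown on a grid of
`n_elements` (default 19) Gabor elements. Pulse `i`'s signed strength is
drawn from `N(mu_k(i), sigma)` with `sigma = 0.15`; `k` indexes five
generating distributions with means `mu_k ∈ {−0.50, −0.10, 0, +0.10,
+0.50}` (sign = direction), sampled per trial from
`trial_type_probabilities` (default uniform). Per-subject ranges seen in
practice (strong means 35–70%, SD 8–24%) are expressed by overriding
`mu_set` and `sigma` in `StimulusConfig`, not hard-coded.

**Discrete-element rounding.** The stimulus is physically composed of
discrete elements, so a drawn strength is realized as a signed integer
element count: `round(strength × n_elements)`, halves away from zero so
the rule is sign-symmetric, clipped to `±n_elements`. Realized strengths
therefore live on the lattice `k / n_elements`. (Rounding to an integer
*percentage* instead would decouple the stimulus from its physical
element count; we flag this as the one place where "rounded to the
nearest integer" admits two readings.)

**Temporal conditions.** In the `flat` condition the generating mean is
constant over pulses. In the `late` condition it rises from exactly 0 at
pulse 1 to exactly `mu_k` at the last pulse along a logistic
`t(i) = 1 / (1 + e^{−(i − m)/s})` with midpoint `m = 4` and scale
`s = 0.3` (pulse-index units), affinely rescaled so the endpoints are met
exactly; the `early` condition is its exact time reverse. The raw
logistic never attains 0 or 1 at the endpoints, so the affine rescaling
is what honors the boundary constraints; a multiplicative-rate
parameterization cannot. The zero-mean distribution is identically zero
in every condition, which is what makes zero-mean trials usable for
classical noise-based reverse correlation.

**Reward.** The rewarded direction is the sign of the realized pulse sum
(computed on integer counts, so an exactly-zero sequence is exact), not
the generating distribution — every pulse is always informative. Trials
whose counts sum to exactly zero are rewarded at random. Frozen-seed
trials reuse one rejection-sampled zero-mean sequence whose counts sum to
zero; they are flagged, bit-identical within a session, and rewarded at
random.

## Model observers

Observers exist to give every estimator a ground truth:

- **Linear observer**: `P(right) = λ_lapse + (1 − 2 λ_lapse) ·
  logistic(kᵀx + b)` — the exact generative inverse of the kernel
  regression.
- **Accumulator**: per pulse, `state ← state·(1 − leak) + gain·x_i +
  noise`; the state is absorbed at `±bound` (later pulses ignored, no
  re-entry); choice = sign of the final state, exact zeros resolved at
  random. The accumulator updates once per pulse rather than in
  continuous time because kernels are estimated at pulse resolution; a
  finer-grained diffusion would be summarized at the same seven points.
  With `bound = ∞, leak = 0, noise = 0` it reduces to the perfect
  integrator and reproduces the uniform-kernel linear observer's choices
  exactly.
- **Extrema detector**: choice = direction of the pulse with the largest
  absolute element count, earliest pulse on magnitude ties, random on an
  all-zero trial.

A tight bound yields early weighting (negative kernel slope), leak yields
late weighting (positive slope); both signatures are monotone in their
parameter over the tested grids.

## Psychometric fitting

`p(x) = γ + (1 − 2γ)/(1 + e^{−β(x−α)})` is fit by maximizing the
Bernoulli log-likelihood. Net strengths are z-scored per subject over all
of that subject's trials (population-SD convention) before fitting, so
`α` and `β` are in standardized units; thresholds are reported in those
units by default. The lapse is optimized on an unbounded scale via
`γ = 0.5·logistic(u)`, which enforces `γ ∈ (0, 0.5)` without box
constraints (unconstrained optimizers otherwise overshoot the boundary).
Three deterministic Nelder–Mead restarts (mild slope, steep slope,
shifted midpoint) guard against local optima. Standard errors are
`sqrt(diag(H⁻¹))` with `H` the central-difference Hessian of the negative
log-likelihood at the optimum in the original `(α, β, γ)`
parameterization. Fits with `|β| > 50` are flagged as (quasi-)separated.
The 75%-correct threshold inverts the fitted curve analytically:
`x₇₅ = α − (1/β)·ln((0.25 − γ)/(0.75 − γ))`, defined only for `γ < 0.25`.

## Kernel estimation

The temporal kernel maximizes the penalized Bernoulli log posterior

    L(w) = Σ_i [Y_i wᵀX_i − log(1 + exp(wᵀX_i))] − λ‖w_pulse‖²

with `X` the trials × (pulses + intercept) design. Two deliberate
choices:

- **Penalty sign.** Adding `+λ‖w‖²` to a log posterior would be an
  anti-prior whose objective is unbounded; the standard penalized
  (subtracted) form is implemented.
- **Unpenalized bias.** The intercept column is excluded from the ridge
  penalty; shrinking it would bias the estimated side preference toward
  zero for no statistical benefit.

The objective is strictly concave for `λ > 0`; a damped (backtracking)
Newton iteration finds the unique optimum, and the solution matches both
a derivative-free optimizer and an independent penalized-logistic
implementation to ≤ 1e−4 per weight.

**Evidence optimization.** The penalty corresponds to a Gaussian prior
`N(0, 1/(2λ))` on each pulse weight with an improper flat prior on the
bias. `λ` is selected on a 25-point log-spaced grid over `[1e−4, 1e4]`
(shrinkage from negligible to total at realistic session sizes) by
maximizing the Laplace approximation to the log marginal likelihood:
log-likelihood at the MAP, plus the log prior, minus half the
log-determinant of the Hessian of the negative log posterior. The grid
maximizer is deterministic given the data; a fixed-point update would
converge to the same neighborhood but introduces iteration-order
sensitivity for no accuracy gain at 7 weights.

Kernels are reported normalized to unit Euclidean norm (bias excluded),
which makes the slope/energy summaries invariant to positive rescaling of
stimulus units and observer sensitivity.

**Whitening check.** Kernels are estimated from all trials; because
logistic regression whitens the stimulus covariance, temporally
correlated signal trials do not bias the kernel shape. The check fits the
kernel on all trials and on zero-mean trials only (≥ 100 required) and
reports the Pearson correlation of the two normalized 7-vectors.

## Summaries, group statistics, controls, QC

- **Slope/energy**: OLS line through (pulse index 1..n, normalized
  weight); energy = `Σ (w_i − w̄)²`. Both computed on normalized kernels.
- **Group tests**: exact two-sided sign test of slopes against zero
  (zeros dropped) — chosen over signed-rank because slope distributions
  are strongly asymmetric by design in the early/late conditions, though
  signed-rank is exposed as an option; one-way ANOVA across conditions;
  pairwise Bartlett tests on variances; Pearson correlations (two-sided
  p) of threshold vs. slope and vs. energy within condition.
- **Consistency control**: inconsistent trials are those whose strongest
  pulse (largest |element count|, earliest on ties) opposes the sign of
  the net strength. Each is matched to an unused consistent trial by
  greedy nearest-neighbor on |net strength| with a maximum distance of
  0.5 lattice steps; unmatched trials are dropped and counted. This
  matcher is simple, deterministic and auditable; optimal (Hungarian)
  matching changes the matched sets negligibly at these tolerances.
  Accuracies carry exact Clopper–Pearson 95% CIs.
- **Session QC**: exclude sessions with < 250 completed trials, with
  < 85% accuracy on trials from the largest-|mu| distributions (both
  signs pooled), or with a 75% threshold more than 2 unscaled median
  absolute deviations from the subject's median (no 1.4826 consistency
  factor; the rule is stated in raw MADs). The MAD rule uses all
  candidate sessions of a subject, needs ≥ 3 of them (otherwise skipped
  with a warning), and is order-independent.

## Validation design and problem sizes

Parameter recovery is the package's primary validation: simulate an
observer with a known kernel, estimate, compare. Recovery tests use
5,000-trial sessions, mechanism-signature and whitening tests 10,000,
psychometric recovery 10,000, the optimizer oracle 200; these sizes keep
the full suite and the acceptance script fast while leaving comfortable
statistical margins.

Two measurement details matter here:

- **Probe sensitivity.** Recovery tests use a high-sensitivity linear
  observer (kernel norm 16, no lapse), whose choices are nearly
  deterministic given the pulses. This isolates estimator fidelity from
  Bernoulli choice noise: with a moderate-sensitivity observer, the
  per-weight sampling error at n = 5,000 is comparable to the
  across-pulse variation of near-flat kernel shapes, and shape
  correlations mostly measure choice noise rather than the estimator.
- **Flat shapes and Pearson r.** Pearson correlation is undefined against
  a constant vector and noise-dominated against near-constant ones, so
  the uniform-kernel recovery test uses cosine similarity of the
  unit-norm kernels (≥ 0.95); non-constant shapes use Pearson r (≥ 0.95).
  The whitening cohort likewise uses a temporally structured observer
  kernel — two estimates of a flat kernel would correlate at chance by
  the same argument.

## What the synthetic data do and do not emulate

The generator reproduces the pulse-level statistics of the task: the
five-Gaussian trial mixture, time-varying mean profiles, element
rounding, zero-mean and frozen-seed trials, and sum-based reward. It does
not render frames (Gabor carrier phase, contrast flicker, spatial
layout), simulate fixation/saccade timing, session-to-session parameter
drift, sequential dependencies, or lapses tied to attention. Passing
recovery tests therefore certifies the estimation chain under the task's
generative statistics; it does not certify that any particular mechanism
describes real subjects, and the model observers are test instruments,
not claims about biology.

## Numerical conventions and degenerate inputs

Seeds are explicit everywhere; the pipeline derives per-stage,
per-session streams from one seed via CRC-named `SeedSequence`
substreams, making reruns byte-identical. Choice coding is 1 = rightward
= positive strength. Ties: exact-zero accumulator states and all-zero
extrema trials resolve uniformly at random; extrema magnitude ties go to
the earliest pulse. Constant strengths cannot be z-scored, one-class
choice vectors cannot be fit, all-zero kernels cannot be normalized, and
a threshold with `γ ≥ 0.25` is undefined — each raises a typed error
rather than returning NaN.

## Known limitations

- The evidence grid bounds `λ` to `[1e−4, 1e4]`; data demanding shrinkage
  outside that range (pathological separation at tiny n) pin at the edge.
- The accumulator has no collapsing bound, urgency, or reaction-time
  output.
- Difficulty matching is greedy in trial order; it does not guarantee the
  globally minimal total match distance.
- Psychometric standard errors are asymptotic (inverse Hessian); at small
  n or `γ` near 0 they can be optimistic, and the `γ` SE is evaluated by
  finite differences near a boundary.
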