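# Methods

## Decision model

An agent decides when to leave a safe place to collect a reward that may
disappear, while the movement exposes it to a threat. Utilities are a gain
G > 0 per collected reward and a loss L < 0 for being punished; both are
assumed known, constant within a trial, and linearly combined. The reward
survives until latency t₁ with probability P_G(t₁) = exp(−λ₁t₁) (exponential
lifetime, rate λ₁). The agent maximises

    Z(t₁, Δt) = P_L(t₁, Δt) · L + P_G(t₁) · G − c(t₁)

where Δt is the planned exposure duration — chosen independently of t₁, so the
optimisation differentiates only in t₁ — and c(t₁) is an optional motor cost
(zero by default).

Two threat models are supported:

* `PoissonThreat` — the objective statistics of the game: a homogeneous
  activation hazard λ₂ that runs only during exposure, giving
  P_L = 1 − exp(−λ₂Δt), constant in t₁. Here ∂Z/∂t₁ < 0 everywhere and the
  maximiser is the interval's left endpoint, returned with a boundary flag.
* `ThreatPrior` — a subjective time-dependent threat probability with value,
  first- and second-derivative contracts. When the prior decays (d1 < 0), the
  expected gain decays, and ∂Z/∂t₁ is positive at the left end of the interval
  and negative at the right end (checked by `verify_assumptions` on a grid), a
  stationary point with a + → − sign change exists and is an interior
  maximiser.

`optimal_latency` scans a dense grid (default 1 ms over [0, 5] s) and refines
the best interior grid point by root-finding on the analytic derivative
(Brent's method between the neighbouring grid points). Among multiple
stationary points the highest expected utility wins; exact ties resolve to the
smaller latency because the scan takes the first argmax. The derivative is
validated against central finite differences at 10⁻⁶ relative tolerance in the
test suite.

Comparative statics: `latency_shift_under_scaling` recomputes the optimum
after L → kL or P_L → min(k·P_L, 1) (a `ScalingError` is raised if the cap
binds inside the searched interval). For an interior optimum under a decaying
prior both scalings delay the optimum; for the Poisson threat — with or
without motor cost — the optimum is unaffected by either, which is the
model-comparison signature the package's analyses target. The motor cost is
parameterised as c(t₁) = c₀·exp(−r·t₁); any decreasing convex cost that is
steep early produces the same qualitative behaviour (interior optimum that
tracks the gain side only).

## The game and its simulator

One epoch offers up to six sequential reward tokens. Token lifetimes are
exponential with mean 1.25 s (λ₁ = 0.8/s); the interval between a token's
disappearance and the next appearance is a carryover of unused presentation
time plus 0.5 s plus an exponential draw with mean 1.25 s, so neither choice
carries an opportunity cost in time. A dormant predator wakes with constant
hazard while the player is outside the safe place; waking removes all tokens
collected in the epoch and ends it. Three threat levels are calibrated so that
a 100 ms exposure is caught with probability 0.1, 0.2 or 0.3, i.e. rates
λ₂ = −ln(1−p)/0.1 s.

Simulator choices:

* **Binned hazard.** Wake-ups are determined independently per 20 ms bin with
  per-bin probability 1 − exp(−λ₂·0.02). Compounding over any whole number of
  bins reproduces the continuous-time probability exactly, so the printed
  design values hold for 100 ms exposures by construction; a fractional
  trailing bin uses the analogous probability for its duration.
* **Exposure only.** Activation while the player is safe self-deactivates, so
  only exposure bins are simulated; this is distributionally identical to
  simulating the full activation process. The whole out-of-safe interval
  counts as exposure, whether or not a token is present.
* **Schedule.** Each subject plays 270 epochs split evenly across the three
  threat levels in randomised order (the schedule is not otherwise
  constrained). A top-level seed fans out to per-subject streams via
  `SeedSequence.spawn`, so adding subjects never reshuffles existing ones.
* **Latency noise.** Realised approach latencies add Gaussian noise (default
  sd 50 ms, truncated at zero) to the planned latency. Within-condition
  variability is not part of the decision model; the noise exists so the
  analysis stage faces realistic dispersion.
* **Direction errors.** An initial wrong left/right response occurs with
  probability 0.028, independent of condition, and is recorded purely as a
  control variable; it does not affect collection.

Agent policies are triples (go/no-go, planned latency, planned exposure). The
decision-theoretic agent plans each movement by maximising Z with the loss set
by a configurable stake function — by default the tokens currently in hand,
optionally the ideal-observer potential loss below — and the threat prior
scaled per level by p_i/p̄ (the level's catch probability relative to the
level average). It goes iff the achieved expected utility is positive. With
nothing at stake the gain side alone drives the plan and the agent moves at
the interval minimum: the early-move regime.

## Behavioural analysis

* **Implicit choices.** Each non-caught epoch expands to six records; record
  s is true iff at least s tokens were collected. Caught epochs are excluded
  (the intended token count cannot be reconstructed), so a full 270-epoch
  session yields at most 1620 choices. No inferential statistics are attached
  to choice data — successive records within an epoch are dependent by
  construction; the package reports condition proportions only.
* **Latency filters.** Only go trials with 150 ms < approach latency < 2 s and
  0 < return latency < 2 s enter latency analyses, and the sixth token is
  dropped (rarely collected; unreliable cells), leaving a 3 × 5 design of
  threat level × potential loss 0–4. Go trials preceding a catch are included
  by default (`include_caught_epochs=False` switches to excluding whole caught
  epochs).
* **Condition means.** Two-stage averages: per subject and cell first, then
  across the subjects contributing to the cell. Empty cells are flagged
  missing and never imputed.
* **Trend test.** Latency ~ threat + loss + threat:loss + (1 | subject), with
  threat level and potential loss as linear numeric contrasts centered at
  their sample means, so the main-effect slopes are average marginal trends
  (see "kinks", below). The single random-intercept variance is profiled by a
  one-dimensional maximum-likelihood search (block-diagonal marginal
  covariance with closed-form inverse per subject); fixed effects follow by
  generalised least squares. F-type statistics use the conservative
  denominator degrees of freedom N − K, K counting all fixed and random
  effects. If the profile search fails, the fit falls back to
  subject-demeaned OLS, flagged in the result. The estimator is cross-checked
  against standard mixed-model software in the test suite; a log-latency
  refit is available as an option. Random-slope models are out of scope; the
  random-intercept specification is primary.

## Ideal observer and prior reconstruction

The stake of a movement exceeds the tokens in hand: getting caught also
forfeits the tokens one would still have collected. The ideal observer
summarises this with, per threat level i, the desired token count D_i (mean
tokens collected on non-caught epochs, averaged within subject first), the
catch probability per movement P_C,i, and the probability P_T of obtaining a
token on an uncaught movement. The potential loss at T tokens in hand is

    L_{i,T} = −D_i (1 − P_C,i)^((D_i − T)/P_T)   for T < D_i,   −T otherwise,

i.e. the expectation of ending with D_i tokens given the remaining
(D_i − T)/P_T exposed movements (an alternative reading, with 1/P_T as a
prefactor instead of in the exponent, is available behind a flag; the
exponent form is the one whose forward model the round-trip test verifies).

The inversion solves the stationarity condition at each observed
condition-mean latency for the time derivative of the level-average prior:

    dP̄_L/dt₁ = −(P̄/P_i) / L_{i,T} · dE(G)/dt₁,    dE(G)/dt₁ = −Gλ₁e^(−λ₁t₁),

where P̄/P_i (mean catch rate over the level's catch rate) is treated as a
constant per level. The derivative points are fit with a first-order
polynomial, clamped at ≤ 0, integrated analytically (the prior is constant
past the clamp root), and the integration constant is set so the prior equals
the average catch rate at the average approach latency. G is fixed at one
token-utility; all losses are in token units, and a common scaling of G and
all losses provably leaves every predicted latency unchanged. Feeding the
fitted prior back through the decision model (threat scaled by P_i/P̄,
loss L_{i,T}, search window [0, 5] s — far wider than the observed latency
range) yields per-condition predicted latencies, with boundary solutions
flagged.

**Self-consistency.** For the forward–inverse round trip to close, the
simulated agent must stake movements by the same accounting the estimator
reads off its behaviour. `self_consistent_experiment` therefore iterates:
simulate with a design-based starting guess of the observer parameters,
re-estimate them from the simulated table, and re-simulate (one pass
suffices; the residual discrepancy is Monte-Carlo noise of the estimates).

**Example prior.** The package's example subjective prior is a clamped
quadratic: derivative −1.2 + 1.5·t per second (zero from 0.8 s on), baseline
0.62 at t = 0, decaying to ≈ 0.14. The derivative parameters were chosen so
that stakes of 1–6 token-utilities put interior optima comfortably inside the
150 ms–2 s response window; the baseline is set so the prior near typical
approach latencies (~0.5 s) matches the average experienced catch rate
(~0.2 per movement under 100 ms exposures) — the consistency condition the
anchoring step of the reconstruction assumes of its data.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis relies on:
sequential tokens with exponential lifetimes, binned exposure hazard at the
design catch probabilities, balanced threat schedules, unbalanced condition
cells arising from behaviour (agents stop collecting at high stakes, and are
caught more at high threat), latency dispersion, and direction errors. It does
not emulate learning or adaptation across epochs (the decision model is static
per movement), within-subject parameter heterogeneity beyond the random
intercept, kinked or non-quadratic priors, sequential dependencies in
motivation, or motor kinematics. Passing the round-trip and sign-recovery
tests therefore demonstrates internal consistency of model, simulator,
analysis and inversion — not that human players use these priors.

One empirical subtlety the synthetic agents do reproduce: under the full
ideal-observer accounting, higher threat lowers the desired token count and
hence the stake at low potential loss, which can flatten or invert the raw
threat effect in the zero-loss cell even though the pure loss-probability
effect is monotone. The trend test's centered coding reports average marginal
slopes for this reason, and the monotonicity tests isolate the scaling effect
by holding the observer quantities level-constant.

## Numerical choices and degenerate inputs

* Grid resolution 1 ms; derivative root refinement by Brent's method between
  grid neighbours; boundary maximisers returned flagged, never raised.
* Prior values are clipped to [0, 1]; the derivative contract reports zero in
  clipped or clamped regions. `fit_prior` warns if the anchoring constant
  falls outside [0, 1] and raises if the fitted derivative line is
  non-negative across all observed latencies.
* Conditions with zero potential loss are skipped (with a warning) in the
  inversion; cells under a configurable minimum observation count are
  excluded from the derivative fit.
* An agent that never moves produces a complete choice table and an empty
  latency table; the pipeline skips the trend and reconstruction stages with
  warnings and exits cleanly. A threat level with no go movements at all
  raises an estimation error.
* Default problem sizes (270 epochs, 6–8 subjects in tests and examples) keep
  every Monte-Carlo estimate's standard error well inside the asserted
  tolerances while the full suite runs in well under a minute.

## Known limitations

* The mixed-model estimator fits a single variance component by maximum
  likelihood (not REML); with few subjects the intercept variance is slightly
  shrunk. The conservative N − K denominator makes the reported p-values
  conservative in compensation.
* The inversion assumes the gain prior is perfectly known and utilities are
  linear; misspecifying λ₁ biases the reconstructed derivative
  multiplicatively.
* The reconstructed prior is a group-level object; no subject-specific priors
  are attempted.
* The L_{i,T} exponent convention is a modelling choice between two readings;
  both are implemented, and only the default is covered by the round-trip
  guarantee.
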