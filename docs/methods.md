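# Methods

## Estimand and estimator

The estimand is the area under a concentration–time curve over the fixed
observation window [0, 24] h, `AUC(θ) = ∫₀²⁴ C(t, θ) dt`, where θ collects
the free PK parameters of one of five registered models.  The estimator
class is the linear-combination (LC) quadrature `Q̂ = Σ wᵢ Ĉ(tᵢ)` applied
to measured concentrations.  Measurements carry independent zero-mean
noise with standard deviation proportional to the true concentration
(constant coefficient of variation cᵥ); only the first two noise moments
enter any formula, so no distributional assumption is made outside the
simulator.

With `S(θ) = Σ wᵢ C(tᵢ, θ)` the estimator's mean is S, its variance is
`cᵥ² Σ wᵢ² C(tᵢ, θ)²`, and the relative risk (expected squared relative
error) is

    R_r(θ) = [ cᵥ² Σ wᵢ² Cᵢ² + (AUC − S)² ] / AUC² .

The design criterion is minimax: choose the knots (and, for free LC rules,
the weights) minimizing `max_{θ∈Θ} R_r(θ)` over a parameter box Θ.
Relative rather than absolute loss is used throughout: AUC spans a ~5-fold
range over the boxes, bioequivalence works on ratios, and the relative
risk is invariant under rescaling of the concentration unit (verified in
the tests).

## The five models

| id | model | free parameters | fixed |
|----|-------|-----------------|-------|
| 1 | 1-compartment, first-order absorption, single dose | kₐ, kₑ | A = 20 |
| 2 | same, steady state (τ = 24 h) | kₐ, kₑ | A = 20 |
| 3 | biexponential iv bolus | k₁, k₂, α = A₂/A₁ | A₁ = 10 |
| 4 | iv bolus, Michaelis–Menten elimination | K_M, V_m | C₀ = 10 |
| 5 | first-order input, Michaelis–Menten elimination | K_M, V_m, kₐ | A = 5 |

Parameter boxes are the published ranges.  Two box conventions needed a
decision:

* **A is taken as the amplitude itself** (A = 20, A = 5), not as the
  composite F·D/V_d it abbreviates.  This reproduces the printed AUC
  maxima (250, 337) exactly.
* **Models 1–2 additionally impose kₐ ≥ 2 kₑ.**  The raw rectangle allows
  kₐ = kₑ (the flip-flop degeneracy), where the single-dose amplitude
  blows up and the AUC of the normalized curve collapses toward zero,
  contradicting the printed minima (56, 58).  With the constraint, the
  minima sit exactly at the corner kₑ = ln2/4, kₐ = 2kₑ.  The constraint is
  exposed as a configurable option (`constrain_absorption`, or a
  `constraints:` list in the YAML config) rather than hard-wired.
* Model 3's k₂ range is stored in ascending order [ln2/24, ln2/4].  Its
  printed AUC minimum (50) is *not* reproducible from the stated closed
  form — the constrained corner gives ≈47.8 — and is therefore documented
  as a discrepancy, not chased with an invented constraint.

Closed forms: models 1–3 have explicit C(t) and AUC with hand-derived
gradients and Hessians.  Model 4's time course satisfies the implicit
relation `K_M ln(C/C₀) + (C − C₀) = −V_m t`; it is solved by a 90-step
safeguarded bisection (vectorized over grids), its AUC comes from the
exact identity `AUC = [K_M(C₀ − C_T) + (C₀² − C_T²)/2] / V_m`, and first
derivatives follow from the implicit-function theorem.  An independent
ODE route exists for cross-checks.  Model 5 has no closed form: it is
integrated with LSODA, the state augmented with the forward sensitivities
∂C/∂p, the running integral and its derivatives (8 states).  Second
derivatives for models 4–5 are central differences of the analytic
gradients (relative step 3e−6).  ODE tolerances: rtol 1e−10 / atol 1e−12
for reference evaluations, 1e−8 / 1e−10 inside optimizer loops.  Batch
(Monte-Carlo) evaluation of model 5 stacks up to 4096 profiles into one
vectorized ODE system so one adaptive integration serves the whole batch.

## Quadratures

* Trapezoid weights: w₁ = (t₂−t₁)/2, interior wᵢ = (tᵢ₊₁−tᵢ₋₁)/2,
  wₙ = (tₙ−tₙ₋₁)/2; they telescope to tₙ − t₁.  Trapezoid designs pin the
  last knot at t = 24.
* For models with C(0) > 0 (2, 3, 4) the first panel can be extended to
  t = 0 by linear extrapolation through the first two samples.  The
  extrapolated area is itself linear in C(t₁), C(t₂), so the adjustment is
  a pair of weight increments Δw₁ = t₁ + t₁²/(2(t₂−t₁)),
  Δw₂ = −t₁²/(2(t₂−t₁)) and the rule stays in the LC class.  The
  extrapolated point does not count toward n (it is not a sample).
* Gauss–Legendre nodes/weights come from `numpy.polynomial.legendre`,
  affinely mapped to [0, 24] (exact to degree 2n−1); Clenshaw–Curtis is
  the classical closed rule on Chebyshev extrema (exact to degree n−1).
  Exactness is verified against monomial integrals for n ≤ 8.
* **n counts knots** (measured concentrations) in every table and API.
  The published trapezoid rows appear to follow the other convention
  (n+1 samples): exhaustive scanning shows the printed n = 2 trapezoid
  objectives are unattainable with two samples but easily attained with
  three.  Exposing the knot count directly lets either reading be tested.
* A minimum knot separation of 1e−6 h is enforced during optimization;
  weights are unconstrained reals.

## Inner maximization (worst case over θ)

`max_risk` maximizes R_r over the box with multistart second-order ascent:
starting points are all feasible box corners, a scrambled-Sobol interior
set (seeded, default 16), and the top points of a dense vectorized
evaluation grid (default 60 per axis for 2-parameter models, 22 for
3-parameter closed forms, 9 for the ODE model).  Candidates are ranked by
risk and the best few are polished with scipy's trust-region constrained
minimizer using the analytic gradient and (for models 1–3) Hessian of R_r,
assembled from the model sensitivities by the chain rule; models 4–5 use a
BFGS Hessian.  The returned value is never below the grid maximum, and the
stored objective is the risk recomputed exactly at the returned maximizer.
On 2-parameter models the result matches a 200×200 brute-force scan to
1e−4 relative (test-enforced).

## Outer minimization (design search)

The max-function's design gradient exists almost everywhere and equals the
design-gradient of R_r at the maximizer (envelope/Danskin property); it is
implemented and finite-difference-verified as `outer_gradient`, with
trapezoid designs chaining through the analytic knot-Jacobian of the
weight formulas.  Plain SQP on the envelope gradient is fragile exactly
where minimax solutions live — at designs where the active maximizer
jumps — so the production search uses a **working-set SQP** instead: keep
a finite set {θⱼ} of worst-case candidates, solve the smooth epigraph
subproblem

    min over (design, s) of s   subject to  R_r(design, θⱼ) ≤ s,  design constraints,

(SLSQP, analytic design gradients, risk scaled by the incumbent objective
so cᵥ = 0 problems stay well-conditioned), then verify the new design with
the full inner maximizer and append its maximizer to the set.  The loop
declares convergence when the verified maximum is within the relative
`outer_tolerance` (default 1e−8, with an absolute floor of 1e−13 on the
squared-risk gap — the double-precision noise floor).  The best verified
design over all rounds and starts is returned, and is finally re-verified
at high grid resolution on the tight-tolerance model.

Outer multistart: 8 structured initial designs (equispaced, geometric,
endpoint-anchored and jittered schedules for the trapezoid; GL, CC,
equispaced-trapezoid and a cheap optimal-trapezoid run for LC, each also
paired with minimax-refined weights).  For fixed knots the worst-case risk
is a pointwise maximum of convex quadratics in the weights, so the
weight subproblem is convex: with cᵥ = 0 it is a Chebyshev approximation
problem solved exactly as a linear program over a dense θ-grid; with
cᵥ > 0 an epigraph SQP over the grid's worst points with one
cutting-plane pass (`best_weights`).  The refined weights both seed the
joint search and polish its result.  Because the classical rules and the
optimal trapezoid are among the starts and the best evaluated design wins,
the optimal LC objective can never exceed GL, CC, or the optimal trapezoid
for the same cell.

Everything is deterministic given `OptimizerSettings.seed`; reruns are
bit-identical.  Ties among equal inner maximizers are broken by fixed
evaluation order.

## Monte-Carlo evaluation

Profiles draw θ uniformly over the feasible box (rejection sampling for
the kₐ ≥ 2 kₑ constraint) and apply independent Gaussian noise
`C·(1 + cᵥ z)` at each knot.  Parameter and noise draws use separate
seeded child streams, so extending the profile count with the same seed
yields a superset sample (making the extreme statistics monotone).
Negative simulated measurements are retained — truncation would break the
zero-mean assumption under the moment formulas.  Reported statistics:
bias on the absolute scale `mean(Q̂ − AUC)`, RMSRE, and the signed
absolute/relative deviances of largest magnitude (plus the most negative
counterparts).  Two consistency bounds tie simulation to optimization:
`RMSRE < √Obj` always (a box-mean cannot exceed the box-max), and with
cᵥ = 0 the extreme relative deviance cannot exceed √Obj unless the inner
maximization failed; with noise that second bound can legitimately
reverse and is reported "not applicable".

The default profile count is 20,000; the test suite and example runs use
2,000, which leaves the two bounds easy to meet while keeping Monte-Carlo
noise around 2% on RMSRE.

What the simulator does *not* emulate: real assay error is rarely exactly
constant-CV (limits of quantification, heavier tails), real θ populations
are log-normal-ish rather than uniform, and model misspecification is out
of scope — passing tests certify the estimator theory and the optimizer,
not robustness to a wrong model.

## Numerical edge cases

* The flip-flop boundary kₐ = kₑ is excluded by the box constraint; the
  degenerate limit formula is deliberately not implemented.
* `auc_range` is deterministic: dense grid (100 per axis for 2-parameter
  boxes, 40 for 3-parameter; 200 in the acceptance script) plus SLSQP
  polish from the extreme grid points, constraints respected.
* Implicit/ODE failures raise `IntegrationError` carrying the model id and
  θ.
* Degenerate (point) boxes are supported throughout and reduce to
  single-θ risk evaluation.

## Known limitations

* No global-optimality certificate: the outer problem is nonconvex and
  multistart + working-set convergence is heuristic, though it matched or
  beat every published objective checked.
* The ODE model makes dense design searches expensive; default grid
  densities for model 5 are deliberately coarse, and design searches on it
  should use generous `OptimizerSettings.max_iterations` when accuracy
  matters.
* Only quadratic absolute/relative losses and LC rules are covered;
  log-trapezoid and other nonlinear rules, infinite-interval AUC, and
  Bayesian (average-risk) designs are out of scope.
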