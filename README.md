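# aucquad

Minimax-optimal sampling designs for estimating the area under a
pharmacokinetic concentration–time curve (AUC) from a handful of noisy
blood samples.

## The problem

In PK and toxicokinetic studies the AUC over a finite window,
`AUC(θ) = ∫₀²⁴ C(t, θ) dt`, is the central exposure measure
(clearance, bioequivalence), but each measured concentration costs a blood
draw, so limited-sampling designs with n = 2–6 samples are common.  Any
linear-combination (LC) quadrature

```
Q̂ = Σᵢ wᵢ Ĉ(tᵢ),    Ĉ(tᵢ) = C(tᵢ, θ)(1 + cᵥ εᵢ)
```

— trapezoid, Gauss–Legendre (GL), Clenshaw–Curtis (CC), or free
knots-and-weights — turns those samples into an AUC estimate.  Under
zero-mean measurement noise with a constant coefficient of variation
(σᵢ = cᵥ C(tᵢ, θ)), the relative risk of the rule at parameters θ is

```
R_r(θ) = { cᵥ² Σᵢ wᵢ² C(tᵢ,θ)²  +  [AUC(θ) − Σᵢ wᵢ C(tᵢ,θ)]² } / AUC(θ)²
```

(estimator variance plus squared bias, scaled by the true AUC).  The PK
parameters θ are never known exactly — only a plausible box Θ is.  The
package solves the minimax design problem

```
min over knots t (and weights w)   of   max over θ ∈ Θ   of   R_r(θ)
```

for five standard models: one-compartment first-order absorption (single
dose and steady state), a biexponential iv bolus, an iv bolus with
Michaelis–Menten elimination, and first-order absorption with
Michaelis–Menten elimination.  The nonlinear models are handled through an
implicit time course (bolus) and forward-sensitivity ODE integration
(first-order input).

## Worked example

```
$ aucquad auc-range --model 1
model 1: AUC range [55.9185, 250.0671] (printed as [56, 250])

$ aucquad optimize --model 1 --n 6 --cv 0 --method gl --seed 1 --out gl6.json
gl design for model 1, n=6, cv=0.0: sqrt(objective) = 1.899E-02 -> gl6.json

$ aucquad evaluate --design gl6.json --profiles 2000 --seed 7
 model  n        cv method  sqrt_objective      bias     rmsre  max_deviance  max_rel_deviance ...
     1  6 0.000E+00     gl       1.899E-02 6.269E-01 6.122E-03     1.973E+00         1.833E-02
  rmsre_lt_sqrt_obj: True
  max_rel_deviance_le_sqrt_obj: True
```

The first command scans the model-1 parameter box (kₐ ∈ [ln2/4, 3 ln2],
kₑ ∈ [ln2/12, ln2/4], kₐ ≥ 2 kₑ) and reports the attainable AUC extremes.
The second computes the worst-case relative risk of a 6-point
Gauss–Legendre rule with no measurement noise: √Obj = 1.899E−2 means the
rule's relative quadrature error can reach 1.9% somewhere in the box.  The
third simulates 2,000 random noise-free profiles: the observed RMSRE
(6.1E−3) and extreme relative deviance (1.83E−2) both stay below √Obj, as
theory requires for a correctly solved inner maximization.

A free minimax-optimal LC rule does far better at the same cost —
`aucquad optimize --model 1 --n 6 --cv 0 --method lc --seed 1 --out lc6.json`
reaches √Obj ≈ 6E−7 here, several orders of magnitude below any classical
rule with six samples.  `aucquad tables` reproduces the full
model × n × cᵥ comparison grid as CSV.

From Python:

```python
import aucquad as aq

model, box = aq.get_model(1), aq.default_box(1)
res = aq.optimize_lc(model, box, aq.NoiseModel(cv=0.05), n=4,
                     settings=aq.OptimizerSettings(seed=1))
print(res.sqrt_objective, res.quadrature.knots, res.quadrature.weights)
```

## Layout

- `aucquad.pk_models` — the five models, exact AUC, analytic/sensitivity
  derivatives, parameter boxes, AUC-range search
- `aucquad.quadrature` — LC rules: trapezoid (+ extrapolation to t = 0),
  GL, CC, design-file serialization
- `aucquad.risk` — moments and risk of an LC estimator under constant-CV
  noise, with θ-gradients and Hessians
- `aucquad.minimax` — inner worst-case search and outer design
  optimization (trapezoid schedules and free LC rules)
- `aucquad.evaluation` — Monte-Carlo profile simulation, summary
  statistics, consistency checks
- `aucquad.cli` — the `aucquad` command

See `docs/methods.md` for the modelling and numerical choices.
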