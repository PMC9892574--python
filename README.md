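# rebicop

**Recursive bivariate copula regression with an endogenous binary treatment.**

`rebicop` estimates the effect of a binary treatment on a binary outcome when
both may be driven by common unobservables — the textbook case being obesity
and chronic disease in health-survey data. Ordinary regression of disease on
obesity is confounded: unmeasured lifestyle and genetic factors push both.
`rebicop` handles this with a two-equation latent-variable system estimated
jointly, for epidemiologists, health economists and biostatisticians who need
a treatment effect rather than an association.

## The model

For individual *i*, with treatment y₁ and outcome y₂:

```
y₁ᵢ* = η₁ᵢ(x₁ᵢ) + ε₁ᵢ             y₁ᵢ = 1{y₁ᵢ* > 0}
y₂ᵢ* = γ·y₁ᵢ + η₂ᵢ(x₂ᵢ) + ε₂ᵢ     y₂ᵢ = 1{y₂ᵢ* > 0}
```

* each ηᵥ is an **additive predictor**: intercept + dummy-coded categorical
  terms + smooth functions of continuous covariates, each smooth a penalized
  B-spline (P-spline) with a sum-to-zero constraint;
* the treatment equation contains an **instrument** (a covariate excluded
  from the outcome equation), supporting identification of γ;
* the joint distribution of the two margins is a **parametric copula**
  `P(y₁=1, y₂=1) = C_θ(P(y₁=1), P(y₂=1))` from one of six families —
  Ali–Mikhail–Haq (`AMH`), Farlie–Gumbel–Morgenstern (`FGM`), Plackett
  (`PL`), Frank (`F`), Gaussian (`N`), Student-t (`T`) — with logit, probit
  or cloglog margins;
* dependence is summarised by **Kendall's τ**; a non-zero τ is the signature
  of endogeneity.

Estimation maximises the penalized log-likelihood
ℓ_p(φ) = ℓ(φ) − ½ φᵀΛ(λ)φ over coefficients φ = (φ₁, γ, φ₂, θ\*) with
automatic multiple smoothing-parameter selection; inference uses the
large-sample posterior φ ~ N(φ̂, H_p⁻¹), so intervals for nonlinear
functionals come from posterior simulation. The headline functional is the
**sample average treatment effect**

```
SATE = (1/n) Σᵢ [ P(y₂ᵢ=1 | do y₁ᵢ=1) − P(y₂ᵢ=1 | do y₁ᵢ=0) ]
```

— the average change in outcome probability if the treatment were switched
on versus off for everyone, covariates held fixed.

## Worked example

```python
import warnings; warnings.simplefilter("ignore", RuntimeWarning)
from rebicop import (simple_config, generate, model_spec_for, fit,
                     tau_interval, sate_interval)

cfg = simple_config(n=5000, seed=42, family="N", tau=-0.30, gamma=1.0)
ds  = generate(cfg)                      # data + ground truth
fitted = fit(model_spec_for(cfg, num_basis=8), ds.data)
ti = tau_interval(fitted, n_draws=1000, seed=1)
si = sate_interval(fitted, ds.data, n_draws=1000, seed=2)
print(f"gamma = {fitted.gamma:.2f}")
print(f"tau   = {ti.tau:.3f}  ({ti.lower:.3f}, {ti.upper:.3f})")
print(f"SATE  = {si.percent:.1f}%  ({100*si.lower:.1f}%, {100*si.upper:.1f}%)")
print(f"truth: gamma = 1.0, tau = -0.300, SATE = {100*ds.truth['true_sate']:.1f}%")
```

prints

```
gamma = 0.76
tau   = -0.199  (-0.331, -0.036)
SATE  = 22.9%  (11.8%, 34.8%)
truth: gamma = 1.0, tau = -0.300, SATE = 31.1%
```

On this draw the point estimates sit below the generating values (γ and τ
trade off — the instrument is rare, so the dependence is weakly identified at
n = 5000) but the 95% intervals behave as designed: across many replicates
they cover γ = 1, τ = −0.30 and the true SATE at close to the nominal rate
(the test suite measures this). A negative τ with a positive γ is exactly
the constellation where a naive independence model would misattribute part
of the error dependence to the treatment.

The `examples/` directory has one short script per capability: a copula
tour, simulate-and-fit, the model-comparison grid, the BMI-threshold
robustness harness, smooth-function export, and a recovery simulation.
A thin CLI mirrors the workflows: `rebicop simulate|fit|grid|robustness|
export-smooths --help`.

## What is (and is not) here

Six copula families with exact sampling and analytic scores; probit, logit
and cloglog margins; P-spline additive predictors with Fellner–Schall
smoothing selection; EDF/AIC/BIC; posterior-simulation intervals for τ and
SATE; a calibrated synthetic-data generator with BMI threshold/exclusion
utilities. Out of scope: rotated copulas, Spearman's ρ, continuous or
survival margins, trivariate systems, population (rather than sample)
average effects, survey weights.
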