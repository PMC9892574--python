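# Methods

## Model

Two binary responses are generated by latent-variable equations: a treatment
equation `y1* = eta1(x1) + e1` and an outcome equation
`y2* = gamma*y1 + eta2(x2) + e2`, with `y_j = 1{y_j* > 0}` and the observed
treatment entering the outcome equation (recursive structure). Each additive
predictor is an intercept plus dummy-coded categorical terms plus penalized
B-spline smooths of continuous covariates. The treatment equation contains an
instrument — a covariate with a nonzero treatment-equation coefficient that is
excluded from the outcome equation. The margins are Bernoulli with success
probability `P(y_j = 1) = G_j(eta_j)` where `G` is the probit, logit or
cloglog mean function; the joint law is completed by a one-parameter copula
on the two marginal success probabilities,

```
p11 = C_theta(P1, P2),  p10 = P1 - p11,  p01 = P2 - p11,
p00 = 1 - P1 - P2 + p11 ,
```

with `P2` evaluated at the observed treatment. The log-likelihood is the sum
of indicator-weighted log cell probabilities. Dependence is reported as
Kendall's tau; `tau != 0` means the unobservables driving treatment and
outcome are associated, i.e. the treatment is endogenous, and the copula
absorbs that association so that `gamma` retains a structural reading.

Assumptions worth stating plainly: a correctly specified copula family and
margins; the exclusion restriction for the instrument; a treatment effect
that is homogeneous on the latent scale (heterogeneity on the probability
scale arises through the nonlinear link); independent observations.

## Copula families

Six families are implemented (codes "AMH", "FGM", "PL", "F", "N", "T"), each
with CDF, analytic partial derivatives (conditional CDFs), the derivative in
theta, the theta <-> tau maps, exact sampling and an unconstrained link for
optimization (`tanh` for the [-1,1] families, `log` for Plackett, identity
for Frank). Numerical specifics:

* **Gaussian**: bivariate normal CDF assembled from Owen's T function
  (deterministic, vectorized); `dC/dtheta` is the bivariate normal density.
* **Student-t**: the CDF uses the exact conditional representation
  `C(u,v) = ∫ f_z(x) F_{z+1}(g(x)) dx` integrated by a fixed 16-node
  Gauss–Legendre rule in a compactified coordinate `psi = arctan(x/c)`,
  `c = min(sqrt(z), 4)`, with a squared endpoint map absorbing the boundary
  cusp of the heavy-tailed weight; the rule converges by ~8 nodes (checked
  against adaptive 2-D integration of the density, agreement ~2e-8). The
  `du`, `dv` and `dtheta` derivatives are the exact derivatives of the same
  fixed rule, so the likelihood score is consistent with the implemented
  CDF to rounding error. For integer degrees of freedom the inner t CDF is
  evaluated by the elementary cosine-power reduction (exact); non-integer
  degrees of freedom use a cubic-spline tabulation (~1e-10). The degrees of
  freedom are fixed, default `zeta = 3`, exposed as a setting.
* **Frank**: Debye function `D1` by adaptive quadrature with a series guard
  near zero; `|theta| < 1e-6` evaluated by the independence-limit expansion
  `C = uv(1 + theta(1-u)(1-v)/2)` so the score is smooth through zero.
* **Plackett**: closed-form CDF with the expansion
  `C = uv(1 + (theta-1)(1-u)(1-v))` for `|theta - 1| < 1e-6`; Kendall's tau
  has no closed form and is computed as `4∬ C c du dv − 1` by 64-node
  Gauss–Legendre product quadrature with the analytic density.
* **AMH**: closed forms throughout; the tau expression is an indeterminate
  form at `theta = 0` and is evaluated by its series `2θ/9 + θ²/18` for
  `|theta| < 1e-4`. Attainable tau is only about [-0.182, 1/3].
* **FGM**: closed forms; attainable tau limited to [-2/9, 2/9].

Sampling uses the latent elliptical representation for Gaussian/Student-t
and conditional inversion by 60-step vectorized bisection for the others.
`tau_to_theta` inverts by closed form where available, otherwise monotone
root-finding (Brent); probabilities are clipped to [1e-12, 1-1e-12] inside
partials and likelihood terms for stability.

## Smooths and design matrices

Smooths are cubic B-splines by default with J = 10 basis functions and a
second-order difference penalty (P-spline convention); J is exposed per
term. Knots: interior knots at covariate quantiles (robust to skewed
covariates such as income), boundary knots repeated at the data min/max,
with an equidistant fallback when quantiles collide on discrete covariates.
Identifiability: each smooth block is reparameterized onto the orthogonal
complement of its column-sum vector (QR-based), dropping one coefficient and
making the smooth average exactly zero over the training data. Two
consequences are documented rather than hidden: with quantile knots the
difference-penalty null space is only approximately a linear-in-x function,
and the clamped boundary knots leave a small edge curvature in the
infinite-smoothing limit (the stiff limit has one effective degree of
freedom but is "near-linear", not exactly linear, at the edges).

Categorical covariates are dummy-coded against their first level (declare
the reference by category order). Column ordering is deterministic:
intercept, parametric terms in declared order (the treatment indicator first
in the outcome equation), then smooth blocks.

## Estimation

The coefficient vector is `phi = (phi1 | phi2 with gamma | theta*)`, with
`theta*` the unconstrained dependence parameter, estimated jointly (not
two-step) and unpenalized. The penalized log-likelihood is
`l_p = l - 0.5 phi' Lambda(lambda) phi`, where `Lambda` carries one block
`lambda_k D_k` per smooth and zero blocks for the intercept, parametric
terms, `gamma` and `theta*`.

* **Initialisation**: two univariate penalized binary fits (treatment
  margin; outcome margin including the observed treatment), dependence
  started at independence.
* **Inner optimisation**: L-BFGS with the analytic score (one fused
  value-and-gradient evaluation), then damped Newton polishing steps using a
  finite-difference Hessian of the analytic gradient until the score
  max-norm is below 1e-6. An FD Hessian of an exact gradient is accurate to
  ~1e-7 and avoids deriving second derivatives of six copula families; at
  the optimum it also supplies the penalized Hessian `H_p` for inference.
* **Smoothing selection**: an outer loop of generalized Fellner–Schall
  updates `lambda_k <- [rank_k/lambda_k - tr(H_p^{-1} S_k)] / (phi' S_k phi)`
  with a half-step in log space (the undamped update oscillates around its
  fixed point), forward-difference curvature inside the loop, convergence
  when the proposed change is below 0.2 in log-lambda, at most 8 sweeps.
  Lambdas are clamped to [1e-4, 1e7].
* **EDF / model choice**: `EDF = tr(H_p^{-1} H)` with `H` the unpenalized
  curvature, summed per smooth block; "Ref.DF" is the block dimension after
  centering (J-1). `AIC = -2 l + 2 EDF`, `BIC = -2 l + log(n) EDF`.
* **Inference**: `phi ~ N(phi_hat, H_p^{-1})`. Standard errors, z- and
  p-values for parametric terms come from the `H_p^{-1}` diagonal; intervals
  for Kendall's tau and the SATE are equal-tailed empirical quantiles over
  posterior draws (default 1000 draws, 95%), mapping each draw of `theta*`
  through the family link and the tau conversion. These intervals need not
  be symmetric. A fit can also be run with the dependence frozen
  (`fix_theta`), e.g. to force independence.

The SATE is implemented as the intervention contrast: the outcome design is
evaluated twice with the treatment column set to 1 and to 0 for everyone
(covariates fixed) and the mean probability difference taken. The
conditional-on-observed-treatment reading would reintroduce the selection
the model exists to remove.

## Synthetic data generator

The generator emulates an adult health-survey extract: age uniform on
[18, 64], education in years (rounded normal, mean 12.7), log-normal income,
binary gender/private-insurance/physical-limitation, 4-level race and
region, 5-level self-rated health; the physical-limitation indicator is the
instrument (treatment equation only). Default coefficients give treatment
prevalence ~29.5% and outcome prevalence ~25%, and the continuous BMI is a
monotone transform of the treatment-equation latent index,
`BMI = 30 exp(0.2 * latent)`, so that thresholding at 30 reproduces the
binary treatment exactly and the BMI distribution has mean ~27 and SD ~6.3.
Default smooth shapes: age rises then plateaus (treatment) / near-linear
rise (outcome); education declines after 12 years; income declines in logs —
illustrative shapes, not estimates. An optional multiplicative measurement
error on BMI lets one demonstrate how error in the treatment scale induces
negative error dependence.

Sampling convention: a copula pair `(v1, v2)` is drawn and `y_j = 1{v_j <=
P(y_j=1)}` with the outcome margin using the realized treatment. This makes
the generated four-cell law identical to the likelihood's `C(P1, P2)`
decomposition for every family including the radially asymmetric AMH (for
the five radially symmetric families it coincides with the
`e_j = F_j^{-1}(v_j)` latent reading). The recorded ground truth includes
the plug-in true SATE on the generated sample.

What the generator does not emulate: survey weights and design effects,
panel structure, item nonresponse, real covariate dependence (covariates are
drawn independently), and misspecified-link scenarios. Passing recovery
tests therefore demonstrates internal consistency of estimation and
intervals under the model, not robustness to real-data violations — except
where the robustness harness deliberately misspecifies the treatment
definition.

## Study designs used by the checks

Simulation sizes were chosen as the package's own desk-scale defaults. The
recovery study uses a reduced design (one smooth and two parametric terms
per equation, J = 8) at n = 5000 with gamma = 1 and tau in {-0.3, 0, 0.3}
where attainable, 20 replicates per cell in the test suite; coverage of the
95% intervals for gamma and SATE and the median |tau_hat - tau| are pooled
over all replicates. With a survey-realistic rare instrument (8% prevalence)
the dependence parameter is weakly identified, so tau_hat has substantial
replicate-to-replicate spread; pooled coverage sits near nominal, while the
pooled median absolute tau error sits essentially on 0.05 — the largest
replicate errors are gamma <-> theta trade-offs along the weak-identification
ridge, with the fits themselves converged. The
robustness harness refits under BMI thresholds {30, 32.5, 35, 37.5, 40,
42.45} and the BMI < 18.5 exclusion at n = 10^4; scenarios that leave a
degenerate treatment arm are skipped with a warning.

## Known limitations

* No analytic Hessian: curvature is finite-differenced from the analytic
  score (cost `2p` score evaluations; accuracy ~1e-7 relative).
* Fellner–Schall selection is a REML-flavoured criterion; an explicit
  AIC-grid search over lambda would be costlier and was not needed for the
  calibration targets here.
* The Frank link is the identity with evaluation clamped to |theta| <= 35
  (tau ~ 0.89); fits needing stronger Frank dependence would hit the clamp.
* Student-t degrees of freedom are fixed, not estimated.
* Quantile knots + difference penalties: the large-lambda limit is only
  approximately linear (see above).
* The posterior is a Gaussian approximation at the penalized optimum; in
  small samples or near boundary dependence it can be poorly calibrated, and
  SATE interval widths at n = 1000 are visibly wider than the root-n
  extrapolation from larger n.
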