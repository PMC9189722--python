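# Methods

This note documents the statistical model, the estimators, the synthetic
case studies, and the numerical and design choices behind `survoi`, in the
spirit of a package vignette. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Decision problem

Two treatment arms, analysed independently. The payoff (net benefit) of arm
*d* is its restricted mean survival time (RMST) over a fixed horizon
*t_h* = 240 months: the area under the survivor curve, in life-months. The
decision maker picks the arm with the larger expected RMST; the value of
further data is the expected improvement in that choice.

## Survival families and the transformed scale

Four two-parameter families are supported. Natural parameterisations:
Weibull (shape k, scale λ, S(t) = exp(−(t/λ)^k)); Gamma (shape α, rate β);
log-normal (sdlog σ, meanlog μ); log-logistic (shape a, scale b,
S(t) = 1/(1 + (t/b)^a)). These conventions match the `flexsurv` R package,
which makes fits directly comparable with the wider literature.

All inference happens on a transformed scale where every
positivity-constrained parameter is log-transformed and the log-normal μ —
already unconstrained — is left alone. A bivariate normal is then a
reasonable belief distribution: mean at the MLE, covariance the inverse
observed information (central finite differences of the log-likelihood,
step 1e−5). On the increasing-hazard case study this covariance agrees with
`flexsurvreg` output to five decimals.

Likelihood: events contribute log f, administratively censored rows log S,
and rows with entry time e > 0 (patients already alive at the interim
cut-off) are left-truncated — their terms are divided by S(e). Truncation,
unlike censoring, adds no data point: it conditions the distribution, which
is exactly what avoids double-counting the interim data when evaluating
simulated follow-up.

Numerics: scalar RMST uses adaptive quadrature (absolute tolerance 1e−8);
vectorised RMST over thousands of parameter draws uses 160-node
Gauss–Legendre quadrature on the substitution t = t_h·u², which removes the
infinite slope of S at zero for shapes below 1 (agreement with the adaptive
route ≈1e−9 relative; tested). Truncated sampling is inverse-CDF:
T = S⁻¹(v·S(t₁)) with v uniform — exact, dimension-free, and vectorised
across draws.

## Model weights

Prior model probabilities after the interim data are Akaike weights,
`P(M_r|x) ∝ exp(−AIC_r/2)`, computed with max-subtraction for overflow
safety. Posterior model probabilities given a simulated follow-up dataset
multiply these by the marginal likelihood of that dataset under each family,
`p(x̃|M_r, x) = ∫ p_LT(x̃|θ) N(θ; θ̂_r, Σ̂_r) dθ`, estimated by iterative
(Meng–Wong) bridge sampling with a moment-matched normal proposal and the
optimal bridge function (relative tolerance 1e−10). The tests verify the
bridge against dense 2-D grid quadrature (within 0.02 nats for all four
families) and against the conjugate normal–normal evidence (0.01 nats).

## The two EVSI estimators

**Outer simulation (shared by both).** K parameter vectors are drawn from
the interim belief (model-averaged runs first draw a family with the prior
weights). For each draw, the n₂ at-risk patients' residual lifetimes are
sampled from the drawn model truncated at t₁ and censored at t₂. n₂ is the
observed at-risk count of the real (case-study) data, identical across
draws. Across several extensions the same parameter draws are reused and
only the follow-up data are redrawn, so the EVSI-vs-extension curve is
smooth in the common Monte Carlo noise.

**Regression estimator.** Each simulated dataset is summarised by its event
count and its person-time measured from t₁ (the origin only shifts the
statistic by the constant n₂·t₁ across draws; a test confirms the EVSI is
invariant to the choice within refit noise). Per arm, the stored net
benefits are smoothed on the two statistics with a penalized tensor-product
cubic B-spline (5 basis functions per margin, marginal second-difference
penalties, smoothing parameters by GCV). The smoother was cross-checked
against `mgcv::gam(nb ~ te(e, y))` on identical tables during development;
increasing the basis dimension does not move the estimates. The EVSI is the
mean of per-draw maxima of fitted values minus the maximum of mean net
benefits; the spline bases span constants, so fitted means equal sample
means and the estimator is exactly zero when only one arm exists.

Standard errors come from resampling each arm's spline coefficients from
their Bayesian posterior normal (B = 1000 by default) and recomputing the
EVSI functional. This prices smoothing uncertainty only; the outer-draw
noise of the K simulated datasets adds a comparable spread (observed ±0.15
to ±0.25 life-months across seeds at K = 6000), which matters when
comparing two independent runs.

**Nested Monte Carlo.** Per outer dataset and arm, the posterior
∝ N(θ; θ̂, Σ̂) · p_LT(x̃|θ) is sampled by random-walk Metropolis: 4 chains,
proposal covariance (2.4²/2)·Σ̂ with per-chain scale adapted toward 23%
acceptance during 500 warmup iterations, thinning 4, split-chain R̂ < 1.05
required (one automatic retry with longer chains; the diagnostic is noisy at
small J). The inner value is the posterior mean RMST; model-averaged runs
weight the per-family inner values by the bridge-sampled posterior model
probabilities. The estimator subtracts the current-information value
computed from the same outer draws; its SE is the outer-level standard
error of the per-draw maxima. With a single candidate family the
model-averaged routine delegates to the single-model one (the bridge factor
cancels in Bayes' theorem), making the R = 1 reduction exact.

At full scale (K = 6000, J = 2000) this method is far too slow for routine
use; the package validates it against the regression estimator at reduced
scale (K = 200, J = 500 single-model; K = 40, J = 400 model-averaged),
where the two agree within combined Monte Carlo error.

## Synthetic case studies

Two scenarios (increasing and decreasing hazard), 200 patients per arm,
enrolled at time zero, censored at t₁ = 12 months, no loss to follow-up.
To make the model-selection problem real, each arm's survival times are
generated from a distribution that none of the candidates matches exactly:
an equal-weight mixture of a Weibull and a Gamma (parameters per arm listed
in `survoi.case_study.SCENARIOS`). The times are deterministic — the 200
centred quantiles (probabilities (i−0.5)/200) of the mixture CDF — so the
case studies contribute no simulation noise of their own and rebuilds are
bit-identical.

This construction was chosen, among several candidate readings of the
reference analysis it reproduces, as the one that best matches that
analysis's reference fit table; the match is exact to ≈0.25 AIC units and
≈0.6% in net benefit, but not to printed rounding, because the original
generation procedure is not fully public. Consequences worth knowing:

* Deterministic quantities (AIC table, weights, net benefits, their
  weighted averages) reproduce to a fraction of a percent.
* Model-averaged value-of-information quantities reproduce well
  (model-averaged EVPI within ≈0.1 of the reference 10.32/9.97).
* The reference *single-Weibull* EVPI and EVSI values are ~10–18% below
  what this package computes. This is not a reconstruction artifact:
  covariances tight enough to yield the reference single-model EVPI would
  push the model-averaged EVPI far below its reference value, so the two
  reference sets of numbers are not consistent with one covariance. The
  package follows the stated method (bivariate normal at the MLE with
  observed-information covariance, verified against `flexsurv`), and its
  single-model numbers are internally consistent (EVSI → EVPI as t₂ grows).
  The corresponding acceptance tests assert the reference values and are
  left failing by design.

## What the generator does and does not emulate

The case studies share every structural assumption of the method: common
enrolment, administrative censoring only, arms independent, survival model
stable over time. Real trials add staggered recruitment (varying follow-up
at the cut-off), loss to follow-up, covariates, and possible
non-proportional or time-varying effects — none of which the generator
produces, so passing tests say nothing about those features. They do show
that the estimators recover decision value correctly when the model class
is misspecified in shape (mixture truth vs. single-family candidates),
which is the central difficulty the method targets.

## ENBS layer

Population EVSI multiplies per-decision EVSI by the affected population:
accrual × (decision horizon − extension − reporting delay), undiscounted by
default (delay 0); both knobs are configurable. The per-month EVSI curve is
interpolated monotonically (PCHIP through (0,0), optionally capped at the
EVPI; isotonic smoothing with a warning if the inputs are non-monotone).
Marginal benefit is the forward difference per month. Marginal cost is the
trial cost rate under approval-with-research; under only-in-research the
forgone benefit of the withheld technology (accrual × current-information
incremental net benefit) is added. The optimum is the last month whose
marginal benefit covers the marginal cost. The reference policy optima for
the case studies are reproduced to within a month under the caption
parameters (trial cost 5 life-months/month, accrual 5 patients/month,
10-year horizon), but since the original population-scaling formula is not
printed, the tests check only the qualitative structure: interior optima
with AWR later than OIR.

## Known limitations

* Two-parameter families only; no splines, cure fractions, or covariates.
* Arms are fitted and simulated independently; no proportional-hazards or
  AFT link between arms.
* The regression estimator's SE omits outer-draw noise (see above); treat
  differences between runs at different seeds accordingly.
* Left truncation assumes the interim belief is exactly the stated
  bivariate normal; with very few events a skewed likelihood would make
  that approximation, and hence the EVSI, optimistic.
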