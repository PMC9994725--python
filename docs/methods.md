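# Methods

## The model

`bfgmplx` implements a seven-parameter bivariate lifetime distribution
obtained by coupling two power Lomax (PLx) margins through the
Farlie–Gumbel–Morgenstern (FGM) copula.

Each margin is power Lomax,

    F(x; γ, β, λ) = 1 − λ^γ (λ + x^β)^(−γ),        x > 0,

with shape parameters γ, β > 0 and scale λ > 0.  The survival function is
polynomial of index γβ, so the r-th raw moment

    E[X^r] = (r/β) λ^(r/β) B(r/β, γ − r/β)

exists only for r < γβ.  The hazard is decreasing for β ≤ 1 and
upside-down bathtub shaped for β > 1.

The joint CDF couples the marginal CDFs F₁, F₂ through the FGM copula
C(u, v) = uv[1 + θ(1 − u)(1 − v)], |θ| < 1:

    F(x₁, x₂) = F₁F₂ [1 + θ S₁ S₂],
    f(x₁, x₂) = f₁f₂ [1 + θ (2S₁ − 1)(2S₂ − 1)],
    R(x₁, x₂) = S₁S₂ [1 + θ F₁ F₂],

with Sⱼ = 1 − Fⱼ.  The FGM family trades tractability for weak
dependence: Kendall's τ = 2θ/9 and Spearman's ρ = θ/3, so |τ| ≤ 2/9.  The
model is positively (negatively) quadrant dependent exactly when θ > 0
(θ < 0): R − R₁R₂ = θ F₁F₂S₁S₂.

All moment-type closed forms route through two beta-function ratios.
With a = r/β,

    Υ(r) = 1 − B(a, 2γ − a) / (2 B(a, γ − a)),     Λ = B(1/β, 2γ − 1/β) / B(1/β, γ − 1/β),

the joint raw moment is E[X₁^r₁ X₂^r₂] = E[X₁^r₁]E[X₂^r₂]·[1 + θ(2Υ₁ − 1)(2Υ₂ − 1)],
the covariance is E[X₁]E[X₂]·θ(1 − Λ₁)(1 − Λ₂), and the conditional mean is

    E[X_t | X_g = x] = E[X_t] [1 + θ (1 − 2F_g(x)) (Λ_t − 1)],

nonlinear in the conditioning value.  The printed source for the
conditional mean is typographically ambiguous in the Λ exponent; the form
above is the one that agrees with direct numerical integration of
x·conditional density (relative error ~1e−12), which is how the package
fixes it.  A "moment generating function" for this model can only be a
formal series — heavy-tailed margins have no MGF in a neighbourhood of
zero — so `mgf_partial_sum` is an explicitly truncated moment series that
drops terms whose moments do not exist and says so.

### Reliability measures

Basu's scalar hazard is f/R.  The vector hazard is −∇ log R, each
component a marginal PLx hazard times the copula correction
1 − θ S_l F_m / A with A = 1 + θF₁F₂.  The mean residual life
m₁(x₁, x₂) = E[X₁ − x₁ | X₁ ≥ x₁, X₂ ≥ x₂] uses the tail-integral
identity m₁ = ∫ₓ₁^∞ R(s, x₂) ds / R(x₁, x₂); the inner integral splits
into S₁(s) and S₁(s)² pieces (the square is a PLx survival with doubled
γ), each an incomplete first moment expressible through the regularized
incomplete beta function.  Vitality is υᵢ = xᵢ + mᵢ.  Published
closed-form MRL expressions for this model omit the incomplete-moment
tails and only hold at the origin; the implementation therefore derives
the tail-integral form and verifies it against 2-D quadrature (rel.
error ≲ 1e−9 in tests).  Survival factors are handled in log space so
deep-tail evaluation does not underflow.

### Exact sampling

Conditional inversion.  Draw U, V iid uniform; X₁ = Q₁(U); solve
C_{2|1}(w | U) = V, which for FGM is the quadratic w[1 + b(1 − w)] = V
with b = θ(1 − 2U), solved in the rationalized closed form
w = 2V / (1 + b + √((1+b)² − 4bV)) (stable as b → 0); X₂ = Q₂(w).  No
Newton iterations are needed; a Newton–Raphson solver exists only as a
test oracle.

## The Weibull-limit ridge

As λ, γ → ∞ with γ/λ fixed, (1 + x^β/λ)^(−γ) → exp(−c x^β): the PLx
family degenerates into a Weibull.  Consequences permeate everything:

* The marginal and joint likelihoods have a flat ridge.  For some
  datasets — including the bundled duration-of-diabetes margin — the
  likelihood increases monotonically along the ridge and the supremum is
  the (unattained) Weibull limit.  The optimizer then runs to large
  (γ̂, λ̂); the fit is flagged `on_ridge`, and the fitted CDF,
  log-likelihood and goodness of fit remain perfectly well defined even
  though (γ̂, λ̂) individually are not.
* Fit quality is ridge-stable only approximately.  Between a point
  partway up the ridge and the Weibull limit the log-likelihood changes
  by fractions of a unit and the KS distance by ~0.01; two optimizers
  stopping at different points on the ridge report slightly different KS
  values even though both are "converged" by loose criteria.
* Wald variances for ridge parameters are meaningless; the package
  reports them with a diagnostic note and falls back to a pseudo-inverse
  when the observed information is numerically singular.

## Estimation

**Maximum likelihood.**  The joint log-likelihood is maximized on the
transformed scale (log for the six positive parameters, atanh for θ) with
the analytic score and a safeguarded quasi-Newton driver (L-BFGS-B),
multi-started from marginal PLx fits plus the τ-inversion start
θ₀ = 9τ̂/2 clipped into (−0.99, 0.99).  A damped Newton–Raphson driver is
provided and tested to reach the same optimum on regular problems; it is
not the default because raw Newton steps are unstable on the ridge.  The
observed information is computed by central differences of the analytic
score (the score itself is exact; printed analytic second-derivative
formulas for this model contain typographical errors and are not
transcribed).  Wald intervals follow the estimate ± z·se convention on
the natural scale without truncation at zero, matching how such tables
are conventionally reported; negative lower bounds for positive
parameters are flagged, not clipped.

**Bayesian.**  Independent gamma priors on the positive parameters,
uniform(−1, 1) on θ.  Hyperparameters come from moment matching: a
target mean m and variance v give shape m²/v, rate m/v; by default the
moments are the ML estimate and its asymptotic variance (optionally
inflated).  Sampling is single-site random-walk Metropolis within Gibbs
in the fixed order (γ₁, β₁, λ₁, γ₂, β₂, λ₂, θ), log-scale proposals for
positive parameters (Jacobian folded into the acceptance ratio), identity
scale for θ.  Proposal scales adapt multiplicatively toward 25–45%
acceptance during burn-in and are frozen afterwards, so retained draws
form a valid Markov chain.  Defaults: 10,000 iterations, 2,000 burn-in,
no thinning.  Point estimates under squared-error loss are posterior
means; equal-tail intervals use the order-statistic percentile rule (the
500th and 9,500th of 10,000 sorted draws at 90%), and HPD intervals the
shortest-window scan.  Both are reported because symmetric tables in this
literature sometimes label the percentile construction "HPD".

## Synthetic-data generator and the simulation study

The generator *is* the exact conditional-inversion sampler above, at the
two study configurations used throughout:

* configuration 1: γ₁=0.6, β₁=3, λ₁=2.8, γ₂=0.9, β₂=2.5, λ₂=0.7;
* configuration 2: γ₁=1.3, β₁=5, λ₁=1.5, γ₂=0.9, β₂=4, λ₂=1.3;

with θ ∈ {0.4, −0.5} and n ∈ {35, 50, 100, 150}.  It emulates clean,
complete, exactly-model-distributed paired lifetimes; it does not emulate
censoring, covariates, measurement rounding or model misspecification, so
passing tests demonstrate internal correctness of the machinery, not
robustness on real data.

`run_study` repeats sample → fit → accumulate with replicate i seeded
`seed + i` (reproducible and shardable), reporting per-parameter bias,
MSE and mean interval length (Wald for ML, credible for Bayes) with Monte
Carlo standard errors next to every cell.  The default is 1,000
replicates; scaled-down runs stay honestly comparable through the
attached MC errors.

**Identification screen.**  On a small fraction of replicates
(~0.5–1% at n = 150, far more at n = 35) the global MLE genuinely sits
far up the Weibull ridge — e.g. γ̂ an order of magnitude above the truth
— and the unconditional MSE of γ̂ is dominated by those few replicates
at any practical replicate count.  Finite printed MSE tables for this
estimator are therefore necessarily conditional, and the harness makes
the conditioning explicit: a replicate contributes only when the fit
converged off the ridge flag, away from the optimizer box, and with
relative Wald SE of each tail index below 1 (`cv_max`).  Screened-out
replicates are tallied as failures; >10% failures flags the report
unreliable.

**Bayesian arm.**  Priors are elicited per replicate.  With
`prior_center="mle"` (default) they are centred on that replicate's own
ML fit — the operationally realistic protocol, which mostly shortens
intervals.  With `prior_center="truth"` they are centred on the true
values with the replicate's asymptotic spread — the well-centred
benchmark that isolates what informative priors can contribute, and the
setting under which the Bayes-beats-ML trend in bias/MSE/interval length
holds uniformly.

## Known irreproducibilities in the reference analysis

Two published headline numbers for the bundled dataset cannot be
recovered by any correct maximizer, and the corresponding acceptance
tests fail by design (they assert the published values):

* The published joint-fit AIC (128.7305) is arithmetically inconsistent
  with the published estimates: evaluating the likelihood at those exact
  estimates gives lnL = −57.8652, i.e. AIC 129.7304 at k = 7 — exactly
  1.0 above the published value.  The true maximum over the full
  parameter space is lnL = −57.6876 (AIC 129.3751, θ̂ ≈ 0.053),
  confirmed from independent starts and optimizers.  This package
  reports the true maximum.
* The published duration-margin KS distance (0.0751) is computed at
  marginal estimates that are not a stationary point: started exactly
  there, any ascent method climbs monotonically to the Weibull-limit
  supremum (lnL −59.803 → −59.625), where KS = 0.0839.  The serum
  creatinine margin has an interior optimum and its published KS
  (0.1020) is reproduced exactly.
* The published copula GoF "parameter" 0.0659 is reproduced exactly by
  maximum pseudo-likelihood on rank/(n+1) pseudo-observations; the
  unnamed published test statistic/p-value are not targets, and the
  package's rank-based Cramér–von Mises statistic with parametric
  bootstrap is its own construction.

## Numerical choices

* CDF/survival via `log1p`/`expm1` throughout; quantile via
  `expm1(−log1p(−u)/γ)`; all stable on the ridge and in deep tails.
* Kendall's τ uses the tie-corrected τ-b convention (the bundled serum
  creatinine values contain ties).
* Pseudo-observations use rank/(n+1) so the pseudo-likelihood stays
  finite.
* KS p-values use the asymptotic one-sample Kolmogorov distribution with
  parameters treated as known — anti-conservative after fitting, but the
  convention used by the reference tables.
* Moment existence (r < γβ) is a hard precondition raising a
  `ValueError`, never a silent NaN.
* Optimizer box in transformed coordinates: |log γ| ≤ 12, |log β| ≤ 5,
  log λ ∈ [−30, 60], |atanh θ| ≤ 6; hits are treated as failures in the
  study harness.
* Default problem sizes in the test suite and acceptance script (500–
  1,000 replicates, 10⁵–4·10⁵ sampler draws, 8,000–12,000 MCMC
  iterations) were chosen so every Monte Carlo comparison carries its own
  standard error; all are package defaults or explicit arguments, and
  scale up freely.

## Limitations

* Complete data only; no censoring or covariates.
* FGM dependence is intrinsically weak (|τ| ≤ 2/9); strongly dependent
  data need a different copula family.
* Wald inference for (γ, λ) is unreliable whenever the ridge flag is on;
  use the likelihood, fit quality, or the Bayesian machinery instead.
* The copula GoF bootstrap refits θ per resample; at its default 500
  resamples the p-value resolution is ~0.002 and the test inherits the
  low power of any rank test at n ≈ 20.
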