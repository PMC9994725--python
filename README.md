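# bfgmplx

A library and command-line tool for the **bivariate
Farlie–Gumbel–Morgenstern power Lomax (BFGMPLx) distribution** — a
seven-parameter model for paired, positive, heavy-tailed lifetimes such
as disease duration paired with a biomarker level.

Each margin is power Lomax,

    F(x; γ, β, λ) = 1 − λ^γ (λ + x^β)^(−γ),      γ, β, λ > 0,  x > 0,

and the two margins are coupled by the FGM copula
C(u, v) = uv[1 + θ(1 − u)(1 − v)] with θ ∈ (−1, 1), giving the joint CDF

    F(x₁, x₂) = F₁(x₁) F₂(x₂) [1 + θ S₁(x₁) S₂(x₂)].

The model is positively (negatively) quadrant dependent for θ > 0
(θ < 0), with Kendall's τ = 2θ/9 and Spearman's ρ = θ/3.

The package provides:

* the univariate power Lomax layer: pdf/cdf/quantile, raw moments,
  marginal maximum-likelihood fitting and goodness of fit (KS, CvM, AD);
* the FGM copula layer: distribution functions, dependence mappings,
  closed-form conditional inversion, and a rank-based Cramér–von Mises
  goodness-of-fit test with parametric bootstrap;
* the joint distribution: CDF/PDF/survival, conditionals, conditional
  expectation, product moments, covariance/correlation, an exact sampler,
  and quadrant-dependence diagnostics;
* bivariate reliability measures: Basu's scalar hazard, the vector
  hazard, mean residual life, and vitality;
* inference: joint ML with analytic score, observed information, Wald
  intervals and information criteria; Bayesian estimation with
  moment-matched gamma priors and a Metropolis-within-Gibbs sampler with
  equal-tail and HPD intervals;
* a Monte Carlo harness for estimator evaluation (bias / MSE / interval
  length with Monte Carlo standard errors);
* a bundled 19-pair dataset: duration of diabetes (years) vs serum
  creatinine (mg/dl).

See `docs/methods.md` for the model's assumptions, the Weibull-limit
ridge that dominates the numerics of this family, and known
irreproducibilities in the reference analysis.

## Worked example

```python
import bfgmplx as bx

ds = bx.builtin_dataset()            # 19 pairs: diabetes duration vs serum creatinine

# marginal power Lomax fits with goodness of fit
fy = bx.plx_fit_ml(ds.x2)
gy = bx.plx_gof(ds.x2, fy.params)
print(f"creatinine: KS={gy.ks:.4f}  p={gy.ks_pvalue:.4f}")

# copula adequacy on ranks
cg = bx.fgm_gof(ds.x1, ds.x2, n_boot=500, seed=1)
print(f"tau={cg.kendall_tau:.4f}  rho={cg.spearman_rho:.4f}  "
      f"theta_pml={cg.theta_hat:.4f}  p={cg.p_value:.4f}")

# joint seven-parameter ML fit
fit = bx.fit_ml(ds.as_sample(), starts=3, seed=0)
print(f"loglik={fit.loglik:.4f}  AIC={fit.ic['AIC']:.4f}  "
      f"theta={fit.estimates.theta:.4f}")
```

Output:

```
creatinine: KS=0.1020  p=0.9890
tau=0.0176  rho=0.0290  theta_pml=0.0659  p=0.1826
loglik=-57.6876  AIC=129.3751  theta=0.0531
```

Reading: the power Lomax margin fits serum creatinine well (small KS
distance, large p-value); the rank correlations are tiny and the FGM
copula is not rejected (bootstrap p = 0.18), with fitted dependence
θ ≈ 0.066; the joint fit agrees, estimating a weakly positive θ ≈ 0.05
whose Wald interval comfortably includes zero.  The duration margin
lands on the Weibull-limit ridge — its (γ̂, λ̂) are reported with a ridge
flag and should not be interpreted individually, while the
log-likelihood and fit quality remain valid.

The same analyses are available from the shell:

```sh
bfgmplx application --seed 0 --out report.json
bfgmplx fit-ml --data pairs.csv --columns 0,1 --level 0.95
bfgmplx fit-bayes --iters 10000 --burnin 2000 --seed 1
bfgmplx simulate --truth '[0.6,3,2.8,0.9,2.5,0.7,0.4]' --n 150 --reps 1000 --seed 7
bfgmplx sample --params '[1.3,5,1.5,0.9,4,1.3,0.4]' --n 500 --seed 3
bfgmplx reliability --params '[1.3,5,1.5,0.9,4,1.3,0.4]' --x1-grid 0.5,1,2 --x2-grid 1
```

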