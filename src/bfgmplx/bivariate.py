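"""Joint bivariate FGM power Lomax (BFGMPLx) distribution.

Couples two power Lomax margins through the FGM copula:

    F(x1, x2) = F1(x1) F2(x2) [1 + theta S1(x1) S2(x2)],
    f(x1, x2) = f1(x1) f2(x2) [1 + theta (2 S1 - 1)(2 S2 - 1)],

with S_j the marginal survival functions.  The module provides the joint
CDF/PDF/survival, conditional laws, the closed-form conditional
expectation, an exact sampler via conditional inversion, product moments,
covariance/correlation, a truncated moment-series object standing in for
the moment generating function (heavy-tailed margins have no MGF in an
open neighbourhood of zero — the series is formal), and the quadrant
dependence gap R - R1 R2 = theta * xi >= 0 for theta >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .fgm import CopulaParam, fgm_cdf, fgm_conditional_inverse
from .plomax import (
    PLxParams,
    plx_cdf,
    plx_moment,
    plx_pdf,
    plx_quantile,
    plx_sf,
)

__all__ = [
    "JointParams",
    "BivariateSample",
    "joint_cdf",
    "joint_pdf",
    "joint_logpdf",
    "joint_survival",
    "conditional_cdf",
    "conditional_pdf",
    "conditional_expectation",
    "sample",
    "product_moment",
    "covariance_correlation",
    "mgf_partial_sum",
    "quadrant_dependence_gap",
    "moment_lambda",
    "moment_upsilon",
]


@dataclass(frozen=True)
class JointParams:
    """Full parameter vector Theta = (gamma1, beta1, lam1, gamma2, beta2, lam2, theta)."""

    m1: PLxParams
    m2: PLxParams
    theta: float

    def __post_init__(self) -> None:
        CopulaParam(self.theta)  # validates the range

    @classmethod
    def from_vector(cls, v) -> "JointParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (7,):
            raise ValueError("expected a length-7 parameter vector")
        return cls(PLxParams(*v[:3]), PLxParams(*v[3:6]), float(v[6]))

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.m1.gamma,
                self.m1.beta,
                self.m1.lam,
                self.m2.gamma,
                self.m2.beta,
                self.m2.lam,
                self.theta,
            ]
        )

    def margin(self, j: int) -> PLxParams:
        if j == 1:
            return self.m1
        if j == 2:
            return self.m2
        raise ValueError("margin index must be 1 or 2")


PARAM_NAMES = ("gamma1", "beta1", "lam1", "gamma2", "beta2", "lam2", "theta")


@dataclass(frozen=True)
class BivariateSample:
    """Paired strictly positive lifetimes (x1_i, x2_i), i = 1..n."""

    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float).ravel()
        x2 = np.asarray(self.x2, dtype=float).ravel()
        if x1.size != x2.size:
            raise ValueError("x1 and x2 must have equal length")
        if x1.size == 0:
            raise ValueError("sample is empty")
        if np.any(x1 <= 0) or np.any(x2 <= 0):
            raise ValueError("all observations must be strictly positive")
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)

    @property
    def n(self) -> int:
        return self.x1.size


def joint_cdf(x1, x2, params: JointParams):
    """Joint CDF via Sklar's theorem with FGM copula and PLx margins."""
    u = plx_cdf(x1, params.m1)
    v = plx_cdf(x2, params.m2)
    return fgm_cdf(u, v, params.theta)


def joint_logpdf(x1, x2, params: JointParams):
    from .plomax import plx_logpdf

    s1 = plx_sf(x1, params.m1)
    s2 = plx_sf(x2, params.m2)
    bracket = 1.0 + params.theta * (2.0 * s1 - 1.0) * (2.0 * s2 - 1.0)
    return (
        plx_logpdf(x1, params.m1) + plx_logpdf(x2, params.m2) + np.log(bracket)
    )


def joint_pdf(x1, x2, params: JointParams):
    """Joint density f1 f2 [1 + theta(2 S1 - 1)(2 S2 - 1)]."""
    return np.exp(joint_logpdf(x1, x2, params))


def joint_survival(x1, x2, params: JointParams):
    """Joint survival S1 S2 [1 + theta F1 F2] = 1 - F1 - F2 + F."""
    s1 = plx_sf(x1, params.m1)
    s2 = plx_sf(x2, params.m2)
    return s1 * s2 * (1.0 + params.theta * (1.0 - s1) * (1.0 - s2))


def _target_given(direction: int, params: JointParams) -> tuple[PLxParams, PLxParams]:
    """Margin of the target variable and of the conditioning variable."""
    if direction == 2:  # law of X2 given X1
        return params.m2, params.m1
    if direction == 1:  # law of X1 given X2
        return params.m1, params.m2
    raise ValueError("direction must be 1 or 2")


def conditional_cdf(x_t, x_g, direction: int, params: JointParams):
    """Conditional CDF of one component given the other's exact value.

    ``direction=2`` gives F(x2 | X1 = x_g); ``direction=1`` the mirror.
    Closed form: Ft [1 + theta - theta Ft - 2 theta Fg (1 - Ft)].
    """
    pt, pg = _target_given(direction, params)
    ft = plx_cdf(x_t, pt)
    fg = plx_cdf(x_g, pg)
    t = params.theta
    return ft * (1.0 + t - t * ft - 2.0 * t * fg * (1.0 - ft))


def conditional_pdf(x_t, x_g, direction: int, params: JointParams):
    """Conditional density; factorizes joint_pdf = conditional_pdf * marginal pdf."""
    pt, pg = _target_given(direction, params)
    ft = plx_cdf(x_t, pt)
    fg = plx_cdf(x_g, pg)
    t = params.theta
    bracket = 1.0 + t - 2.0 * t * ft - 2.0 * t * fg * (1.0 - 2.0 * ft)
    return plx_pdf(x_t, pt) * bracket


def moment_lambda(j: int, params: JointParams) -> float:
    """Ratio Lambda_j = B(1/b, 2g - 1/b) / B(1/b, g - 1/b), in (1/2, 1)."""
    p = params.margin(j)
    a = 1.0 / p.beta
    if p.gamma <= a:
        raise ValueError(f"margin {j}: first moment requires gamma > 1/beta")
    return float(special.beta(a, 2.0 * p.gamma - a) / special.beta(a, p.gamma - a))


def moment_upsilon(r: float, j: int, params: JointParams) -> float:
    """Upsilon_j(r) = 1 - B(r/b, 2g - r/b) / (2 B(r/b, g - r/b))."""
    p = params.margin(j)
    a = r / p.beta
    if p.gamma <= a:
        raise ValueError(f"margin {j}: moment of order {r} requires r < gamma*beta")
    return float(1.0 - special.beta(a, 2.0 * p.gamma - a) / (2.0 * special.beta(a, p.gamma - a)))


def conditional_expectation(x_g, direction: int, params: JointParams) -> float:
    """E[X_t | X_g = x_g], a nonlinear function of the conditioning value.

    Derived by integrating x against the conditional density.  Using
    f_t(x) S_t(x) = f(x; 2 gamma_t)/2, one gets E[X F_t(X)] = mu(1 - Lambda_t/2)
    with mu = E[X_t] and Lambda_t the beta-function ratio above, hence

        E[X_t | X_g = x_g] = mu [1 + theta (1 - 2 Fg(x_g)) (Lambda_t - 1)],

    which matches numerical integration of x * conditional_pdf.  Since
    Lambda_t < 1, positive theta pulls the conditional mean below mu for
    small x_g and above it for large x_g, as positive dependence should.
    """
    pt, pg = _target_given(direction, params)
    mu = plx_moment(1.0, pt)
    lam_t = moment_lambda(direction, params)
    fg = plx_cdf(x_g, pg)
    t = params.theta
    return mu * (1.0 + t * (1.0 - 2.0 * fg) * (lam_t - 1.0))


def sample(n: int, params: JointParams, seed=None) -> BivariateSample:
    """Draw n pairs exactly via conditional inversion.

    U, V ~ iid Uniform(0,1); X1 = Q1(U); W = C^{-1}_{2|1}(V | U);
    X2 = Q2(W).  Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = 1e-15
    u = np.clip(rng.uniform(size=n), eps, 1 - eps)
    v = np.clip(rng.uniform(size=n), eps, 1 - eps)
    x1 = plx_quantile(u, params.m1)
    w = np.clip(fgm_conditional_inverse(v, u, params.theta), eps, 1 - eps)
    x2 = plx_quantile(w, params.m2)
    return BivariateSample(x1, x2)


def product_moment(r1: float, r2: float, params: JointParams) -> float:
    """Joint raw moment E[X1^r1 X2^r2] in closed form.

    Product of the marginal raw moments times the FGM correction
    ``1 + theta(2 Upsilon_1 - 1)(2 Upsilon_2 - 1)``; exists iff
    r_j < gamma_j beta_j for both margins.
    """
    for r, j in ((r1, 1), (r2, 2)):
        p = params.margin(j)
        if r >= p.gamma * p.beta:
            raise ValueError(
                f"margin {j}: moment of order {r} does not exist "
                f"(requires r < gamma*beta = {p.gamma * p.beta})"
            )
    m1 = plx_moment(r1, params.m1)
    m2 = plx_moment(r2, params.m2)
    u1 = moment_upsilon(r1, 1, params)
    u2 = moment_upsilon(r2, 2, params)
    t = params.theta
    corr = 1.0 + t - 2.0 * t * u2 - 2.0 * t * u1 + 4.0 * t * u1 * u2
    return m1 * m2 * corr


def covariance_correlation(params: JointParams) -> tuple[float, float]:
    """Covariance and Pearson correlation of (X1, X2).

    cov = E[X1]E[X2] theta (1 - Lambda1)(1 - Lambda2) ... via the product
    moment; rho = cov / (sd1 sd2).  Zero iff theta = 0, sharing its sign.
    Requires second moments (2 < gamma_j beta_j).
    """
    for j in (1, 2):
        p = params.margin(j)
        if 2.0 >= p.gamma * p.beta:
            raise ValueError(f"margin {j}: second moment requires gamma*beta > 2")
    e1 = plx_moment(1.0, params.m1)
    e2 = plx_moment(1.0, params.m2)
    cov = product_moment(1.0, 1.0, params) - e1 * e2
    v1 = plx_moment(2.0, params.m1) - e1**2
    v2 = plx_moment(2.0, params.m2) - e2**2
    rho = cov / np.sqrt(v1 * v2)
    return float(cov), float(rho)


def mgf_partial_sum(t1: float, t2: float, N: int, params: JointParams) -> tuple[float, list[str]]:
    """Partial sum of the formal joint moment series up to order N in each index.

    The (n1, n2) term is t1^n1 t2^n2 / (n1! n2!) * E[X1^n1 X2^n2]; terms
    whose moments do not exist are dropped, with a truncation warning.  The
    n=0 terms contribute 1.  Because PLx margins are heavy tailed the full
    series diverges for t != 0; this object is a formal moment expansion.
    """
    warnings: list[str] = []
    n1_max = int(np.ceil(params.m1.gamma * params.m1.beta)) - 1
    n2_max = int(np.ceil(params.m2.gamma * params.m2.beta)) - 1
    if N > min(n1_max, n2_max):
        warnings.append(
            f"series truncated at orders ({min(N, n1_max)}, {min(N, n2_max)}): "
            "higher moments do not exist"
        )
    total = 0.0
    for n1 in range(0, min(N, n1_max) + 1):
        for n2 in range(0, min(N, n2_max) + 1):
            if n1 == 0 and n2 == 0:
                term = 1.0
            elif n1 == 0:
                term = t2**n2 / special.factorial(n2) * plx_moment(n2, params.m2)
            elif n2 == 0:
                term = t1**n1 / special.factorial(n1) * plx_moment(n1, params.m1)
            else:
                term = (
                    t1**n1
                    * t2**n2
                    / (special.factorial(n1) * special.factorial(n2))
                    * product_moment(n1, n2, params)
                )
            total += float(term)
    return total, warnings


def quadrant_dependence_gap(x1, x2, params: JointParams):
    """Signed gap R(x1,x2) - R1(x1) R2(x2) = theta F1 F2 S1 S2.

    Positive everywhere for theta > 0 (positive quadrant dependence),
    negative for theta < 0, identically zero under independence.
    """
    s1 = plx_sf(x1, params.m1)
    s2 = plx_sf(x2, params.m2)
    return params.theta * (1.0 - s1) * (1.0 - s2) * s1 * s2
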