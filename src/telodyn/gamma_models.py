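"""Gamma log-link GLMs and a year-random-intercept gamma GLMM.

The modelling response (positively shifted rTL z-score) is treated as
gamma-distributed with mean mu = exp(X beta [+ u_g]) and shape alpha, i.e.
Var(y) = mu^2 / alpha. Fixed-effect GLM coefficients come from iteratively
reweighted least squares (via statsmodels); the shape is then profiled out
by maximum likelihood from the digamma score equation, and the reported
log-likelihood is the full gamma likelihood at the joint optimum.

The mixed model adds a group-level (year) intercept u_g ~ N(0, sigma^2) on
the link scale and maximises the marginal likelihood, integrating u_g per
group by adaptive Gauss-Hermite quadrature (15 nodes by default; one node
reproduces the Laplace approximation). All fits are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

#: factor level sets with the reference level first (treatment contrasts)
FACTOR_LEVELS = {
    "sex": ("female", "male", "unknown"),
    "tissue": ("blood", "tail"),
    "morphotype": ("eisentrauti", "galloti", "insulanagae"),
}
CONTINUOUS_TERMS = ("svl", "env_pc1", "env_pc2")


class ModelSpecError(ValueError):
    """Invalid model specification (marginality violations, bad terms)."""


class FitError(RuntimeError):
    """Numerical failure while fitting (rank deficiency, divergence)."""


@dataclass(frozen=True)
class ModelSpec:
    """A gamma log-link model: fixed terms plus an optional random intercept.

    ``fixed_terms`` may contain main effects over the study predictors and
    interaction terms written 'a:b' (both parents must also be present).
    """

    response: str = "rtl_shifted"
    fixed_terms: tuple[str, ...] = ()
    random_intercept: str | None = None

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise ModelSpecError(
                        f"interaction {t!r} requires both parent main effects"
                    )

    @property
    def label(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "1"


@dataclass
class DesignMatrices:
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray | None
    names: list[str]
    n_dropped: int
    info: dict = field(default_factory=dict)


@dataclass
class FitResult:
    """A fitted gamma GLM or GLMM (the currency of model selection)."""

    spec: ModelSpec | None
    names: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    shape: float
    sigma_group: float
    loglik: float
    n: int
    k: int
    converged: bool
    y: np.ndarray
    mu: np.ndarray
    design_info: dict = field(default_factory=dict)
    method: str = "glm"

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def summary(self) -> pd.DataFrame:
        se = self.se()
        z = self.beta / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": self.names, "estimate": self.beta, "se": se, "z": z, "p": p}
        )

    def to_dict(self) -> dict:
        return {
            "terms": self.names,
            "beta": self.beta.tolist(),
            "se": self.se().tolist(),
            "shape": self.shape,
            "sigma_group": self.sigma_group,
            "loglik": self.loglik,
            "n": self.n,
            "k": self.k,
            "aicc": aicc(self),
            "converged": self.converged,
            "method": self.method,
        }


def _factor_columns(
    data: pd.DataFrame, factor: str, standardized: dict
) -> tuple[np.ndarray, list[str]]:
    levels = FACTOR_LEVELS[factor]
    observed = set(data[factor].unique())
    unknown_levels = observed - set(levels)
    if unknown_levels:
        raise ModelSpecError(f"unknown {factor} level(s): {sorted(unknown_levels)}")
    non_ref = [lv for lv in levels[1:] if lv in observed]
    if not non_ref:
        missing = [lv for lv in levels[1:] if lv not in observed]
        raise ModelSpecError(
            f"factor {factor!r} has no contrast: level(s) {missing} absent after filtering"
        )
    cols = np.column_stack([(data[factor] == lv).to_numpy(float) for lv in non_ref])
    return cols, [f"{factor}_{lv}" for lv in non_ref]


def build_design(
    samples: pd.DataFrame, spec: ModelSpec, standardize: bool = True
) -> DesignMatrices:
    """Model matrix with treatment contrasts and standardised covariates.

    Rows with any missing required field are dropped (logged). Reference
    levels: female (sex), blood (tissue), eisentrauti (morphotype).
    Continuous predictors are centred and scaled to SD 1 by default so
    coefficients are per-SD effects.
    """
    main_terms = [t for t in spec.fixed_terms if ":" not in t]
    required = [spec.response] + main_terms
    if spec.random_intercept:
        required.append(spec.random_intercept)
    missing_cols = [c for c in required if c not in samples.columns]
    if missing_cols:
        raise ModelSpecError(f"missing columns in sample table: {missing_cols}")
    data = samples.dropna(subset=required)
    n_dropped = len(samples) - len(data)
    if n_dropped:
        logger.info("build_design: dropped %d row(s) with missing data", n_dropped)
    y = data[spec.response].to_numpy(float)
    if np.any(y <= 0):
        raise ModelSpecError("response must be strictly positive for a gamma model")

    blocks: list[np.ndarray] = [np.ones((len(data), 1))]
    names: list[str] = ["intercept"]
    info: dict = {"centers": {}, "scales": {}, "factor_levels": {}, "n_dropped": n_dropped}
    col_map: dict[str, tuple[np.ndarray, list[str]]] = {}

    for term in main_terms:
        if term in FACTOR_LEVELS:
            cols, cnames = _factor_columns(data, term, info)
            info["factor_levels"][term] = [FACTOR_LEVELS[term][0]] + [
                c.split("_", 1)[1] for c in cnames
            ]
        else:
            x = data[term].to_numpy(float)
            if standardize:
                c, s = float(x.mean()), float(x.std(ddof=1))
                if s == 0:
                    raise ModelSpecError(f"continuous term {term!r} is constant")
                x = (x - c) / s
                info["centers"][term], info["scales"][term] = c, s
            cols, cnames = x[:, None], [term]
        col_map[term] = (cols, cnames)
        blocks.append(cols)
        names.extend(cnames)

    for term in spec.fixed_terms:
        if ":" not in term:
            continue
        a, b = term.split(":")
        ca, na = col_map[a]
        cb, nb = col_map[b]
        inter = np.column_stack([ca[:, i] * cb[:, j] for i in range(ca.shape[1]) for j in range(cb.shape[1])])
        inames = [f"{x}:{z}" for x in na for z in nb]
        blocks.append(inter)
        names.extend(inames)

    X = np.hstack(blocks)
    groups = data[spec.random_intercept].to_numpy() if spec.random_intercept else None
    return DesignMatrices(X=X, y=y, groups=groups, names=names, n_dropped=n_dropped, info=info)


# ---------------------------------------------------------------------------
# gamma likelihood machinery


def gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    """Exact gamma log-likelihood with mean parameterisation."""
    a = shape
    return float(
        np.sum(
            a * np.log(a)
            - special.gammaln(a)
            + (a - 1) * np.log(y)
            - a * np.log(mu)
            - a * y / mu
        )
    )


def estimate_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """ML gamma shape given fitted means: solves the digamma score equation

        log(a) + 1 - psi(a) + mean(log(y/mu) - y/mu) = 0.
    """
    c = float(np.mean(np.log(y / mu) - y / mu))  # <= -1, equality iff y == mu
    if c >= -1.0 - 1e-12:
        return 1e8  # perfect fit: shape diverges; return a large finite value
    f = lambda la: np.log(np.exp(la)) + 1 - special.digamma(np.exp(la)) + c
    lo, hi = -12.0, 20.0
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [names[i] for i in piv[r:]]
        raise FitError(f"design matrix is rank deficient; collinear column(s): {bad}")


def fit_gamma_glm(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    spec: ModelSpec | None = None,
    design_info: dict | None = None,
) -> FitResult:
    """Gamma log-link GLM by IRLS, with ML shape and exact log-likelihood.

    The coefficient estimates do not depend on the shape; the Wald covariance
    is the inverse Fisher information (X'X)^-1 / shape (log link makes the
    information weights constant).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    if np.any(y <= 0):
        raise FitError("gamma response must be positive")
    _check_rank(X, names)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=100, tol=1e-10)
    beta = np.asarray(res.params, float)
    mu = np.exp(X @ beta)
    shape = estimate_shape(y, mu)
    ll = gamma_loglik(y, mu, shape)
    xtx_inv = np.linalg.inv(X.T @ X)
    vcov = xtx_inv / shape
    return FitResult(
        spec=spec,
        names=names,
        beta=beta,
        vcov=vcov,
        shape=shape,
        sigma_group=0.0,
        loglik=ll,
        n=len(y),
        k=X.shape[1] + 1,
        converged=bool(res.converged),
        y=y,
        mu=mu,
        design_info=design_info or {},
        method="glm",
    )


def glmm_marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    beta: np.ndarray,
    shape: float,
    sigma: float,
    n_quad: int = 15,
) -> float:
    """Marginal log-likelihood of the gamma GLMM by adaptive Gauss-Hermite.

    For each group the random intercept is integrated out on a quadrature
    grid centred at the conditional mode and scaled by the curvature there
    (n_quad=1 gives the Laplace approximation). Vectorised over groups.
    """
    a = shape
    eta = X @ beta
    w_y = y * np.exp(-eta)  # y_i / exp(eta_i)
    n_per = np.bincount(group_idx, minlength=n_groups).astype(float)

    # conditional mode per group by Newton (h is strictly concave in u)
    u = np.zeros(n_groups)
    for _ in range(100):
        s = np.bincount(group_idx, weights=w_y * np.exp(-u[group_idx]), minlength=n_groups)
        grad = a * (s - n_per) - u / sigma**2
        hess = -a * s - 1.0 / sigma**2
        step = grad / hess
        u -= step
        if np.max(np.abs(grad)) < 1e-10:
            break
    s = np.bincount(group_idx, weights=w_y * np.exp(-u[group_idx]), minlength=n_groups)
    tau = 1.0 / np.sqrt(a * s + 1.0 / sigma**2)

    z, w = hermgauss(n_quad)
    # h(u) up to terms constant in u; constants added back at the end
    def h_of(u_nodes: np.ndarray) -> np.ndarray:
        # u_nodes: (G, J)
        s_g = np.zeros_like(u_nodes)
        for j in range(u_nodes.shape[1]):
            s_g[:, j] = np.bincount(
                group_idx, weights=w_y * np.exp(-u_nodes[group_idx, j]), minlength=n_groups
            )
        return -a * (n_per[:, None] * u_nodes + s_g) - u_nodes**2 / (2 * sigma**2)

    nodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
    hvals = h_of(nodes)
    log_int = (
        np.log(np.sqrt(2.0) * tau)
        + special.logsumexp(hvals + z[None, :] ** 2 + np.log(w)[None, :], axis=1)
    )
    const_obs = float(
        np.sum(a * np.log(a) - special.gammaln(a) + (a - 1) * np.log(y) - a * eta)
    )
    const_group = -0.5 * n_groups * np.log(2 * np.pi * sigma**2)
    return const_obs + const_group + float(np.sum(log_int))


def _numeric_hessian(f, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    p = len(x0)
    H = np.zeros((p, p))
    f0 = f(x0)
    steps = eps * np.maximum(1.0, np.abs(x0))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def fit_gamma_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: Sequence[str] | None = None,
    n_quad: int = 15,
    spec: ModelSpec | None = None,
    design_info: dict | None = None,
    compute_vcov: bool = True,
) -> FitResult:
    """Gamma log-link GLMM with one random intercept, fitted by marginal ML.

    Optimises (beta, log shape, log sigma) by L-BFGS-B from GLM starting
    values; the marginal likelihood uses adaptive Gauss-Hermite quadrature.
    A sigma estimate collapsing to (near) zero is a valid boundary fit and is
    flagged in the log. k counts fixed coefficients + shape + variance.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    codes, uniq = pd.factorize(np.asarray(groups))
    n_groups = len(uniq)
    if n_groups < 2:
        raise FitError("random intercept requires >= 2 groups")
    glm = fit_gamma_glm(X, y, names=names)
    resid_g = np.bincount(codes, weights=np.log(y) - np.log(glm.mu), minlength=n_groups)
    resid_g /= np.bincount(codes, minlength=n_groups)
    sigma0 = float(np.clip(np.std(resid_g), 0.02, 1.0))
    p = X.shape[1]
    theta0 = np.concatenate([glm.beta, [np.log(glm.shape), np.log(sigma0)]])

    def nll(theta: np.ndarray) -> float:
        beta = theta[:p]
        shape = np.exp(theta[p])
        sigma = np.exp(theta[p + 1])
        return -glmm_marginal_loglik(X, y, codes, n_groups, beta, shape, sigma, n_quad)

    bounds = [(None, None)] * p + [(-10.0, 20.0), (np.log(1e-4), 3.0)]
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        # line-search failures on near-flat likelihoods: polish derivative-free
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    beta = theta[:p]
    shape = float(np.exp(theta[p]))
    sigma = float(np.exp(theta[p + 1]))
    loglik = -float(res.fun)
    boundary = sigma < 1e-3
    if boundary:
        logger.info("sigma_group collapsed to boundary (%.2e); random effect ~ null", sigma)
    if compute_vcov:
        H = _numeric_hessian(nll, theta)
        try:
            cov_all = np.linalg.inv(H)
            vcov = cov_all[:p, :p]
            if np.any(np.diag(vcov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            vcov = np.linalg.inv(X.T @ X) / shape  # fall back to GLM information
    else:
        vcov = np.linalg.inv(X.T @ X) / shape
    return FitResult(
        spec=spec,
        names=names,
        beta=beta,
        vcov=vcov,
        shape=shape,
        sigma_group=sigma,
        loglik=loglik,
        n=len(y),
        k=p + 2,
        converged=bool(res.success),
        y=y,
        mu=np.exp(X @ beta),
        design_info=design_info or {},
        method="glmm",
    )


def fit_model(samples: pd.DataFrame, spec: ModelSpec, n_quad: int = 15, **kwargs) -> FitResult:
    """Build the design for ``spec`` and fit the GLM or GLMM it calls for."""
    d = build_design(samples, spec)
    if spec.random_intercept:
        return fit_gamma_glmm(
            d.X, d.y, d.groups, names=d.names, n_quad=n_quad, spec=spec,
            design_info=d.info, **kwargs,
        )
    return fit_gamma_glm(d.X, d.y, names=d.names, spec=spec, design_info=d.info)


# ---------------------------------------------------------------------------
# information criteria and fit statistics


def aicc(fit: FitResult) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    n, k = fit.n, fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n must exceed k+1)")
    return -2.0 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def nagelkerke_r2(fit: FitResult, null_fit: FitResult) -> float:
    """Likelihood-ratio pseudo-R2 rescaled to a 0-1 maximum."""
    if fit.n != null_fit.n:
        raise ValueError("fit and null must use the same rows")
    l1, l0, n = fit.loglik, null_fit.loglik, fit.n
    if l1 < l0 - 1e-8:
        logger.warning("nagelkerke_r2: full model loglik below null (misordered models?)")
    cox_snell = 1.0 - np.exp(2.0 * (l0 - l1) / n)
    max_cs = 1.0 - np.exp(2.0 * l0 / n)
    return float(cox_snell / max_cs)


def gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Gamma deviance D = 2 sum[-log(y/mu) + (y-mu)/mu]."""
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


def deviance_explained(fit: FitResult, null_fit: FitResult) -> float:
    """Fraction of gamma deviance explained relative to the null model."""
    d0 = gamma_deviance(null_fit.y, null_fit.mu)
    if d0 == 0:
        raise ValueError("null deviance is zero")
    d1 = gamma_deviance(fit.y, fit.mu)
    return float(1.0 - d1 / d0)
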