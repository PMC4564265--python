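"""Binomial (logistic) mixed model with nested random intercepts, Laplace ML.

The field analyses model herbivore presence/absence per plant with random
intercepts for population nested within county:

    logit P(y_i = 1) = x_i' beta + u_county(i) + v_pop(i),
    u_c ~ N(0, sigma_county^2),  v_p ~ N(0, sigma_pop^2).

Estimation is maximum likelihood with a Laplace approximation to the
integral over random effects (not REML), so that deviance differences
between nested fixed-effect structures are valid likelihood-ratio
statistics.  The random-effect vector is low dimensional (counties +
populations), so the inner mode-finding is a damped Newton iteration on the
full joint penalised log-likelihood and the outer profile over
(beta, log sigma) uses L-BFGS-B.

Only what the survey analyses need is implemented: Bernoulli response,
random intercepts, Wald standard errors from the joint information matrix,
and the variance components required for marginal R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

__all__ = ["MixedLogitResult", "fit_binomial_mixed"]

_LOG_SIGMA_BOUNDS = (np.log(1e-4), np.log(20.0))


@dataclass
class MixedLogitResult:
    """Fit summary for the nested-intercept logistic mixed model."""

    terms: tuple[str, ...]
    params: np.ndarray
    se: np.ndarray
    sigma_county: float
    sigma_pop: float
    loglik: float
    deviance: float          # -2 * Laplace log-likelihood
    var_fixed: float         # variance of the fixed-effect linear predictor
    n: int
    converged: bool
    flags: tuple[str, ...] = ()
    response_checksum: int = 0

    @property
    def ok(self) -> bool:
        return self.converged and not self.flags

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])


def _design_checksum(y: np.ndarray) -> int:
    return int(np.asarray(y, dtype=np.int64).sum() * 1_000_003 + y.size)


def _inner_mode(beta, log_sigmas, X, y, ci, pi, nc, npop, pop_county):
    """Newton maximisation of the joint penalised log-likelihood over u.

    Returns (u_hat, penalised loglik at mode, log det(I + Zt W Z D)).
    """
    var = np.r_[
        np.full(nc, np.exp(2.0 * log_sigmas[0])),
        np.full(npop, np.exp(2.0 * log_sigmas[1])),
    ]
    q = nc + npop
    eta_fix = X @ beta
    u = np.zeros(q)

    def penalised(u_):
        eta = eta_fix + u_[ci] + u_[nc + pi]
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(np.sum(u_**2 / var))

    f = penalised(u)
    for _ in range(200):
        eta = eta_fix + u[ci] + u[nc + pi]
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        resid = y - mu
        g = np.zeros(q)
        np.add.at(g, ci, resid)
        np.add.at(g, nc + pi, resid)
        g -= u / var
        sw_c = np.bincount(ci, weights=w, minlength=nc)
        sw_p = np.bincount(pi, weights=w, minlength=npop)
        H = np.zeros((q, q))
        H[np.arange(nc), np.arange(nc)] = sw_c
        H[nc + np.arange(npop), nc + np.arange(npop)] = sw_p
        H[pop_county, nc + np.arange(npop)] = sw_p
        H[nc + np.arange(npop), pop_county] = sw_p
        H[np.diag_indices(q)] += 1.0 / var
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = g / np.diag(H)
        # step-halving to guarantee ascent
        t = 1.0
        for _half in range(30):
            f_new = penalised(u + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        u = u + t * step
        if abs(f_new - f) < 1e-11 and np.max(np.abs(t * step)) < 1e-9:
            f = f_new
            break
        f = f_new

    # log det(I + Zt W Z D) evaluated at the mode (D cancels the prior det,
    # keeping the expression finite as sigma -> 0).
    eta = eta_fix + u[ci] + u[nc + pi]
    mu = expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    sw_c = np.bincount(ci, weights=w, minlength=nc)
    sw_p = np.bincount(pi, weights=w, minlength=npop)
    S = np.zeros((q, q))
    S[np.arange(nc), np.arange(nc)] = sw_c
    S[nc + np.arange(npop), nc + np.arange(npop)] = sw_p
    S[pop_county, nc + np.arange(npop)] = sw_p
    S[nc + np.arange(npop), pop_county] = sw_p
    M = np.eye(q) + S * var  # S @ diag(var)
    sign, logdet = np.linalg.slogdet(M)
    return u, f, float(logdet)


def _laplace_nll(theta, X, y, ci, pi, nc, npop, pop_county):
    p = X.shape[1]
    beta = theta[:p]
    log_sigmas = theta[p:]
    _, f_mode, logdet = _inner_mode(beta, log_sigmas, X, y, ci, pi, nc, npop, pop_county)
    return -(f_mode - 0.5 * logdet)


def fit_binomial_mixed(
    y: np.ndarray,
    X: np.ndarray,
    county_idx: np.ndarray,
    pop_idx: np.ndarray,
    term_names: tuple[str, ...] | None = None,
) -> MixedLogitResult:
    """Fit the logistic mixed model by Laplace-approximate maximum likelihood.

    Parameters
    ----------
    y
        Binary response (0/1), no missing values.
    X
        Fixed-effect design matrix (include the intercept column explicitly).
    county_idx, pop_idx
        Integer codes (0-based) for county and population of each
        observation; each population must belong to exactly one county.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    ci = np.asarray(county_idx, dtype=int)
    pi = np.asarray(pop_idx, dtype=int)
    n, p = X.shape
    terms = tuple(term_names) if term_names else tuple(f"x{j}" for j in range(p))
    if len(terms) != p:
        raise ValueError("term_names length must match the number of design columns")
    nc = int(ci.max()) + 1
    npop = int(pi.max()) + 1
    pop_county = np.zeros(npop, dtype=int)
    for pp in range(npop):
        counties = np.unique(ci[pi == pp])
        if counties.size != 1:
            raise ValueError(f"population {pp} spans {counties.size} counties; nesting violated")
        pop_county[pp] = counties[0]
    if npop < 2:
        raise ValueError("need at least 2 populations to fit the nested random effects")

    flags: list[str] = []
    if y.min() == y.max():
        return MixedLogitResult(
            terms=terms, params=np.full(p, np.nan), se=np.full(p, np.nan),
            sigma_county=np.nan, sigma_pop=np.nan, loglik=np.nan, deviance=np.nan,
            var_fixed=np.nan, n=n, converged=False,
            flags=("degenerate_response",), response_checksum=_design_checksum(y),
        )

    # Plain logistic start for beta (few Newton steps, ridge-stabilised).
    beta0 = np.zeros(p)
    for _ in range(25):
        mu = expit(X @ beta0)
        w = mu * (1 - mu) + 1e-9
        g = X.T @ (y - mu) - 1e-8 * beta0
        H = (X * w[:, None]).T @ X + 1e-8 * np.eye(p)
        step = np.linalg.solve(H, g)
        beta0 = beta0 + step
        if np.max(np.abs(step)) < 1e-8:
            break

    theta0 = np.r_[beta0, np.log(0.3), np.log(0.3)]
    bounds = [(None, None)] * p + [_LOG_SIGMA_BOUNDS, _LOG_SIGMA_BOUNDS]
    args = (X, y, ci, pi, nc, npop, pop_county)
    res = optimize.minimize(
        _laplace_nll, theta0, args=args, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = res.x
    beta = theta[:p]
    sigma_c, sigma_p_ = np.exp(theta[p]), np.exp(theta[p + 1])
    loglik = -float(res.fun)
    if not res.success:
        flags.append("nonconvergence")
    if np.max(np.abs(beta)) > 15.0:
        flags.append("possible_separation")

    # Wald SEs from the joint (beta, u) information at the mode.
    u, _, _ = _inner_mode(beta, theta[p:], X, y, ci, pi, nc, npop, pop_county)
    var = np.r_[np.full(nc, sigma_c**2), np.full(npop, sigma_p_**2)]
    q = nc + npop
    eta = X @ beta + u[ci] + u[nc + pi]
    mu = expit(eta)
    w = mu * (1 - mu) + 1e-12
    I_bb = (X * w[:, None]).T @ X
    Zw = np.zeros((n, q))
    Zw[np.arange(n), ci] = 1.0
    Zw[np.arange(n), nc + pi] = 1.0
    I_bu = X.T @ (Zw * w[:, None])
    I_uu = Zw.T @ (Zw * w[:, None]) + np.diag(1.0 / var)
    try:
        cov_beta = np.linalg.inv(I_bb - I_bu @ np.linalg.solve(I_uu, I_bu.T))
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flags.append("singular_information")

    var_fixed = float(np.var(X @ beta)) if p > 0 else 0.0
    return MixedLogitResult(
        terms=terms, params=beta, se=se, sigma_county=float(sigma_c),
        sigma_pop=float(sigma_p_), loglik=loglik, deviance=-2.0 * loglik,
        var_fixed=var_fixed, n=n, converged=res.success, flags=tuple(flags),
        response_checksum=_design_checksum(y),
    )
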