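"""Maximum-likelihood logistic regression with a scalar random intercept.

Model: ``y_gi ~ Bernoulli(expit(x_gi' beta + b_g))`` with ``b_g ~ N(0, tau^2)``
independent across groups.  The marginal likelihood integrates the random
intercept out group by group with adaptive Gauss-Hermite quadrature: the
integrand is centered at its mode (found by a concave 1-d Newton step,
vectorized across groups) and scaled by its curvature, which keeps the
quadrature accurate even for large clusters.  ``(beta, log tau)`` is then
maximized with BFGS and standard errors come from the inverse of a
finite-difference Hessian of the marginal log-likelihood.

With a single group the variance is not identifiable; the fit then reduces
to ordinary logistic regression with ``tau = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = ["GLMMLogitResult", "fit_logit_random_intercept"]


@dataclass
class GLMMLogitResult:
    params: np.ndarray  # fixed-effect coefficients (log-odds scale)
    cov_params: np.ndarray  # covariance of the fixed effects
    tau: float  # random-intercept SD
    loglik: float
    converged: bool
    n_groups: int

    def contrast(self, c: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
        """Estimate and Wald CI of the linear contrast c'beta."""
        from scipy.stats import norm

        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov_params @ c))
        zq = norm.ppf(0.5 + level / 2.0)
        return est, est - zq * se, est + zq * se


def _group_modes(eta, y, gidx, n_groups, tau2, tol=1e-10, max_iter=50):
    """Mode and curvature of each group's integrand, Newton on concave f."""
    b = np.zeros(n_groups)
    for _ in range(max_iter):
        p = expit(eta + b[gidx])
        grad = np.bincount(gidx, weights=y - p, minlength=n_groups) - b / tau2
        hess = -np.bincount(gidx, weights=p * (1.0 - p), minlength=n_groups) - 1.0 / tau2
        step = grad / hess
        b = b - step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(eta + b[gidx])
    curv = np.bincount(gidx, weights=p * (1.0 - p), minlength=n_groups) + 1.0 / tau2
    return b, curv


def _marginal_loglik(params, X, y, gidx, n_groups, nodes, lognw):
    beta, logtau = params[:-1], params[-1]
    tau2 = np.exp(2.0 * logtau)
    eta = X @ beta
    bhat, curv = _group_modes(eta, y, gidx, n_groups, tau2)
    s = 1.0 / np.sqrt(curv)  # (G,)
    # f_g(b) at the shifted nodes, all groups x nodes at once
    bk = bhat[:, None] + s[:, None] * nodes[None, :]  # (G, K)
    eta_k = eta[:, None] + bk[gidx]  # (n, K)
    # Bernoulli log-likelihood contributions, summed into groups
    ll_obs = y[:, None] * eta_k - np.logaddexp(0.0, eta_k)
    f = np.zeros((n_groups, len(nodes)))
    for k in range(len(nodes)):
        f[:, k] = np.bincount(gidx, weights=ll_obs[:, k], minlength=n_groups)
    f -= bk**2 / (2.0 * tau2)
    ll_g = (
        logsumexp(lognw[None, :] + nodes[None, :] ** 2 / 2.0 + f, axis=1)
        + np.log(s)
        - 0.5 * np.log(2.0 * np.pi * tau2)
    )
    return float(ll_g.sum())


def _numerical_hessian(fun, x, step=1e-4):
    k = len(x)
    H = np.empty((k, k))
    hs = step * (1.0 + np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H


def fit_logit_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 15,
) -> GLMMLogitResult:
    """Fit the random-intercept logistic model by adaptive Gauss-Hermite ML."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _, gidx = np.unique(groups, return_inverse=True)
    n_groups = int(gidx.max()) + 1

    if n_groups < 2:
        import statsmodels.api as sm

        fit = sm.Logit(y, X).fit(disp=0)
        return GLMMLogitResult(
            params=np.asarray(fit.params, dtype=float),
            cov_params=np.asarray(fit.cov_params(), dtype=float),
            tau=0.0,
            loglik=float(fit.llf),
            converged=bool(fit.mle_retvals.get("converged", True)),
            n_groups=1,
        )

    # probabilists' Hermite nodes: integral against exp(-x^2/2)
    nodes, weights = hermegauss(n_quad)
    lognw = np.log(weights)

    import statsmodels.api as sm

    start_beta = sm.Logit(y, X).fit(disp=0, maxiter=200).params
    x0 = np.concatenate([np.asarray(start_beta, dtype=float), [np.log(0.3)]])

    def negll(params):
        return -_marginal_loglik(params, X, y, gidx, n_groups, nodes, lognw)

    res = minimize(negll, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-7})
    H = _numerical_hessian(negll, res.x)
    k = X.shape[1]
    try:
        cov_full = np.linalg.inv(H)
        cov_beta = cov_full[:k, :k]
    except np.linalg.LinAlgError:
        cov_beta = np.linalg.pinv(H)[:k, :k]
    return GLMMLogitResult(
        params=res.x[:k],
        cov_params=cov_beta,
        tau=float(np.exp(res.x[-1])),
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_groups=n_groups,
    )
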