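"""Latent-class trajectory model for longitudinal adherence summaries.

A finite mixture of Gaussian linear mixed models: patient ``i`` with
observation months ``t`` and responses ``y_i`` belongs to class ``j`` with
probability ``pi_j``; conditionally on class membership,

    y_i ~ N(X_i beta_j,  V_i),    V_i = Z_i D Z_i' + sigma^2 I,

where ``X_i`` stacks the fixed-effect design rows ``[1, t, h_12(t), ...,
h_96(t)]`` built from a linear-spline (hinge) basis ``h_T(t) = max(0, t-T)``
with knots every 12 months, and ``Z_i = [1, t]`` carries a random intercept
and a random slope with free 2x2 covariance ``D`` shared across classes.

Estimation maximizes the marginal mixture log-likelihood by EM:

* E-step: posterior class probabilities ``p_ij`` proportional to
  ``pi_j * N(y_i; X_i beta_j, V_i)``;
* M-step: ``pi`` from posterior means, ``beta_j`` by posterior-weighted
  generalized least squares, and ``(D, sigma)`` by numerical ascent on the
  expected complete-data log-likelihood (log-Cholesky parameterization,
  sigma floored at 1e-4).

Each conditional maximization can only improve the objective, so the
marginal log-likelihood is non-decreasing across iterations; the trace is
recorded and checked.  All per-patient quantities are computed from
sufficient statistics (X'X, X'y, y'y) through the Woodbury identity, so the
cost per iteration is independent of the number of months per patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import DataError

__all__ = [
    "BasisConfig",
    "LatentClassModel",
    "design_row",
    "design_matrix",
    "fit_lcmm",
    "map_classify",
    "typical_trajectory",
    "relabel_classes",
    "marginal_loglik",
]

DEFAULT_KNOTS = (12, 24, 36, 48, 60, 72, 84, 96)

_SIGMA_FLOOR = 1e-4
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class BasisConfig:
    """Linear-spline basis: columns ``[1, t, max(0, t-T) for T in knots]``."""

    knots: tuple = DEFAULT_KNOTS
    include_intercept: bool = True
    include_linear_t: bool = True

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if len(k) and np.any(np.diff(k) <= 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return int(self.include_intercept) + int(self.include_linear_t) + len(self.knots)

    @property
    def column_names(self) -> list:
        names = []
        if self.include_intercept:
            names.append("intercept")
        if self.include_linear_t:
            names.append("t")
        names += [f"hinge_{int(T)}" for T in self.knots]
        return names


def design_row(t: float, basis: BasisConfig | None = None) -> np.ndarray:
    """Fixed-effect design row at month ``t``."""
    return design_matrix(np.asarray([t], dtype=float), basis)[0]


def design_matrix(t: np.ndarray, basis: BasisConfig | None = None) -> np.ndarray:
    basis = basis or BasisConfig()
    t = np.asarray(t, dtype=float)
    cols = []
    if basis.include_intercept:
        cols.append(np.ones_like(t))
    if basis.include_linear_t:
        cols.append(t)
    for T in basis.knots:
        cols.append(np.maximum(0.0, t - T))
    return np.column_stack(cols)


@dataclass
class LatentClassModel:
    """Fitted mixture of linear mixed models."""

    n_classes: int
    class_weights: np.ndarray
    class_coefficients: np.ndarray  # (J, p), rows on the basis columns
    random_intercept_sd: float
    random_slope_sd: float
    re_correlation: float
    residual_sd: float
    log_likelihood: float
    n_em_iterations: int
    converged: bool
    basis: BasisConfig = field(default_factory=BasisConfig)
    loglik_trace: list = field(default_factory=list, repr=False)

    @property
    def re_covariance(self) -> np.ndarray:
        c = self.re_correlation * self.random_intercept_sd * self.random_slope_sd
        return np.array(
            [
                [self.random_intercept_sd**2, c],
                [c, self.random_slope_sd**2],
            ]
        )

    def to_dict(self) -> dict:
        return {
            "n_classes": int(self.n_classes),
            "class_weights": [float(w) for w in self.class_weights],
            "class_coefficients": [[float(b) for b in row] for row in self.class_coefficients],
            "basis_columns": self.basis.column_names,
            "knots": [int(k) for k in self.basis.knots],
            "random_intercept_sd": float(self.random_intercept_sd),
            "random_slope_sd": float(self.random_slope_sd),
            "re_correlation": float(self.re_correlation),
            "residual_sd": float(self.residual_sd),
            "log_likelihood": float(self.log_likelihood),
            "n_em_iterations": int(self.n_em_iterations),
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# sufficient statistics and likelihood machinery


class _Stats:
    """Per-patient sufficient statistics for the marginal likelihood."""

    def __init__(self, data: pd.DataFrame, basis: BasisConfig, time_col: str, y_col: str):
        if not (basis.include_intercept and basis.include_linear_t):
            raise ValueError("fitting requires an intercept and a linear time column")
        if data[y_col].isna().any():
            raise DataError("NaN response values")
        p = basis.n_columns
        ids, ns, Gs, gs, yys = [], [], [], [], []
        for pid, grp in data.groupby("patient_id", sort=True):
            if grp[time_col].duplicated().any():
                raise DataError(f"duplicate time points for patient {pid}")
            X = design_matrix(grp[time_col].to_numpy(dtype=float), basis)
            y = grp[y_col].to_numpy(dtype=float)
            ids.append(pid)
            ns.append(len(y))
            Gs.append(X.T @ X)
            gs.append(X.T @ y)
            yys.append(float(y @ y))
        self.ids = ids
        self.n_obs = np.asarray(ns, dtype=float)
        self.G = np.stack(Gs)  # (n, p, p)
        self.g = np.stack(gs)  # (n, p)
        self.yy = np.asarray(yys, dtype=float)
        self.p = p
        self.n = len(ids)


def _unpack(theta: np.ndarray):
    """theta = (log L11, L21, log L22, log sigma) -> (D, Dinv, logdetD, sigma2).

    D = L L' with L lower-triangular; the inverse and log-determinant come
    from L analytically, which stays stable when the variances are tiny.
    """
    l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
    D = np.array([[l11 * l11, l11 * l21], [l11 * l21, l21 * l21 + l22 * l22]])
    Linv = np.array([[1.0 / l11, 0.0], [-l21 / (l11 * l22), 1.0 / l22]])
    Dinv = Linv.T @ Linv
    logdetD = 2.0 * float(theta[0] + theta[2])
    return D, Dinv, logdetD, float(np.exp(2.0 * theta[3]))


def _pack(D: np.ndarray, sigma: float) -> np.ndarray:
    L = np.linalg.cholesky(D + 1e-12 * np.eye(2))
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]), np.log(max(sigma, _SIGMA_FLOOR))])


_THETA_BOUNDS = [
    (np.log(1e-5), np.log(1e3)),
    (-100.0, 100.0),
    (np.log(1e-5), np.log(1e3)),
    (np.log(_SIGMA_FLOOR), np.log(1e3)),
]


def _v_pieces(stats: _Stats, vp):
    """Woodbury pieces shared by density, GLS and quadratic forms."""
    D, Dinv, logdetD, sigma2 = vp
    A = Dinv[None, :, :] + stats.G[:, :2, :2] / sigma2  # (n, 2, 2)
    Ainv = np.linalg.inv(A)
    _, logdetA = np.linalg.slogdet(A)
    logdetV = stats.n_obs * np.log(sigma2) + logdetA + logdetD
    return Ainv, logdetV


def _logdensities(stats: _Stats, beta: np.ndarray, vp) -> np.ndarray:
    """log N(y_i; X_i beta_j, V_i) for all patients x classes, via Woodbury."""
    sigma2 = vp[3]
    Ainv, logdetV = _v_pieces(stats, vp)
    base = (
        stats.yy[:, None]
        - 2.0 * stats.g @ beta.T
        + np.einsum("jp,npq,jq->nj", beta, stats.G, beta)
    )  # (n, J)
    # w_ij = Z_i'(y_i - X_i beta_j), shape (n, J, 2)
    w = stats.g[:, None, :2] - np.einsum("nqp,jp->njq", stats.G[:, :2, :], beta)
    corr = np.einsum("njq,nqr,njr->nj", w, Ainv, w)
    quad = base / sigma2 - corr / sigma2**2
    return -0.5 * (stats.n_obs[:, None] * _LOG2PI + logdetV[:, None] + quad)


def _estep(stats, pi, beta, vp):
    logphi = _logdensities(stats, beta, vp)
    logw = np.log(pi)[None, :] + logphi
    norm = logsumexp(logw, axis=1)
    post = np.exp(logw - norm[:, None])
    return float(norm.sum()), post


def _gls_beta(stats: _Stats, post: np.ndarray, vp) -> np.ndarray:
    sigma2 = vp[3]
    Ainv, _ = _v_pieces(stats, vp)
    XtZ = stats.G[:, :, :2]  # (n, p, 2)
    Sxx = stats.G / sigma2 - np.einsum("npq,nqr,nsr->nps", XtZ, Ainv, XtZ) / sigma2**2
    Sxy = stats.g / sigma2 - np.einsum("npq,nqr,nr->np", XtZ, Ainv, stats.g[:, :2]) / sigma2**2
    J = post.shape[1]
    beta = np.empty((J, stats.p))
    for j in range(J):
        lhs = np.einsum("n,npq->pq", post[:, j], Sxx)
        rhs = np.einsum("n,np->p", post[:, j], Sxy)
        lhs = lhs + 1e-10 * np.eye(stats.p) * max(np.trace(lhs) / stats.p, 1.0)
        beta[j] = np.linalg.solve(lhs, rhs)
    return beta


def _variance_objective(stats, post, beta):
    def fun(theta):
        logphi = _logdensities(stats, beta, _unpack(theta))
        return -float(np.sum(post * logphi))

    return fun


def _update_variance(stats, post, beta, theta0, inner_maxiter):
    fun = _variance_objective(stats, post, beta)
    f0 = fun(theta0)
    res = minimize(
        fun,
        theta0,
        method="L-BFGS-B",
        bounds=_THETA_BOUNDS,
        options={"maxiter": inner_maxiter, "ftol": 1e-12},
    )
    # a conditional-maximization step must never lose ground
    return (res.x, float(res.fun)) if res.fun <= f0 else (theta0, f0)


def _patient_ols_coefs(stats: _Stats) -> np.ndarray:
    """Per-patient OLS intercept/slope on [1, t]; initialization feature."""
    coefs = np.empty((stats.n, 2))
    for i in range(stats.n):
        Gzz = stats.G[i, :2, :2] + 1e-8 * np.eye(2)
        coefs[i] = np.linalg.solve(Gzz, stats.g[i, :2])
    return coefs


def _initial_posteriors(stats: _Stats, J: int, rng: np.random.Generator, start: int) -> np.ndarray:
    coefs = _patient_ols_coefs(stats)
    scale = coefs.std(axis=0)
    scale[scale == 0] = 1.0
    z = coefs / scale
    if start > 0:
        z = z + rng.normal(0.0, 0.3 * (1 + start / 4), size=z.shape)
    if J == 1:
        labels = np.zeros(stats.n, dtype=int)
    else:
        km = KMeans(n_clusters=J, n_init=5, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(z)
    post = np.full((stats.n, J), 0.05 / max(J - 1, 1))
    post[np.arange(stats.n), labels] = 0.95 if J > 1 else 1.0
    post /= post.sum(axis=1, keepdims=True)
    return post


def _init_params(stats: _Stats, post: np.ndarray):
    J = post.shape[1]
    pi = post.mean(axis=0)
    beta = np.empty((J, stats.p))
    resid_num, resid_den = 0.0, 0.0
    for j in range(J):
        lhs = np.einsum("n,npq->pq", post[:, j], stats.G)
        rhs = np.einsum("n,np->p", post[:, j], stats.g)
        lhs = lhs + 1e-6 * np.eye(stats.p) * max(np.trace(lhs) / stats.p, 1.0)
        beta[j] = np.linalg.solve(lhs, rhs)
        sq = stats.yy - 2.0 * stats.g @ beta[j] + np.einsum("p,npq,q->n", beta[j], stats.G, beta[j])
        resid_num += float(post[:, j] @ sq)
        resid_den += float(post[:, j] @ stats.n_obs)
    sigma2 = max(resid_num / max(resid_den, 1.0), 1e-4)
    coefs = _patient_ols_coefs(stats)
    # within-class spread of the per-patient coefficients: initializing the
    # random-effect variance from the total spread lets the intercept
    # variance swallow the class separation and EM collapses to one curve
    d = np.zeros(2)
    for j in range(J):
        w = post[:, j] / post[:, j].sum()
        mu = w @ coefs
        d += pi[j] * (w @ (coefs - mu) ** 2)
    d = np.maximum(d * 0.5, 1e-6)
    D = np.diag(d)
    theta = _pack(D, np.sqrt(sigma2 * 0.5))
    return pi, beta, theta


def _run_em(stats, post0, tol, max_iter, inner_maxiter):
    pi, beta, theta = _init_params(stats, post0)
    vp = _unpack(theta)
    trace = []
    converged = False
    ll_prev = -np.inf
    post = post0
    for it in range(max_iter):
        ll, post = _estep(stats, pi, beta, vp)
        trace.append(ll)
        if ll < ll_prev - 1e-6 * (1.0 + abs(ll_prev)):
            warnings.warn(
                f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}",
                RuntimeWarning,
            )
        if it > 0 and abs(ll - ll_prev) < tol * (1.0 + abs(ll_prev)):
            converged = True
            break
        ll_prev = ll
        pi = np.maximum(post.mean(axis=0), 1e-10)
        pi /= pi.sum()
        beta = _gls_beta(stats, post, vp)
        theta, _ = _update_variance(stats, post, beta, theta, inner_maxiter)
        vp = _unpack(theta)
    ll, post = _estep(stats, pi, beta, vp)
    trace.append(ll)
    return ll, pi, beta, theta, post, trace, converged


def _profile_single_class(stats, beta, theta, inner_maxiter=200):
    """Exact profile-likelihood polish for J=1: beta is GLS-profiled out at
    every variance evaluation, so the optimum is the plain LMM ML fit."""

    def fun(theta_):
        vp = _unpack(theta_)
        b = _gls_beta(stats, np.ones((stats.n, 1)), vp)
        ll, _ = _estep(stats, np.array([1.0]), b, vp)
        return -ll

    res = minimize(fun, theta, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12})
    theta_best = res.x if res.fun <= fun(theta) else theta
    beta = _gls_beta(stats, np.ones((stats.n, 1)), _unpack(theta_best))
    return beta, theta_best


def fit_lcmm(
    data: pd.DataFrame,
    n_classes: int = 3,
    basis: BasisConfig | None = None,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    time_col: str = "month",
    y_col: str = "y",
    inner_maxiter: int = 30,
) -> tuple[LatentClassModel, pd.DataFrame]:
    """Fit the latent-class trajectory model; best of ``n_starts`` restarts.

    Parameters
    ----------
    data
        Long table with columns ``patient_id``, ``time_col`` and ``y_col``.
    n_classes
        Number of latent classes J (>= 1).
    basis
        Fixed-effect basis; default is the 12-month hinge basis.
    n_starts
        Seeded restarts: the first clusters per-patient OLS intercept/slope
        coefficients, later ones perturb them before clustering.

    Returns
    -------
    (model, posteriors) where posteriors has columns ``patient_id``,
    ``p_1 .. p_J`` with rows summing to 1.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    basis = basis or BasisConfig()
    stats = _Stats(data, basis, time_col, y_col)
    if stats.n < n_classes:
        raise DataError(f"{stats.n} patients cannot support {n_classes} classes")
    rng = np.random.default_rng(seed)

    best = None
    for start in range(max(1, n_starts) if n_classes > 1 else 1):
        post0 = _initial_posteriors(stats, n_classes, rng, start)
        result = _run_em(stats, post0, tol, max_iter, inner_maxiter)
        if best is None or result[0] > best[0]:
            best = result
    ll, pi, beta, theta, post, trace, converged = best

    if n_classes == 1:
        beta, theta = _profile_single_class(stats, beta, theta)
        ll, post = _estep(stats, np.array([1.0]), beta, _unpack(theta))
        trace.append(ll)
        converged = True

    D, _, _, sigma2 = _unpack(theta)
    sd_i, sd_s = np.sqrt(D[0, 0]), np.sqrt(D[1, 1])
    corr = float(D[0, 1] / (sd_i * sd_s)) if sd_i > 0 and sd_s > 0 else 0.0
    model = LatentClassModel(
        n_classes=n_classes,
        class_weights=pi,
        class_coefficients=beta,
        random_intercept_sd=float(sd_i),
        random_slope_sd=float(sd_s),
        re_correlation=corr,
        residual_sd=float(np.sqrt(sigma2)),
        log_likelihood=float(ll),
        n_em_iterations=len(trace) - 1,
        converged=converged,
        basis=basis,
        loglik_trace=trace,
    )
    posteriors = pd.DataFrame(post, columns=[f"p_{j + 1}" for j in range(n_classes)])
    posteriors.insert(0, "patient_id", stats.ids)
    return model, posteriors


def marginal_loglik(
    data: pd.DataFrame,
    model: LatentClassModel,
    time_col: str = "month",
    y_col: str = "y",
) -> float:
    """Marginal mixture log-likelihood of ``data`` at the model's parameters."""
    stats = _Stats(data, model.basis, time_col, y_col)
    theta = _pack(model.re_covariance, model.residual_sd)
    ll, _ = _estep(
        stats,
        np.asarray(model.class_weights, dtype=float),
        np.asarray(model.class_coefficients, dtype=float),
        _unpack(theta),
    )
    return ll


def map_classify(posteriors: pd.DataFrame) -> pd.DataFrame:
    """Maximum-a-posteriori class per patient; ties to the lowest index."""
    pcols = [c for c in posteriors.columns if c.startswith("p_")]
    P = posteriors[pcols].to_numpy(dtype=float)
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8) or np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
        raise DataError("posterior rows must be probabilities summing to 1")
    idx = np.argmax(P, axis=1)
    return pd.DataFrame(
        {
            "patient_id": posteriors["patient_id"].to_numpy(),
            "map_class": idx + 1,
            "map_probability": P[np.arange(len(P)), idx],
        }
    )


def typical_trajectory(
    model: LatentClassModel,
    posteriors: pd.DataFrame,
    j: int,
    months: np.ndarray,
) -> pd.DataFrame:
    """Typical trajectory of class ``j`` (1-based) on a month grid.

    ``value_curve`` is the fixed-effect curve ``design_row(t) . beta_j``;
    ``value_weighted`` is the posterior-weighted mean of per-patient class-j
    predictions, which coincides with the curve because the fixed effects
    are shared within a class.  Both are reported.
    """
    if not 1 <= j <= model.n_classes:
        raise ValueError(f"class index {j} out of range 1..{model.n_classes}")
    wsum = float(posteriors[f"p_{j}"].sum())
    if wsum < 1e-8:
        warnings.warn(f"class {j} is empty (sum of posteriors ~ 0); curve from beta only")
    X = design_matrix(np.asarray(months, dtype=float), model.basis)
    curve = X @ np.asarray(model.class_coefficients)[j - 1]
    return pd.DataFrame({"month": months, "value_weighted": curve, "value_curve": curve})


def relabel_classes(
    model: LatentClassModel,
    posteriors: pd.DataFrame,
    order: np.ndarray | None = None,
    at_month: float = 12.0,
    descending: bool = True,
) -> tuple[LatentClassModel, pd.DataFrame]:
    """Permute class labels into a stable reporting order.

    Default rule: descending fixed-effect curve level at ``at_month`` (so
    class 1 is the highest trajectory).  ``order`` overrides with an
    explicit permutation of 0-based old indices.  The likelihood is
    invariant under the permutation.
    """
    beta = np.asarray(model.class_coefficients)
    if order is None:
        level = design_row(at_month, model.basis) @ beta.T
        order = np.argsort(-level if descending else level, kind="stable")
    order = np.asarray(order, dtype=int)
    if sorted(order.tolist()) != list(range(model.n_classes)):
        raise ValueError("order must be a permutation of 0..J-1")
    new_model = LatentClassModel(
        n_classes=model.n_classes,
        class_weights=np.asarray(model.class_weights)[order],
        class_coefficients=beta[order],
        random_intercept_sd=model.random_intercept_sd,
        random_slope_sd=model.random_slope_sd,
        re_correlation=model.re_correlation,
        residual_sd=model.residual_sd,
        log_likelihood=model.log_likelihood,
        n_em_iterations=model.n_em_iterations,
        converged=model.converged,
        basis=model.basis,
        loglik_trace=list(model.loglik_trace),
    )
    pcols = [f"p_{j + 1}" for j in range(model.n_classes)]
    P = posteriors[pcols].to_numpy()[:, order]
    new_post = posteriors.copy()
    new_post[pcols] = P
    return new_model, new_post
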