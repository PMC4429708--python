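"""Outcome-association stages: viral load, CD4 recovery, mortality.

Three models link the adherence summaries to clinical outcomes:

* a mixed logistic regression of the six-monthly undetectable-viral-load
  indicator (< 1000 copies/mL) on the mean-trajectory class crossed with
  the variance class (full interaction, reference cell DrI mean x High
  variance), with a random intercept on the six-month period;
* a mixed linear model of the monthly CD4 change (six-month visit-to-visit
  difference divided by 6, cells/mm3/month) with the same fixed structure
  and random intercept;
* a Cox proportional-hazards model with time-varying covariates: monthly
  counting-process episodes from month 12 carrying the current 12-month
  moving mean (per 10 adherence points) and standardized variance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError
from .glmm import fit_logit_random_intercept
from .synthetic import MEAN_CLASS_LABELS, VAR_CLASS_LABELS

__all__ = [
    "build_six_month_outcomes",
    "fit_mixed_logistic",
    "fit_mixed_linear",
    "build_survival_episodes",
    "fit_cox_td",
    "cox_partial_loglik",
    "person_time",
]


def build_six_month_outcomes(
    visits: pd.DataFrame,
    classes: pd.DataFrame,
    threshold: float = 1000.0,
) -> pd.DataFrame:
    """Six-monthly outcome rows per patient.

    A visit at month ``m`` belongs to period ``ceil(m / 6)``; the baseline
    visit (month 0) is excluded as an outcome but serves as the previous
    CD4 value for period 1.  ``undetectable`` is a strict threshold
    (``viral_load < threshold``); ``cd4_monthly_change`` is the CD4
    difference between consecutive periods divided by 6 (NaN when the
    preceding period has no visit).

    ``classes`` must carry ``patient_id``, ``mean_class``, ``var_class``.
    """
    v = visits.copy()
    v["period"] = np.ceil(v["month"] / 6.0).astype(int)
    dup = v.duplicated(subset=["patient_id", "period"], keep="last")
    if dup.any():
        warnings.warn(f"{int(dup.sum())} periods with two visits; keeping the later visit")
        v = v[~dup]
    v = v.sort_values(["patient_id", "period"]).reset_index(drop=True)

    prev = v[["patient_id", "period", "cd4"]].copy()
    prev["period"] += 1
    merged = v.merge(prev, on=["patient_id", "period"], how="left", suffixes=("", "_prev"))
    merged["cd4_monthly_change"] = (merged["cd4"] - merged["cd4_prev"]) / 6.0
    merged["undetectable"] = (merged["viral_load"] < threshold).astype(int)

    out = merged[merged["period"] >= 1]
    out = out.merge(classes[["patient_id", "mean_class", "var_class"]], on="patient_id", how="inner")
    return out[
        ["patient_id", "period", "mean_class", "var_class", "undetectable", "cd4_monthly_change"]
    ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cell-means design and Table-style contrasts


def _cell_design(outcomes: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Indicator column per observed (mean_class, var_class) cell."""
    cells = sorted(
        set(zip(outcomes["mean_class"].astype(int), outcomes["var_class"].astype(int)))
    )
    if len(cells) < 9:
        warnings.warn(f"only {len(cells)} of 9 class cells are populated; missing cells dropped")
    X = np.zeros((len(outcomes), len(cells)))
    mc = outcomes["mean_class"].to_numpy()
    vc = outcomes["var_class"].to_numpy()
    for k, (m, v) in enumerate(cells):
        X[:, k] = (mc == m) & (vc == v)
    return X, cells


def _contrast_rows(cells: list, mean_labels, var_labels) -> list:
    """Reporting contrasts: each mean class vs the reference mean class at
    High variance, and Low/Moderate vs High variance within each mean class.
    Reference cell = last mean class x last variance class."""
    ref_mc, ref_vc = len(mean_labels), len(var_labels)
    idx = {cell: k for k, cell in enumerate(cells)}
    rows = []

    def contrast(plus, minus):
        c = np.zeros(len(cells))
        c[idx[plus]] += 1.0
        if minus is not None:
            c[idx[minus]] -= 1.0
        return c

    if (ref_mc, ref_vc) in idx:
        rows.append((f"reference ({mean_labels[ref_mc - 1]} x {var_labels[ref_vc - 1]})",
                     contrast((ref_mc, ref_vc), None)))
    for m in range(1, len(mean_labels) + 1):
        if m != ref_mc and (m, ref_vc) in idx and (ref_mc, ref_vc) in idx:
            rows.append((f"{mean_labels[m - 1]} average adherence",
                         contrast((m, ref_vc), (ref_mc, ref_vc))))
        for v in range(1, len(var_labels)):
            if (m, v) in idx and (m, ref_vc) in idx:
                rows.append((f"{var_labels[v - 1]} variance ({mean_labels[m - 1]})",
                             contrast((m, v), (m, ref_vc))))
    return rows


def _effects_frame(rows, estimate_fn, ratio: bool, model: str, level: float = 0.95) -> pd.DataFrame:
    recs = []
    zq = norm.ppf(0.5 + level / 2.0)
    for term, c in rows:
        est, se = estimate_fn(c)
        lo, hi = est - zq * se, est + zq * se
        recs.append(
            {
                "term": term,
                "estimate": est,
                "ratio": float(np.exp(est)) if ratio else np.nan,
                "ci_low": float(np.exp(lo)) if ratio else lo,
                "ci_high": float(np.exp(hi)) if ratio else hi,
                "model": model,
            }
        )
    return pd.DataFrame(recs)


def fit_mixed_logistic(
    outcomes: pd.DataFrame,
    mean_labels=MEAN_CLASS_LABELS,
    var_labels=VAR_CLASS_LABELS,
) -> pd.DataFrame:
    """Undetectable viral load ~ mean class x variance class (+ period RI).

    Returns one row per reporting contrast with odds ratios and 95% CIs;
    the reference cell is the last mean class crossed with the last
    variance class (DrI x High under the default labelling).  The
    reference row reports the cell's own level (log-odds and odds), not a
    ratio; every other row is a contrast against it (mean-class rows) or
    against the High-variance cell of the same mean class (variance rows).
    """
    X, cells = _cell_design(outcomes)
    y = outcomes["undetectable"].to_numpy(dtype=float)
    fit = fit_logit_random_intercept(X, y, outcomes["period"].to_numpy())
    if not fit.converged:
        warnings.warn("mixed logistic fit did not fully converge; estimates from best iterate")
    rows = _contrast_rows(cells, mean_labels, var_labels)

    def est(c):
        e = float(c @ fit.params)
        return e, float(np.sqrt(c @ fit.cov_params @ c))

    return _effects_frame(rows, est, ratio=True, model="mixed_logistic")


def fit_mixed_linear(
    outcomes: pd.DataFrame,
    mean_labels=MEAN_CLASS_LABELS,
    var_labels=VAR_CLASS_LABELS,
) -> pd.DataFrame:
    """Monthly CD4 change ~ mean class x variance class (+ period RI)."""
    import statsmodels.api as sm

    data = outcomes.dropna(subset=["cd4_monthly_change"])
    X, cells = _cell_design(data)
    y = data["cd4_monthly_change"].to_numpy(dtype=float)
    groups = data["period"].to_numpy()
    k = X.shape[1]
    params = cov = None
    if len(np.unique(groups)) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mlm = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        params = np.asarray(mlm.params)[:k]
        cov = np.asarray(mlm.cov_params())[:k, :k]
        # boundary fits (period variance -> 0) leave a junk Hessian; the
        # model then degenerates to OLS, so report that fit instead
        re_var = float(np.asarray(mlm.cov_re).ravel()[0])
        if (
            not np.all(np.isfinite(cov))
            or np.any(np.diag(cov) <= 0)
            or re_var < 1e-8 * max(mlm.scale, 1e-12)
            or np.max(np.diag(cov)) > 1e6 * mlm.scale
        ):
            warnings.warn("period random-intercept variance on the boundary; using OLS")
            params = cov = None
    if params is None:
        ols = sm.OLS(y, X).fit()
        params, cov = np.asarray(ols.params), np.asarray(ols.cov_params())
    rows = _contrast_rows(cells, mean_labels, var_labels)

    def est(c):
        return float(c @ params), float(np.sqrt(c @ cov @ c))

    return _effects_frame(rows, est, ratio=False, model="mixed_linear")


# ---------------------------------------------------------------------------
# survival


def build_survival_episodes(
    moving_points: pd.DataFrame,
    survival: pd.DataFrame,
) -> pd.DataFrame:
    """Monthly counting-process episodes with time-varying adherence covariates.

    Each month ``m`` (from 12, while the patient is at risk) contributes the
    episode ``(m, m+1]`` carrying the moving mean (per 10 points) and the
    standardized variance measured at ``m``; a death at ``T`` marks the
    episode ending at ``T``.  Patients whose follow-up ends at or before
    month 12 have no covariate history and are excluded with a warning.
    """
    surv = survival.set_index("patient_id")
    frames = []
    excluded = []
    for pid, grp in moving_points.groupby("patient_id", sort=True):
        if pid not in surv.index:
            continue
        t_end = int(surv.loc[pid, "time_month"])
        event = int(surv.loc[pid, "event"])
        if t_end <= 12:
            excluded.append(pid)
            continue
        g = grp[(grp["month"] >= 12) & (grp["month"] < t_end)].sort_values("month")
        if g.empty:
            excluded.append(pid)
            continue
        ep = pd.DataFrame(
            {
                "patient_id": pid,
                "start": g["month"].to_numpy(dtype=int),
                "stop": g["month"].to_numpy(dtype=int) + 1,
                "event": 0,
                "moving_mean_per10": g["moving_mean"].to_numpy() / 10.0,
                "std_variance": g["std_variance"].to_numpy(),
            }
        )
        if event == 1 and ep["stop"].iloc[-1] == t_end:
            ep.iloc[-1, ep.columns.get_loc("event")] = 1
        frames.append(ep)
    if excluded:
        warnings.warn(f"{len(excluded)} patients excluded (follow-up ends by month 12)")
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "start", "stop", "event", "moving_mean_per10", "std_variance"]
        )
    return pd.concat(frames, ignore_index=True)


def person_time(episodes: pd.DataFrame) -> float:
    """Total at-risk person-months covered by the episodes."""
    return float((episodes["stop"] - episodes["start"]).sum())


_TERMS = {
    "mean": ["moving_mean_per10"],
    "variance": ["std_variance"],
    "both": ["moving_mean_per10", "std_variance"],
    "interaction": ["moving_mean_per10", "std_variance", "mean_x_variance"],
}


def cox_partial_loglik(
    episodes: pd.DataFrame, covariates: list, beta: np.ndarray, ties: str = "breslow"
) -> float:
    """Explicit counting-process partial log-likelihood (Breslow or Efron)."""
    beta = np.asarray(beta, dtype=float)
    X = episodes[covariates].to_numpy(dtype=float)
    start = episodes["start"].to_numpy(dtype=float)
    stop = episodes["stop"].to_numpy(dtype=float)
    event = episodes["event"].to_numpy(dtype=int)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(stop[event == 1]):
        at_risk = (start < t) & (stop >= t)
        dead = (stop == t) & (event == 1)
        d = int(dead.sum())
        ll += float(eta[dead].sum())
        risk_sum = float(np.exp(eta[at_risk]).sum())
        if ties == "breslow":
            ll -= d * np.log(risk_sum)
        elif ties == "efron":
            tie_sum = float(np.exp(eta[dead]).sum())
            for r in range(d):
                ll -= np.log(risk_sum - r / d * tie_sum)
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return ll


def _cox_newton_breslow(episodes, covariates, max_iter=50, tol=1e-10):
    X = episodes[covariates].to_numpy(dtype=float)
    start = episodes["start"].to_numpy(dtype=float)
    stop = episodes["stop"].to_numpy(dtype=float)
    event = episodes["event"].to_numpy(dtype=int)
    k = X.shape[1]
    beta = np.zeros(k)
    times = np.unique(stop[event == 1])
    for _ in range(max_iter):
        grad = np.zeros(k)
        hess = np.zeros((k, k))
        eta = X @ beta
        w = np.exp(eta)
        for t in times:
            at_risk = (start < t) & (stop >= t)
            dead = (stop == t) & (event == 1)
            d = int(dead.sum())
            Xr, wr = X[at_risk], w[at_risk]
            s0 = wr.sum()
            s1 = wr @ Xr
            s2 = (wr[:, None] * Xr).T @ Xr
            mu = s1 / s0
            grad += X[dead].sum(axis=0) - d * mu
            hess -= d * (s2 / s0 - np.outer(mu, mu))
        step = np.linalg.solve(hess - 1e-10 * np.eye(k), grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    cov = np.linalg.inv(-hess + 1e-12 * np.eye(k))
    return beta, cov


def fit_cox_td(episodes: pd.DataFrame, terms: str = "both", ties: str = "efron") -> pd.DataFrame:
    """Time-dependent Cox model on monthly counting-process episodes.

    ``terms`` selects the covariate set (``mean``, ``variance``, ``both`` or
    ``both + interaction``); hazard ratios are per +1 covariate unit (the
    moving mean enters per 10 adherence points).  Efron tie handling runs
    through lifelines; ``ties='breslow'`` uses the in-package Newton fit on
    the explicit Breslow partial likelihood.
    """
    if terms not in _TERMS:
        raise ValueError(f"terms must be one of {sorted(_TERMS)}")
    if episodes["event"].sum() < 1:
        raise ValueError("no events: the partial likelihood is undefined")
    df = episodes.copy()
    if terms == "interaction":
        df["mean_x_variance"] = df["moving_mean_per10"] * df["std_variance"]
    cols = _TERMS[terms]

    if ties == "efron":
        from lifelines import CoxTimeVaryingFitter

        ctv = CoxTimeVaryingFitter(penalizer=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                df[["patient_id", "start", "stop", "event"] + cols],
                id_col="patient_id",
                event_col="event",
                start_col="start",
                stop_col="stop",
            )
        summ = ctv.summary
        recs = []
        for term in cols:
            recs.append(
                {
                    "term": term,
                    "estimate": float(summ.loc[term, "coef"]),
                    "ratio": float(summ.loc[term, "exp(coef)"]),
                    "ci_low": float(np.exp(summ.loc[term, "coef lower 95%"])),
                    "ci_high": float(np.exp(summ.loc[term, "coef upper 95%"])),
                    "model": f"cox_{terms}",
                }
            )
        return pd.DataFrame(recs)

    if ties != "breslow":
        raise ValueError(f"unknown tie method {ties!r}")
    beta, cov = _cox_newton_breslow(df, cols)
    zq = norm.ppf(0.975)
    recs = []
    for i, term in enumerate(cols):
        se = float(np.sqrt(cov[i, i]))
        recs.append(
            {
                "term": term,
                "estimate": float(beta[i]),
                "ratio": float(np.exp(beta[i])),
                "ci_low": float(np.exp(beta[i] - zq * se)),
                "ci_high": float(np.exp(beta[i] + zq * se)),
                "model": f"cox_{terms}",
            }
        )
    return pd.DataFrame(recs)
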