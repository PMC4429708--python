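"""Outcome stages: six-month outcomes, mixed models, counting-process Cox."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import expit

from adherevar.glmm import _marginal_loglik, fit_logit_random_intercept
from adherevar.outcomes import (
    build_six_month_outcomes,
    build_survival_episodes,
    cox_partial_loglik,
    fit_cox_td,
    fit_mixed_linear,
    fit_mixed_logistic,
    person_time,
)

from conftest import make_frames
from adherevar import CohortConfig


def _classes(pids, mean_class=1, var_class=1):
    return pd.DataFrame({"patient_id": pids, "mean_class": mean_class, "var_class": var_class})


class TestSixMonthOutcomes:
    def test_strict_viral_load_threshold(self):
        visits = pd.DataFrame(
            {"patient_id": [1, 1], "month": [6, 12], "cd4": [300.0, 360.0],
             "viral_load": [999.0, 1000.0]}
        )
        out = build_six_month_outcomes(visits, _classes([1]))
        assert out.loc[out["period"] == 1, "undetectable"].iloc[0] == 1
        assert out.loc[out["period"] == 2, "undetectable"].iloc[0] == 0

    def test_cd4_monthly_change_is_sixth_of_visit_difference(self):
        visits = pd.DataFrame(
            {"patient_id": [1, 1], "month": [6, 12], "cd4": [300.0, 360.0],
             "viral_load": [500.0, 500.0]}
        )
        out = build_six_month_outcomes(visits, _classes([1]))
        assert out.loc[out["period"] == 2, "cd4_monthly_change"].iloc[0] == pytest.approx(10.0)

    def test_baseline_excluded_but_anchors_first_change(self):
        visits = pd.DataFrame(
            {"patient_id": [1, 1], "month": [0, 6], "cd4": [200.0, 230.0],
             "viral_load": [50000.0, 400.0]}
        )
        out = build_six_month_outcomes(visits, _classes([1]))
        assert out["period"].tolist() == [1]
        assert out["cd4_monthly_change"].iloc[0] == pytest.approx(5.0)

    def test_change_requires_consecutive_periods(self):
        visits = pd.DataFrame(
            {"patient_id": [1, 1], "month": [6, 18], "cd4": [300.0, 400.0],
             "viral_load": [500.0, 500.0]}
        )
        out = build_six_month_outcomes(visits, _classes([1]))
        assert np.isnan(out.loc[out["period"] == 3, "cd4_monthly_change"].iloc[0])

    def test_two_visits_in_one_period_keeps_later(self):
        visits = pd.DataFrame(
            {"patient_id": [1, 1], "month": [4, 6], "cd4": [250.0, 300.0],
             "viral_load": [2000.0, 400.0]}
        )
        with pytest.warns(UserWarning, match="two visits"):
            out = build_six_month_outcomes(visits, _classes([1]))
        assert len(out) == 1
        assert out["undetectable"].iloc[0] == 1

    def test_cell_probability_within_binomial_band(self):
        # with the period effect off, the undetectable indicator in the
        # (cH, High) cell is iid Bernoulli(expit(cell logit))
        cfg = CohortConfig(n_patients=300, seed=19, vl_period_sd=0.0, hazard_base=0.0)
        frames = make_frames(cfg)
        truth = frames["truth"].rename(
            columns={"true_mean_class": "mean_class", "true_var_class": "var_class"}
        )
        out = build_six_month_outcomes(frames["visits"], truth)
        cell = out[(out["mean_class"] == 1) & (out["var_class"] == 3)]
        p = expit(np.asarray(cfg.vl_logits)[0, 2])
        n = len(cell)
        assert abs(cell["undetectable"].mean() - p) < 3.0 * np.sqrt(p * (1 - p) / n)


class TestMixedLogistic:
    def test_glmm_likelihood_matches_quadrature_oracle(self):
        rng = np.random.default_rng(2)
        n, G = 400, 8
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        g = rng.integers(0, G, size=n)
        y = (rng.uniform(size=n) < expit(X @ [0.3, 0.8] + 0.6 * rng.normal(size=G)[g])).astype(float)
        params = np.array([0.25, 0.9, np.log(0.5)])
        nodes, weights = hermegauss(25)
        ours = _marginal_loglik(params, X, y, g, G, nodes, np.log(weights))

        tau = np.exp(params[-1])
        oracle = 0.0
        for grp in range(G):
            sel = g == grp
            eta = X[sel] @ params[:2]
            ysel = y[sel]

            def integrand(b):
                p = expit(eta + b)
                lik = np.prod(p**ysel * (1 - p) ** (1 - ysel))
                return lik * np.exp(-(b**2) / (2 * tau**2)) / np.sqrt(2 * np.pi * tau**2)

            val, _ = quad(integrand, -8 * tau, 8 * tau, limit=200)
            oracle += np.log(val)
        # 25-node adaptive quadrature carries ~1e-6 truncation error here
        assert ours == pytest.approx(oracle, abs=1e-5)

    def test_glmm_matches_lme4_glmer_oracle(self, tmp_path):
        rng = np.random.default_rng(7)
        G, npg, tau = 12, 120, 0.5
        rows = []
        for g in range(G):
            b = rng.normal(0, tau)
            x = rng.normal(size=npg)
            y = rng.uniform(size=npg) < expit(-0.4 + 1.1 * x + b)
            rows += [(g, xi, int(yi)) for xi, yi in zip(x, y)]
        df = pd.DataFrame(rows, columns=["g", "x", "y"])
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        fit = fit_logit_random_intercept(X, df["y"].to_numpy(float), df["g"].to_numpy())

        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15)
            co <- summary(m)$coefficients
            cat(co[1,1], co[2,1], co[1,2], co[2,2],
                sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
        """)
        res = subprocess.run(["Rscript", "-"], input=script, text=True, capture_output=True)
        assert res.returncode == 0, res.stderr
        b0, b1, se0, se1, tau_hat, llf = map(float, res.stdout.split())
        assert fit.params[0] == pytest.approx(b0, abs=2e-4)
        assert fit.params[1] == pytest.approx(b1, abs=2e-4)
        assert np.sqrt(fit.cov_params[0, 0]) == pytest.approx(se0, rel=2e-3)
        assert np.sqrt(fit.cov_params[1, 1]) == pytest.approx(se1, rel=2e-3)
        assert fit.tau == pytest.approx(tau_hat, abs=2e-3)
        assert fit.loglik == pytest.approx(llf, abs=1e-3)

    def test_single_period_reduces_to_plain_logistic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 600
        mc = rng.integers(1, 4, n)
        vc = rng.integers(1, 4, n)
        eta = 0.3 + 0.5 * (mc == 1) - 0.4 * (vc == 3)
        out = pd.DataFrame(
            {
                "patient_id": np.arange(n),
                "period": 1,
                "mean_class": mc,
                "var_class": vc,
                "undetectable": (rng.uniform(size=n) < expit(eta)).astype(int),
                "cd4_monthly_change": 0.0,
            }
        )
        eff = fit_mixed_logistic(out)
        # oracle: plain logistic on the same cell indicators
        cells = sorted(set(zip(mc, vc)))
        X = np.column_stack([(mc == m) & (vc == v) for m, v in cells]).astype(float)
        ora = sm.Logit(out["undetectable"], X).fit(disp=0)
        idx = {c: k for k, c in enumerate(cells)}
        c = np.zeros(len(cells))
        c[idx[(1, 3)]], c[idx[(3, 3)]] = 1.0, -1.0
        expected = float(c @ ora.params)
        got = eff.loc[eff["term"] == "cH average adherence", "estimate"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-4)


class TestMixedLinear:
    def test_constant_response_recovered_exactly(self):
        out = pd.DataFrame(
            {
                "patient_id": np.arange(90),
                "period": np.tile([1, 2, 3], 30),
                "mean_class": np.repeat([1, 2, 3], 30),
                "var_class": np.tile([1, 2, 3], 30),
                "undetectable": 0,
                "cd4_monthly_change": 4.2,
            }
        )
        with pytest.warns(UserWarning):
            eff = fit_mixed_linear(out)
        ref = eff.loc[eff["term"].str.startswith("reference"), "estimate"].iloc[0]
        assert ref == pytest.approx(4.2, abs=1e-8)
        contrasts = eff.loc[~eff["term"].str.startswith("reference"), "estimate"]
        np.testing.assert_allclose(contrasts, 0.0, atol=1e-8)


class TestSurvivalEpisodes:
    def _moving(self, pid, months):
        return pd.DataFrame(
            {"patient_id": pid, "month": months,
             "moving_mean": 90.0, "moving_variance": 10.0, "std_variance": 0.1}
        )

    def test_censored_patient_episode_layout(self):
        mov = self._moving(1, [12, 13])
        surv = pd.DataFrame({"patient_id": [1], "time_month": [14], "event": [0]})
        ep = build_survival_episodes(mov, surv)
        assert ep[["start", "stop"]].to_numpy().tolist() == [[12, 13], [13, 14]]
        assert ep["event"].sum() == 0

    def test_death_marks_last_episode(self):
        mov = self._moving(1, [12])
        surv = pd.DataFrame({"patient_id": [1], "time_month": [13], "event": [1]})
        ep = build_survival_episodes(mov, surv)
        assert ep[["start", "stop", "event"]].to_numpy().tolist() == [[12, 13, 1]]

    def test_early_death_excluded_with_warning(self):
        mov = self._moving(1, [12])
        surv = pd.DataFrame({"patient_id": [1], "time_month": [12], "event": [1]})
        with pytest.warns(UserWarning, match="excluded"):
            ep = build_survival_episodes(mov, surv)
        assert len(ep) == 0

    def test_person_time_and_events_conserved(self):
        from adherevar.moving import moving_mean_variance, standardize_variances

        frames = make_frames(CohortConfig(n_patients=50, seed=23))
        mov = moving_mean_variance(frames["adherence"])
        mov, _ = standardize_variances(mov)
        ep = build_survival_episodes(mov, frames["survival"])
        surv = frames["survival"]
        included = surv[surv["time_month"] > 12]
        expected = (included["time_month"].clip(upper=108) - 12).sum()
        assert person_time(ep) == pytest.approx(float(expected))
        assert ep["event"].sum() == included["event"].sum()
        # episodes contiguous and non-overlapping per patient
        for _, grp in ep.groupby("patient_id"):
            g = grp.sort_values("start")
            assert (g["stop"].to_numpy()[:-1] == g["start"].to_numpy()[1:]).all()
            assert (g["event"].to_numpy()[:-1] == 0).all()


class TestCoxTd:
    def _toy_episodes(self):
        # three patients, constant covariates, one death at t=20 for the
        # middle covariate -> finite partial-likelihood maximum
        return pd.DataFrame(
            {
                "patient_id": [1, 2, 3],
                "start": [12, 12, 12],
                "stop": [20, 30, 25],
                "event": [1, 0, 0],
                "moving_mean_per10": [1.0, 0.0, 2.0],
                "std_variance": [0.0, 0.0, 0.0],
            }
        )

    def test_partial_likelihood_maximum_matches_grid_oracle(self):
        ep = self._toy_episodes()
        # oracle: maximize the explicit one-event partial likelihood
        # l(b) = b*1 - log(e^0 + e^b + e^2b)
        res = minimize_scalar(
            lambda b: -(b - np.log(1 + np.exp(b) + np.exp(2 * b))),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-12},
        )
        fit_b = fit_cox_td(ep, terms="mean", ties="breslow")
        assert fit_b["estimate"].iloc[0] == pytest.approx(res.x, abs=1e-6)
        fit_e = fit_cox_td(ep, terms="mean", ties="efron")
        assert fit_e["estimate"].iloc[0] == pytest.approx(res.x, abs=1e-4)

    def test_partial_loglik_evaluator_agrees_with_closed_form(self):
        ep = self._toy_episodes()
        for b in (-0.5, 0.0, 0.7):
            expected = b - np.log(1 + np.exp(b) + np.exp(2 * b))
            got = cox_partial_loglik(ep, ["moving_mean_per10"], np.array([b]))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_breslow_and_efron_agree_without_ties(self):
        rng = np.random.default_rng(3)
        frames = make_frames(CohortConfig(n_patients=150, seed=41))
        from adherevar.moving import moving_mean_variance, standardize_variances

        mov = moving_mean_variance(frames["adherence"])
        mov, _ = standardize_variances(mov)
        ep = build_survival_episodes(mov, frames["survival"])
        fe = fit_cox_td(ep, terms="both", ties="efron")
        fb = fit_cox_td(ep, terms="both", ties="breslow")
        # monthly grid has few ties at this size; methods nearly coincide
        np.testing.assert_allclose(fe["estimate"], fb["estimate"], atol=0.05)

    def test_no_events_is_an_error(self):
        ep = self._toy_episodes()
        ep["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cox_td(ep)

    def test_unknown_terms_rejected(self):
        with pytest.raises(ValueError):
            fit_cox_td(self._toy_episodes(), terms="bogus")
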