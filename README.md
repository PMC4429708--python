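# adherevar

Tools for studying how the **level** and the **variability** of adherence to
HIV antiretroviral therapy relate to virological response, immune recovery
and mortality in a long-running treatment cohort — implemented as a tested,
reusable pipeline and exercised end to end on a synthetic cohort generator
with known ground truth.

## The problem and the method

Monthly pill-count adherence `y_it ∈ [0, 100]` is summarized, from month 12
on, by a 12-month moving average `m_it` and moving variance `v_it`.  Because
a high average mechanically forces a low variance, the raw variance carries
little information beyond the mean.  The package therefore computes a
**standardized variance**: patient-months are pooled, sorted by moving mean,
cut into consecutive bins of ~30 points, and within each bin the variance
with rank `k` among `n_c` maps to

    z = Φ⁻¹( k / (1 + n_c) )

— a variance measure decorrelated from the mean by construction.

Typical adherence histories are extracted with a **latent-class trajectory
model**: a 3-component mixture of Gaussian linear mixed models in which
class `j` has mean curve `f^j(t) = Xβ_j` on a linear-spline basis
`[1, t, (t−12)₊, (t−24)₊, …, (t−96)₊]`, with a patient-level random
intercept and random slope (`b_i ~ N(0, D)`) and residual variance σ².  The
marginal mixture likelihood is maximized by EM (closed-form posterior
E-step; weighted GLS for β; numerical update of `D, σ`; best of several
seeded restarts), and each patient is classified by the **maximum a
posteriori** rule.  The same machinery fits the standardized-variance
trajectories, giving low / moderate / high variability classes.

Three association stages link adherence to outcomes:

* mixed **logistic** regression of the six-monthly undetectable viral-load
  indicator (< 1000 copies/mL) on mean class × variance class with a
  six-month-period random intercept (adaptive Gauss–Hermite ML);
* mixed **linear** regression of the monthly CD4 change
  ((CD4_p − CD4_{p−1})/6, cells/mm³/month) with the same structure;
* a **time-dependent Cox model** on monthly counting-process episodes
  `(m, m+1]` carrying the current moving mean (per 10 points) and
  standardized variance, so `HR = exp(β)` per covariate unit.

The synthetic cohort generator simulates all of this forward: three mean
trajectory archetypes (constantly high; high, slowly decreasing; decreasing
then rapidly increasing), three noise strata, six-monthly labs whose cell
means encode known odds ratios and CD4 slopes, and a discrete monthly death
hazard `h_t = h₀ · exp(β_m m_t/10 + β_z z_t)` — ground truth for every
recovery test.

## Worked example

```python
import numpy as np
from adherevar import (CohortConfig, generate_cohort, moving_mean_variance,
                       standardize_variances, fit_lcmm, relabel_classes,
                       map_classify)
from adherevar.synthetic import cohort_to_frames
from adherevar.outcomes import (build_survival_episodes, fit_cox_td)

frames = cohort_to_frames(generate_cohort(CohortConfig(n_patients=317, seed=1)))
mov = moving_mean_variance(frames["adherence"])
mov, _ = standardize_variances(mov)
print(round(mov["std_variance"].min(), 2), round(mov["std_variance"].max(), 2))
# -1.85 1.85       <- the z range implied by rank k/(1+30) in bins of ~30

model, post = fit_lcmm(mov.rename(columns={"moving_mean": "y"}),
                       n_classes=3, n_starts=4, seed=2)
model, post = relabel_classes(model, post)   # class 1 = highest curve
print(np.round(model.class_weights * 100, 1))
# [67.1 17.4 15.5]  <- % of patients on the constantly-high / declining /
#                      dipping-recovering trajectories

ep = build_survival_episodes(mov, frames["survival"])
print(fit_cox_td(ep, terms="both")[["term", "ratio"]])
#                 term     ratio
# 0  moving_mean_per10  0.783833
# 1       std_variance  1.719296
# each 10-point rise in the moving mean lowers the death hazard ~22%
# (true effect 27%), and each unit of standardized variance raises it
# (true effect +45%); both are single-cohort estimates at 56 events
```

The same stages run from the shell:

```bash
adherevar all --seed 1 --outdir run     # simulate → moving → trajectories →
                                        # outcomes → report (+ manifest)
```

which writes `table1.csv` (mean-class × variance-class cross-tabulation),
`effects.csv` (odds ratios, CD4 slopes, hazard ratios with 95% CIs),
trajectory tables/figures and a hash manifest; identical seeds give
identical files.

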