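# Methods

## Moving statistics

For each patient, from month 12 onward, the moving mean and moving sample
variance (denominator n−1) of the previous 12 monthly adherence values are
computed on the calendar grid.  A point is emitted only when all 12 months
of the window are observed (complete-window rule); a `min_obs` switch allows
k-of-12 windows for gappy data.  The complete-window default keeps the
statistic's meaning uniform across patients; relaxing it mixes window sizes
into one statistic.

## Standardized variance

All patient-months are pooled, stably sorted by moving mean and cut into
`K = max(1, round(N/30))` consecutive bins; the remainder after integer
division is spread one-per-bin from the first bin, so every bin holds
"nearly 30" points for any N.  Within a bin of size `n_c`, the variance with
rank `k` (average ranks on ties) maps to `Φ⁻¹(k/(1+n_c))`.  Consequences
used as test oracles:

* the multiset of z values within a bin is fixed, so z is independent of
  the bin's mean level — the Spearman correlation between moving mean and
  standardized variance is ~0 by construction;
* |z| ≤ Φ⁻¹(n_max/(1+n_max)); with bins of 30 that is ±1.849, which is why
  standardized variances live essentially in [−1.85, 1.85];
* within a bin, z is monotone in the raw variance.

The fitted bin map (`StandardizationMap`) is serializable and can
standardize held-out points: a point joins the bin whose mean interval
contains it (boundary bins absorb points outside the training range), and
its variance is ranked against the bin's training variances.

Ties in means are resolved by stable sort; whether tied means could straddle
bin boundaries differently in other implementations is undecidable, but the
rule here is deterministic.  Alternative de-trendings of the variance
(regression residuals, coefficient of variation) are deliberately not
implemented.

## Latent-class trajectory model

Patient `i` belongs to latent class `j` with probability `π_j`; given the
class,

    y_i ~ N(X_i β_j, Z_i D Z_i' + σ² I),

where `X_i` stacks rows `[1, t, h_12(t), …, h_96(t)]` with hinge functions
`h_T(t) = max(0, t − T)` at 12-month knots, and `Z_i = [1, t]`.  The hinge
(linear-spline) basis is the minimal form that allows inflexion points at
yearly resolution; the basis is pluggable (`BasisConfig`).  `D` (2×2, free
correlation) and σ are shared across classes: sharing stabilizes EM with
three classes of very different sizes; a class-specific σ was considered
and rejected as an invitation to variance-collapse spikes.

Estimation is EM on the marginal mixture likelihood:

* E-step: `p_ij ∝ π_j N(y_i; X_i β_j, V_i)`, computed with the Woodbury
  identity from per-patient sufficient statistics (X'X, X'y, y'y), so the
  cost per iteration does not grow with months per patient;
* M-step: `π_j` = posterior means; `β_j` by posterior-weighted GLS;
  `(D, σ)` by L-BFGS-B on the expected complete-data log-likelihood in a
  log-Cholesky parameterization (σ floored at 1e-4; an update is accepted
  only if it improves the objective, preserving EM monotonicity).

Convergence: relative log-likelihood change < 1e-6 (default) or 500
iterations; the trace is recorded and checked for monotonicity.
Initialization clusters per-patient OLS intercept/slope coefficients
(k-means); restarts perturb the coefficients before clustering; the best
final likelihood wins.  The initial random-effect variance is the
within-cluster spread of those coefficients — seeding it with the total
spread lets the random intercept swallow the class separation at the
starting point.  For a single class the final fit is polished by direct
profile-likelihood maximization (β profiled out by GLS), which makes the
J=1 fit agree with a standard linear-mixed-model ML fit to ~1e-5.

MAP classification takes the row argmax (ties to the lowest index).
Typical trajectories are reported both as the posterior-weighted mean of
per-patient class-j predictions and as the fixed-effect curve; with shared
fixed effects the two coincide.  Classes are relabelled for reporting by
curve level at month 12 (descending for adherence means, ascending for
standardized variances, so class 1 reads cH / Low).

## Outcome models

Visits at month m belong to six-month period `ceil(m/6)`; the baseline
visit (month 0) is excluded as an outcome but anchors the first CD4 change.
Undetectable viral load is strictly `< 1000` copies/mL.  The CD4 change
between consecutive periods is divided by 6 to a monthly rate.

Both regressions use a full mean-class × variance-class interaction via
cell-means coding with reference cell DrI × High; reported terms are the
published-table contrasts (each mean class vs DrI at High variance;
Low/Moderate vs High within each mean class), with the reference row
reporting the cell's own level.  The logistic model carries a six-month
period random intercept, fitted by adaptive Gauss–Hermite maximum
likelihood written for this package (no frequentist GLMM exists in the
Python stack used); it matches lme4's `glmer` (nAGQ=15) to ~1e-4 on a test
fixture.  The linear model delegates to statsmodels MixedLM (ML); when the
period variance collapses to the boundary the model degenerates to OLS and
is reported as such.  The "six-month" random intercept is read as the
calendar period index shared across patients; a patient-level intercept is
a plausible alternative reading not implemented.

Survival uses monthly counting-process episodes `(m, m+1]` from month 12
(late entry: moving covariates do not exist earlier; where the original
analysis started its risk set is unstated) carrying that month's moving
mean / 10 and standardized variance; a death at T marks the episode ending
at T.  Fitting delegates to lifelines `CoxTimeVaryingFitter` (Efron ties,
the default appropriate to the monthly grid); a Newton fit on the explicit
Breslow partial likelihood is available by flag and doubles as the oracle
in tests.  Univariate, multivariate and mean×variance-interaction
covariate sets are supported.

## Synthetic cohort generator

Defaults encode the study conditions: 317 patients, 108 months, mean-class
shares (0.697, 0.170, 0.133), variance-stratum shares (0.226, 0.489,
0.285), piecewise-linear mean curves (cH flat 95%; HsD 90% to month 48
declining to 65% by month 84 with a final-year rise; DrI 80% falling to 48%
by month 36 and recovering to 90%), hazard log-linear in the moving mean
(log 0.73 per 10 points) and standardized variance (log 1.45 per unit), and
lab-outcome cell parameters whose implied odds ratios (2.91, 2.88, …) and
CD4 slope contrasts (4.70, 4.28, 2.79, …) are the recovery targets.

Values the source conditions do not pin down are calibration choices:
monthly noise SDs (3.5, 7, 12)% by variance stratum; patient-level random
intercept SD 2%; baseline hazard 0.03/month at covariates zero, chosen
analytically so a typical profile yields roughly one death in six over the
follow-up (observed ~15–18% across seeds); reference-cell undetectable
logit 0.4; CD4 baseline N(230, 80) cells/mm³, period effect SD 1.0 and
residual SD 4.0 cells/mm³/month on the monthly change; viral-load
magnitudes log-uniform on either side of the threshold.  One master seed
drives per-patient sub-streams (stable under appending patients) plus a
cohort-level stream for shared period effects.  Survival is simulated on
the monthly grid — death in `(m, m+1]` with probability `1 − exp(−h_m)` —
because the covariates update monthly; the survivor-driven late rise of the
HsD curve emerges from the hazard rather than being hard-coded.  Adherence
is clipped to [0, 100] after noise addition, which biases class means
slightly toward the interior near the boundaries (a few tenths of a point
at 95% with moderate noise, up to ~3 points under the high-noise stratum);
recovery tests of class-conditional means therefore use curves away from
the boundaries.

### What the generator does and does not emulate

It reproduces the latent structure the analysis assumes — trajectory
archetypes, variability strata, outcome cell means, a proportional-hazards
death process on the true covariate paths.  It does not emulate staggered
entry or informative dropout (censoring is administrative at 108 months),
drug-specific adherence, missing visits, or serial correlation in the lab
outcomes.  Passing recovery tests therefore shows the estimators recover
the parameters of a correctly specified generating process at realistic
sample sizes; it does not validate the substantive findings on real data.

### A known, instructive limitation

Standardized-variance values of one patient are strongly serially
correlated (consecutive 12-month windows share 11 months).  The trajectory
mixture assumes iid residuals given the random effects, and on synthetic
monthly z data its maximum-likelihood solution prefers using the three
class curves as fluctuation templates (reducing σ² across ~27,000
observations) over separating the three patient-level strata: the collapsed
fit beats the truth-separated fit by ~1,300 log-likelihood units, and EM
started from the true classification converges to the same collapse.  MAP
variance classes on such data are therefore not a reliable recovery of the
noise strata (mean-adherence classes, separated by curve shape, are
recovered at ~98%).  This is a property of the model class, not of the
optimizer; analyses of real data with this model may face the same
identification issue.  For this reason the outcome-model recovery tests
condition on ground-truth classes, and the acceptance script reports the
variance-class MAP agreement honestly rather than hiding it.

## Problem sizes and numerical choices

Unit tests run cohorts of 40–400 patients; the acceptance suite uses a
300-patient well-separated cohort for trajectory recovery, 20 seeded
317-patient replicates for calibrated outcome recovery (bands are the
replicate mean ± 1.96 SD) and 10 replicates for the null generator; the
acceptance script analyzes one 317-patient cohort with 4 EM restarts.
Tie-breaks: stable sorts throughout; MAP ties to the lowest class;
degenerate inputs (empty cohorts, single periods, constant responses,
boundary variance fits) fall back to the exact special case and warn.
Floats round-trip through CSV exactly (`float_precision="round_trip"` on
read).
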