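"""Synthetic longitudinal HIV-therapy cohort generator.

Emulates a West-African antiretroviral-therapy cohort of ~317 patients
followed monthly for up to 108 months: monthly pill-count adherence (%),
six-monthly CD4 counts and viral loads, and death times.  The latent
structure matches what the downstream analysis assumes —

* three mean-adherence trajectory archetypes: constantly high (cH),
  high but slowly decreasing (HsD), decreasing then rapidly increasing
  (DrI), drawn independently of
* three adherence-variability strata (low / moderate / high monthly
  noise SD around the class curve);
* six-monthly lab outcomes whose cell means depend on the (mean class,
  variance class) pair;
* a discrete monthly death hazard, from month 12 on, log-linear in the
  patient's current 12-month moving mean (per 10 adherence points) and
  population-standardized moving variance.

The generator is the ground truth for every recovery test downstream:
its defaults are the study conditions, not tuning knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .moving import moving_mean_variance, standardize_variances

__all__ = [
    "CohortConfig",
    "SimulatedPatient",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_to_frames",
    "MEAN_CLASS_LABELS",
    "VAR_CLASS_LABELS",
]

MEAN_CLASS_LABELS = ("cH", "HsD", "DrI")
VAR_CLASS_LABELS = ("Low", "Moderate", "High")

# Piecewise-linear mean curves (month, adherence %), one per mean class.
# cH flat at 95; HsD high to month 48 then declining to 65 by month 84 with
# a survivor-driven rise over the last year; DrI dropping from 80 to below
# 50 by month 36 then recovering to 90 by month 84.
DEFAULT_MEAN_CURVES = (
    ((0, 95.0), (108, 95.0)),
    ((0, 90.0), (48, 90.0), (84, 65.0), (96, 65.0), (108, 85.0)),
    ((0, 80.0), (12, 80.0), (36, 48.0), (84, 90.0), (108, 90.0)),
)

_LN = math.log
# Undetectable-viral-load cell logits, rows = mean class (cH, HsD, DrI),
# cols = variance class (Low, Moderate, High).  Anchored at 0.4 for the
# DrI x High reference cell; offsets are the log odds-ratios the analysis
# should recover (cH vs DrI log-OR = ln 2.91, etc.).
DEFAULT_VL_LOGITS = (
    (0.4 + _LN(2.91) + _LN(1.82), 0.4 + _LN(2.91) + _LN(1.76), 0.4 + _LN(2.91)),
    (0.4 + _LN(2.88) + _LN(1.71), 0.4 + _LN(2.88) + _LN(0.69), 0.4 + _LN(2.88)),
    (0.4 + _LN(1.73), 0.4 + _LN(1.28), 0.4),
)

# Monthly CD4 slope (cells/mm3/month) per (mean class, variance class) cell;
# the cH-vs-DrI main contrast is 4.70 and DrI's High-to-Low contrast 2.79.
DEFAULT_CD4_SLOPES = (
    (5.50, 4.41, 4.74),
    (6.52, 3.91, 4.32),
    (2.83, 2.47, 0.04),
)


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Hazard defaults encode a 27% mortality reduction per 10 adherence
    points (log 0.73) and a 45% increase per unit standardized variance
    (log 1.45); ``hazard_base`` is the monthly rate at moving mean 0 and
    standardized variance 0, calibrated so that a typical patient profile
    yields roughly one death in six over nine years of follow-up.
    """

    n_patients: int = 317
    max_month: int = 108
    mean_class_probs: tuple = (0.697, 0.170, 0.133)
    var_class_probs: tuple = (0.226, 0.489, 0.285)
    mean_curves: tuple = DEFAULT_MEAN_CURVES
    noise_sd_by_var_class: tuple = (3.5, 7.0, 12.0)
    patient_intercept_sd: float = 2.0
    visit_interval: int = 6
    cd4_baseline_mean: float = 230.0
    cd4_baseline_sd: float = 80.0
    cd4_slope_matrix: tuple = DEFAULT_CD4_SLOPES
    cd4_period_sd: float = 1.0
    cd4_resid_sd: float = 4.0
    vl_logits: tuple = DEFAULT_VL_LOGITS
    vl_period_sd: float = 0.3
    hazard_base: float = 0.03
    log_hr_mean_per_10pct: float = _LN(0.73)
    log_hr_stdvar_per_unit: float = _LN(1.45)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_class_probs", "var_class_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigurationError(f"{name} must be 3 non-negative values summing to 1")
        sds = np.asarray(self.noise_sd_by_var_class, dtype=float)
        if sds.shape != (3,) or np.any(sds < 0):
            raise ConfigurationError("noise_sd_by_var_class must be 3 non-negative SDs")
        if np.any(sds[:-1] > sds[1:]):
            raise ConfigurationError("noise SDs must be non-decreasing (low <= moderate <= high)")
        if self.max_month <= 12:
            raise ConfigurationError("max_month must exceed 12")
        if self.visit_interval < 1:
            raise ConfigurationError("visit_interval must be >= 1")
        if self.hazard_base < 0:
            raise ConfigurationError("hazard_base must be non-negative")
        for curve in self.mean_curves:
            vals = np.asarray([v for _, v in curve], dtype=float)
            if np.any(vals < 0) or np.any(vals > 100):
                raise ConfigurationError("adherence curves must be valued in [0, 100]")


@dataclass
class SimulatedPatient:
    """One simulated patient with ground-truth class labels.

    Exactly one of ``death_month`` / ``censor_month`` is set; no adherence
    or visit observation lies after the follow-up end.
    """

    patient_id: int
    true_mean_class: int
    true_var_class: int
    adherence: pd.DataFrame  # columns: month, adherence
    visits: pd.DataFrame  # columns: month, cd4, viral_load
    death_month: int | None
    censor_month: int | None

    @property
    def followup_end(self) -> int:
        return self.death_month if self.death_month is not None else self.censor_month

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulatedPatient):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.true_mean_class == other.true_mean_class
            and self.true_var_class == other.true_var_class
            and self.death_month == other.death_month
            and self.censor_month == other.censor_month
            and self.adherence.reset_index(drop=True).equals(other.adherence.reset_index(drop=True))
            and self.visits.reset_index(drop=True).equals(other.visits.reset_index(drop=True))
        )


def _curve_values(curve, months: np.ndarray) -> np.ndarray:
    pts = np.asarray(curve, dtype=float)
    return np.interp(months, pts[:, 0], pts[:, 1])


def _patient_rng(seed: int, i: int) -> np.random.Generator:
    # stable per-patient sub-streams: appending patients never perturbs
    # the draws of existing ones
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 1, i))))


def _cohort_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 0))))


def generate_cohort(config: CohortConfig) -> list[SimulatedPatient]:
    """Simulate a cohort under ``config``; reproducible given ``config.seed``.

    Adherence is simulated on the full month grid first; the death hazard is
    then integrated monthly from month 12 along each patient's moving-mean /
    standardized-variance path, and all observations after death are dropped.
    """
    n, last = config.n_patients, config.max_month
    months = np.arange(1, last + 1)
    sds = np.asarray(config.noise_sd_by_var_class, dtype=float)

    mean_classes = np.empty(n, dtype=int)
    var_classes = np.empty(n, dtype=int)
    adherence = np.empty((n, last), dtype=float)
    death_u = np.empty(n, dtype=float)
    rngs = []
    for i in range(n):
        rng = _patient_rng(config.seed, i)
        mc = int(rng.choice(3, p=config.mean_class_probs))
        vc = int(rng.choice(3, p=config.var_class_probs))
        intercept = rng.normal(0.0, config.patient_intercept_sd)
        eps = rng.normal(0.0, 1.0, size=last) * sds[vc]
        adherence[i] = np.clip(_curve_values(config.mean_curves[mc], months) + intercept + eps, 0.0, 100.0)
        death_u[i] = rng.uniform()
        mean_classes[i], var_classes[i] = mc + 1, vc + 1
        rngs.append(rng)

    # population moving stats on the full (pre-death) grid drive the hazard
    adf = pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(1, n + 1), last),
            "month": np.tile(months, n),
            "adherence": adherence.ravel(),
        }
    )
    mov = moving_mean_variance(adf)
    mov, _ = standardize_variances(mov)
    mov_mean = mov.pivot(index="patient_id", columns="month", values="moving_mean").to_numpy()
    mov_z = mov.pivot(index="patient_id", columns="month", values="std_variance").to_numpy()
    hazard_months = np.arange(12, last)  # hazard over (m, m+1], m = 12..last-1
    col = hazard_months - 12  # moving stats start at month 12

    # monthly hazard and inverse-cdf death draw
    loghr = (
        config.log_hr_mean_per_10pct * mov_mean[:, col] / 10.0
        + config.log_hr_stdvar_per_unit * mov_z[:, col]
    )
    hazard = config.hazard_base * np.exp(loghr)
    surv = np.exp(-np.cumsum(hazard, axis=1))

    rng_c = _cohort_rng(config.seed)
    n_periods = last // config.visit_interval
    vl_period_eff = rng_c.normal(0.0, config.vl_period_sd, size=n_periods)
    cd4_period_eff = rng_c.normal(0.0, config.cd4_period_sd, size=n_periods)

    vl_logits = np.asarray(config.vl_logits, dtype=float)
    cd4_slopes = np.asarray(config.cd4_slope_matrix, dtype=float)

    patients = []
    for i in range(n):
        died = surv[i] < death_u[i]
        if died.any():
            death_month = int(hazard_months[np.argmax(died)] + 1)
            censor_month = None
            end = death_month
        else:
            death_month = None
            censor_month = last
            end = last
        rng = rngs[i]
        mc, vc = mean_classes[i] - 1, var_classes[i] - 1

        cd4 = max(rng.normal(config.cd4_baseline_mean, config.cd4_baseline_sd), 10.0)
        visit_rows = [(0, cd4, 10.0 ** rng.uniform(4.0, 5.7))]
        m = config.visit_interval
        while m <= end:
            p = m // config.visit_interval - 1
            delta = cd4_slopes[mc, vc] + cd4_period_eff[p] + rng.normal(0.0, config.cd4_resid_sd)
            cd4 = cd4 + config.visit_interval * delta
            eta = vl_logits[mc, vc] + vl_period_eff[p]
            undet = rng.uniform() < 1.0 / (1.0 + math.exp(-eta))
            vl = 10.0 ** rng.uniform(1.7, 2.99) if undet else 10.0 ** rng.uniform(3.0, 5.5)
            visit_rows.append((m, cd4, vl))
            m += config.visit_interval

        patients.append(
            SimulatedPatient(
                patient_id=i + 1,
                true_mean_class=int(mean_classes[i]),
                true_var_class=int(var_classes[i]),
                adherence=pd.DataFrame(
                    {"month": months[:end], "adherence": adherence[i, :end]}
                ),
                visits=pd.DataFrame(visit_rows, columns=["month", "cd4", "viral_load"]),
                death_month=death_month,
                censor_month=censor_month,
            )
        )
    return patients


def cohort_to_frames(patients: list[SimulatedPatient]) -> dict[str, pd.DataFrame]:
    """Long-format tables (adherence, visits, survival, truth) for a cohort."""
    if not patients:
        return {
            "adherence": pd.DataFrame(columns=["patient_id", "month", "adherence"]),
            "visits": pd.DataFrame(columns=["patient_id", "month", "cd4", "viral_load"]),
            "survival": pd.DataFrame(columns=["patient_id", "time_month", "event"]),
            "truth": pd.DataFrame(columns=["patient_id", "true_mean_class", "true_var_class"]),
        }
    adh = pd.concat(
        [p.adherence.assign(patient_id=p.patient_id) for p in patients], ignore_index=True
    )[["patient_id", "month", "adherence"]]
    vis = pd.concat(
        [p.visits.assign(patient_id=p.patient_id) for p in patients], ignore_index=True
    )[["patient_id", "month", "cd4", "viral_load"]]
    surv = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "time_month": [p.followup_end for p in patients],
            "event": [1 if p.death_month is not None else 0 for p in patients],
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "true_mean_class": [p.true_mean_class for p in patients],
            "true_var_class": [p.true_var_class for p in patients],
        }
    )
    return {"adherence": adh, "visits": vis, "survival": surv, "truth": truth}


_FILES = {
    "adherence": "adherence.csv",
    "visits": "visits.csv",
    "survival": "survival.csv",
    "truth": "truth.csv",
}


def write_cohort(patients: list[SimulatedPatient], outdir: str | Path) -> dict[str, Path]:
    """Write adherence.csv, visits.csv, survival.csv and the ground-truth
    sidecar truth.csv under ``outdir``; deterministic row order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = cohort_to_frames(patients)
    paths = {}
    for key, fname in _FILES.items():
        df = frames[key]
        sort_cols = [c for c in ("patient_id", "month") if c in df.columns]
        df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True) if len(df) else df
        path = outdir / fname
        df.to_csv(path, index=False)
        paths[key] = path
    return paths


def _read_csv(path: Path, numeric_cols: dict[str, type]) -> pd.DataFrame:
    if not path.exists():
        raise ConfigurationError(f"missing input file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(numeric_cols) - set(df.columns)
    if missing:
        raise DataError(f"{path.name}: missing columns {sorted(missing)}")
    for colname, typ in numeric_cols.items():
        col = pd.to_numeric(df[colname], errors="coerce")
        bad = col.isna() & df[colname].notna()
        if bad.any() or df[colname].isna().any():
            row = int(np.flatnonzero(col.isna())[0])
            raise DataError(f"{path.name}: non-numeric or missing {colname!r} at data row {row}")
        df[colname] = col.astype(typ)
    return df


def read_cohort(indir: str | Path) -> list[SimulatedPatient]:
    """Inverse of :func:`write_cohort`; validates and reassembles patients."""
    indir = Path(indir)
    adh = _read_csv(indir / _FILES["adherence"], {"patient_id": int, "month": int, "adherence": float})
    vis = _read_csv(indir / _FILES["visits"], {"patient_id": int, "month": int, "cd4": float, "viral_load": float})
    surv = _read_csv(indir / _FILES["survival"], {"patient_id": int, "time_month": int, "event": int})
    truth = _read_csv(indir / _FILES["truth"], {"patient_id": int, "true_mean_class": int, "true_var_class": int})

    dup = adh.duplicated(subset=["patient_id", "month"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(f"adherence.csv: duplicated patient-month at data row {row}")
    if ((adh["adherence"] < 0) | (adh["adherence"] > 100)).any():
        row = int(np.flatnonzero(((adh["adherence"] < 0) | (adh["adherence"] > 100)).to_numpy())[0])
        raise DataError(f"adherence.csv: adherence outside [0, 100] at data row {row}")

    surv = surv.set_index("patient_id")
    truth = truth.set_index("patient_id")
    patients = []
    for pid in surv.index:
        event = int(surv.loc[pid, "event"])
        time = int(surv.loc[pid, "time_month"])
        patients.append(
            SimulatedPatient(
                patient_id=int(pid),
                true_mean_class=int(truth.loc[pid, "true_mean_class"]),
                true_var_class=int(truth.loc[pid, "true_var_class"]),
                adherence=adh.loc[adh["patient_id"] == pid, ["month", "adherence"]].reset_index(drop=True),
                visits=vis.loc[vis["patient_id"] == pid, ["month", "cd4", "viral_load"]].reset_index(drop=True),
                death_month=time if event == 1 else None,
                censor_month=None if event == 1 else time,
            )
        )
    return patients
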