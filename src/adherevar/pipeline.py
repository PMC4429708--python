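"""Stage orchestration: simulate -> moving -> trajectories -> outcomes -> report.

Each stage reads its inputs from, and writes its outputs to, a single run
directory of plain-text files, so stages can be re-run independently.  A run
manifest records a SHA-256 hash of every file written; identical
configuration and seed give identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .moving import moving_mean_variance, standardize_variances
from .outcomes import (
    build_six_month_outcomes,
    build_survival_episodes,
    fit_cox_td,
    fit_mixed_linear,
    fit_mixed_logistic,
)
from .synthetic import (
    MEAN_CLASS_LABELS,
    VAR_CLASS_LABELS,
    CohortConfig,
    generate_cohort,
    write_cohort,
)
from .trajectories import (
    BasisConfig,
    fit_lcmm,
    map_classify,
    relabel_classes,
    typical_trajectory,
)

__all__ = ["PipelineConfig", "run_pipeline", "cross_tabulate", "CrossTabulation", "load_config"]

logger = logging.getLogger("adherevar")

ALL_STAGES = ("simulate", "moving", "trajectories", "outcomes", "report")


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    cohort: dict = field(default_factory=dict)
    window: int = 12
    target_class_size: int = 30
    n_classes: int = 3
    knots: tuple = (12, 24, 36, 48, 60, 72, 84, 96)
    n_starts: int = 4
    tol: float = 1e-6
    max_iter: int = 300
    vl_threshold: float = 1000.0
    ties: str = "efron"
    cox_terms: tuple = ("both",)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stages", "knots", "cox_terms"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


@dataclass
class CrossTabulation:
    """Counts and percentages of patients over variance x mean classes."""

    counts: pd.DataFrame  # rows: variance classes, cols: mean classes
    row_pct: pd.DataFrame  # cell / row total, in percent
    col_pct: pd.DataFrame  # cell / column total, in percent
    row_total_pct: pd.Series  # row total / grand total
    col_total_pct: pd.Series
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy long layout for CSV output."""
        rows = []
        for vr in self.counts.index:
            for mc in self.counts.columns:
                rows.append(
                    {
                        "var_class": vr,
                        "mean_class": mc,
                        "count": int(self.counts.loc[vr, mc]),
                        "row_pct": self.row_pct.loc[vr, mc],
                        "col_pct": self.col_pct.loc[vr, mc],
                    }
                )
        return pd.DataFrame(rows)


def cross_tabulate(
    assignments_mean: pd.DataFrame,
    assignments_variance: pd.DataFrame,
    mean_labels=MEAN_CLASS_LABELS,
    var_labels=VAR_CLASS_LABELS,
) -> CrossTabulation:
    """3x3 patient cross-tabulation of mean-trajectory vs variance classes.

    Percentages are rounded to 2 decimals; both inputs must cover exactly
    the same patients.
    """
    a = assignments_mean.set_index("patient_id")["map_class"]
    b = assignments_variance.set_index("patient_id")["map_class"]
    sym = set(a.index).symmetric_difference(b.index)
    if sym:
        raise ConfigurationError(f"mismatched patient sets; symmetric difference: {sorted(sym)}")
    mean_named = a.map(lambda j: mean_labels[int(j) - 1])
    var_named = b.map(lambda j: var_labels[int(j) - 1])
    counts = (
        pd.crosstab(var_named, mean_named)
        .reindex(index=list(var_labels), columns=list(mean_labels), fill_value=0)
    )
    counts.index.name, counts.columns.name = "var_class", "mean_class"
    n = int(counts.to_numpy().sum())
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = (counts.div(row_tot.replace(0, np.nan), axis=0) * 100).round(2).fillna(0.0)
        col_pct = (counts.div(col_tot.replace(0, np.nan), axis=1) * 100).round(2).fillna(0.0)
    return CrossTabulation(
        counts=counts,
        row_pct=row_pct,
        col_pct=col_pct,
        row_total_pct=(row_tot / n * 100).round(2),
        col_total_pct=(col_tot / n * 100).round(2),
        n=n,
    )


# ---------------------------------------------------------------------------
# stages


def _require(outdir: Path, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise ConfigurationError(
                f"required input {name!r} not found in {outdir}; "
                "enable the stage that produces it or provide the file"
            )


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> list:
    cohort_cfg = CohortConfig(seed=cfg.seed, **cfg.cohort)
    patients = generate_cohort(cohort_cfg)
    paths = write_cohort(patients, outdir)
    return [p.name for p in paths.values()]


def _stage_moving(cfg: PipelineConfig, outdir: Path) -> list:
    _require(outdir, "adherence.csv")
    adh = pd.read_csv(outdir / "adherence.csv")
    mov = moving_mean_variance(adh, window=cfg.window)
    mov, smap = standardize_variances(mov, target_class_size=cfg.target_class_size)
    mov.to_csv(outdir / "moving.csv", index=False)
    (outdir / "stdmap.json").write_text(json.dumps(smap.to_dict()))
    return ["moving.csv", "stdmap.json"]


def _fit_and_write(mov, ycol, tag, cfg, outdir, ascending):
    basis = BasisConfig(knots=cfg.knots)
    model, post = fit_lcmm(
        mov.rename(columns={ycol: "y"}),
        n_classes=cfg.n_classes,
        basis=basis,
        n_starts=cfg.n_starts,
        seed=cfg.seed,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
    )
    model, post = relabel_classes(model, post, descending=not ascending)
    classes = map_classify(post)
    (outdir / f"model_{tag}.json").write_text(json.dumps(model.to_dict(), indent=1))
    post.to_csv(outdir / f"posteriors_{tag}.csv", index=False)
    classes.to_csv(outdir / f"classes_{tag}.csv", index=False)
    return model, post


def _stage_trajectories(cfg: PipelineConfig, outdir: Path) -> list:
    _require(outdir, "moving.csv")
    mov = pd.read_csv(outdir / "moving.csv")
    _fit_and_write(mov, "moving_mean", "mean", cfg, outdir, ascending=False)
    _fit_and_write(mov, "std_variance", "variance", cfg, outdir, ascending=True)
    return [
        "model_mean.json", "posteriors_mean.csv", "classes_mean.csv",
        "model_variance.json", "posteriors_variance.csv", "classes_variance.csv",
    ]


def _read_class_pair(outdir: Path) -> pd.DataFrame:
    cm = pd.read_csv(outdir / "classes_mean.csv").rename(columns={"map_class": "mean_class"})
    cv = pd.read_csv(outdir / "classes_variance.csv").rename(columns={"map_class": "var_class"})
    return cm[["patient_id", "mean_class"]].merge(cv[["patient_id", "var_class"]], on="patient_id")


def _stage_outcomes(cfg: PipelineConfig, outdir: Path) -> list:
    _require(outdir, "visits.csv", "survival.csv", "moving.csv", "classes_mean.csv", "classes_variance.csv")
    visits = pd.read_csv(outdir / "visits.csv")
    survival = pd.read_csv(outdir / "survival.csv")
    mov = pd.read_csv(outdir / "moving.csv")
    classes = _read_class_pair(outdir)

    outcomes = build_six_month_outcomes(visits, classes, threshold=cfg.vl_threshold)
    outcomes.to_csv(outdir / "outcomes.csv", index=False)
    episodes = build_survival_episodes(mov, survival)
    episodes.to_csv(outdir / "episodes.csv", index=False)

    effects = [fit_mixed_logistic(outcomes), fit_mixed_linear(outcomes)]
    for terms in cfg.cox_terms:
        effects.append(fit_cox_td(episodes, terms=terms, ties=cfg.ties))
    pd.concat(effects, ignore_index=True).to_csv(outdir / "effects.csv", index=False)
    return ["outcomes.csv", "episodes.csv", "effects.csv"]


def _stage_report(cfg: PipelineConfig, outdir: Path) -> list:
    _require(outdir, "classes_mean.csv", "classes_variance.csv",
             "model_mean.json", "model_variance.json", "moving.csv")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = pd.read_csv(outdir / "classes_mean.csv")
    cv = pd.read_csv(outdir / "classes_variance.csv")
    tab = cross_tabulate(cm, cv)
    tab.to_frame().to_csv(outdir / "table1.csv", index=False)

    mov = pd.read_csv(outdir / "moving.csv")
    months = np.arange(int(mov["month"].min()), int(mov["month"].max()) + 1)
    written = ["table1.csv"]
    for tag, labels, ylab in (
        ("mean", MEAN_CLASS_LABELS, "moving mean adherence (%)"),
        ("variance", VAR_CLASS_LABELS, "standardized variance (z)"),
    ):
        d = json.loads((outdir / f"model_{tag}.json").read_text())
        from .trajectories import LatentClassModel

        model = LatentClassModel(
            n_classes=d["n_classes"],
            class_weights=np.asarray(d["class_weights"]),
            class_coefficients=np.asarray(d["class_coefficients"]),
            random_intercept_sd=d["random_intercept_sd"],
            random_slope_sd=d["random_slope_sd"],
            re_correlation=d["re_correlation"],
            residual_sd=d["residual_sd"],
            log_likelihood=d["log_likelihood"],
            n_em_iterations=d["n_em_iterations"],
            converged=d["converged"],
            basis=BasisConfig(knots=tuple(d["knots"])),
        )
        post = pd.read_csv(outdir / f"posteriors_{tag}.csv")
        curves = []
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for j in range(1, model.n_classes + 1):
            tr = typical_trajectory(model, post, j, months)
            tr["class"] = labels[j - 1] if j <= len(labels) else str(j)
            curves.append(tr)
            ax.plot(tr["month"], tr["value_curve"],
                    label=f"{tr['class'].iloc[0]} ({model.class_weights[j - 1]:.1%})")
        ax.set_xlabel("months since therapy start")
        ax.set_ylabel(ylab)
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"fig_trajectories_{tag}.png", dpi=100,
                    metadata={"Software": "adherevar"})
        plt.close(fig)
        pd.concat(curves, ignore_index=True).to_csv(outdir / f"trajectories_{tag}.csv", index=False)
        written += [f"trajectories_{tag}.csv", f"fig_trajectories_{tag}.png"]
    return written


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "moving": _stage_moving,
    "trajectories": _stage_trajectories,
    "outcomes": _stage_outcomes,
    "report": _stage_report,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order; returns (and writes) the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    for stage in config.stages:
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        try:
            files = _STAGE_FNS[stage](config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"seconds": round(dt, 3), "outputs": files}
        for name in files:
            manifest["files"][name] = _sha256(outdir / name)
        logger.info("stage %s: done in %.2fs (%d files)", stage, dt, len(files))
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
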