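"""End-to-end pipeline: cohort → labels → imputation → selection → training.

Each stage function is thin glue over the corresponding module and
writes its artifacts under the run directory; ``run_all`` chains them:

1. generate a synthetic cohort and derive per-step labels;
2. exclude participants already positive at the first step;
3. inject MCAR missingness and drop features with >= 80 % missing values
   at any step;
4. first imputation pass over the wide feature set;
5. L1 feature selection on the imputed design;
6. second imputation pass restricted to the selected features;
7. repeated stratified-CV evaluation of the four progressive submodels,
   the non-progressive and recurrent baselines, and the soft-voting
   ensembles.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import cohort as cohort_mod
from . import feature_selection as fs
from . import imputation as imp
from .config import RunConfig
from .ensemble_eval import run_experiment
from .labeling import (
    LabelSeries,
    derive_labels,
    exclude_baseline_positives,
    summarize_prevalence,
)
from .panel import CohortConfig, CohortPanel
from .trainer import TrainConfig

logger = logging.getLogger("progself")


def _timed(stage):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %s finished in %.1fs", stage, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def cohort_config(cfg: RunConfig) -> CohortConfig:
    c = cfg.cohort
    return CohortConfig(
        n_participants=c.n_participants,
        n_steps=c.n_steps,
        n_features=c.n_features,
        n_informative=c.n_informative,
        target_prevalence_first=c.target_prevalence_first,
        target_prevalence_last=c.target_prevalence_last,
        missing_rate_range=(c.missing_rate_lo, c.missing_rate_hi),
        seed=cfg.stage_seed("cohort"),
    )


@_timed("simulate")
def stage_simulate(cfg: RunConfig, outdir: Path) -> CohortPanel:
    panel = cohort_mod.generate_cohort(cohort_config(cfg))
    panel.to_csv(outdir / "cohort_full.csv")
    logger.info(
        "generated cohort: %d participants x %d steps x %d features",
        panel.n_participants,
        panel.n_steps,
        panel.n_features,
    )
    return panel


@_timed("label")
def stage_label(
    cfg: RunConfig, panel: CohortPanel, outdir: Path
) -> tuple[CohortPanel, LabelSeries]:
    labels = derive_labels(panel)
    n_before = panel.n_participants
    panel, labels = exclude_baseline_positives(panel, labels)
    logger.info(
        "excluded %d baseline-positive participants; %d retained",
        n_before - panel.n_participants,
        panel.n_participants,
    )
    labels.to_csv(outdir / "labels.csv")
    summarize_prevalence(labels).to_csv(outdir / "prevalence.csv", index=False)
    return panel, labels


@_timed("mask")
def stage_mask(cfg: RunConfig, panel: CohortPanel, outdir: Path) -> CohortPanel:
    cc = cohort_config(cfg)
    masked = cohort_mod.inject_missingness(panel, cc)
    masked = fs.missingness_filter(masked, cfg.selection.max_missing)
    masked.to_csv(outdir / "cohort_masked.csv")
    logger.info(
        "missingness injected; %d features survive the %.0f%% filter",
        masked.n_features,
        100 * cfg.selection.max_missing,
    )
    return masked


@_timed("impute")
def stage_impute(
    cfg: RunConfig, panel: CohortPanel, outdir: Path, tag: str = "pre"
) -> CohortPanel:
    i = cfg.imputation
    model = imp.fit_imputer(
        panel,
        epochs=i.epochs,
        seed=cfg.stage_seed(f"impute_{tag}"),
        hidden_size=i.hidden_size,
        learning_rate=i.learning_rate,
        batch_size=i.batch_size,
        consistency_weight=i.consistency_weight,
        method=i.method,
    )
    model.save(outdir / f"imputer_{tag}.npz")
    out = imp.impute(model, panel)
    out.to_csv(outdir / f"cohort_imputed_{tag}.csv")
    return out


@_timed("select")
def stage_select(
    cfg: RunConfig, imputed: CohortPanel, labels: LabelSeries, outdir: Path
) -> list[str]:
    X, y = fs.build_design_table(imputed, labels, layout=cfg.selection.layout)
    result = fs.lasso_select(
        X,
        y,
        cv_folds=cfg.selection.cv_folds,
        seed=cfg.stage_seed("select"),
        family=cfg.selection.family,
    )
    result.report().to_csv(outdir / "lasso_coefficients.csv", index=False)
    result.to_json(outdir / "lasso_summary.json")
    selected = result.selected_features
    logger.info("selected %d features: %s", len(selected), selected)
    if not selected:
        raise ValueError("L1 selection returned no features; weaken the penalty grid")
    return selected


@_timed("evaluate")
def stage_evaluate(
    cfg: RunConfig, panel: CohortPanel, labels: LabelSeries, outdir: Path
):
    t = cfg.training
    e = cfg.evaluation
    tconf = TrainConfig(
        batch_size=t.batch_size,
        dropout=t.dropout,
        n_layers=t.n_layers,
        hidden_size=t.hidden_size,
        max_epochs=t.max_epochs,
        patience=t.patience,
        learning_rate=t.learning_rate,
        optimizer_name=t.optimizer_name,
        cell_kind=t.cell_kind,
    )
    report = run_experiment(
        panel,
        labels,
        tconf,
        n_repetitions=e.n_repetitions,
        n_folds=e.n_folds,
        window_n=cfg.windowing.n,
        include_pair_family=e.include_pair_family,
        include_recurrent_baselines=e.include_recurrent_baselines,
        threshold=e.threshold,
        seed=cfg.stage_seed("evaluate"),
        log=logger.info,
    )
    report.to_csv(outdir / "metrics.csv")
    _write_tables(report, outdir)
    return report


def _write_tables(report, outdir: Path) -> None:
    """Emit the familiar report shapes: baselines, singles, ensembles."""
    t = report.table
    groups = {
        "table_nonprogressive.csv": t.index.str.startswith("nonprogressive"),
        "table_submodels.csv": t.index.str.startswith("submodel"),
        "table_ensembles.csv": t.index.str.startswith("ensemble"),
        "table_recurrent_baselines.csv": t.index.str.startswith("baseline"),
    }
    for name, sel in groups.items():
        if sel.any():
            t[sel].to_csv(outdir / name)


def run_all(cfg: RunConfig):
    """Run the whole pipeline under ``cfg.output_dir``; returns the report."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    panel = stage_simulate(cfg, outdir)
    panel, labels = stage_label(cfg, panel, outdir)
    masked = stage_mask(cfg, panel, outdir)
    imputed_wide = stage_impute(cfg, masked, outdir, tag="pre")
    selected = stage_select(cfg, imputed_wide, labels, outdir)
    masked_selected = masked.subset_features(selected)
    imputed_final = stage_impute(cfg, masked_selected, outdir, tag="post")
    report = stage_evaluate(cfg, imputed_final, labels, outdir)
    return report
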