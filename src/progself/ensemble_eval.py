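"""Soft-voting ensembles and repeated stratified cross-validated evaluation.

Folds are stratified on the final time-step's binary label; each
repetition reshuffles the folds with a fresh seed, every configuration is
scored on the held-out fold, per-repetition scores are fold means, and
the report gives mean ± SD over repetitions for accuracy, AUC, recall,
precision and F1 (all in percent).  Ensembles soft-vote member submodels
with equal weights (elementwise mean probability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .labeling import LabelSeries
from .panel import CohortPanel
from .trainer import TrainConfig, make_task, progressive_train, train_task
from .windowing import materialize, submodel_sequences

METRICS = ("accuracy", "auc", "recall", "precision", "f1")

#: the seven ensemble combinations evaluated in the combination sweep
TABLE3_COMBINATIONS = (
    (1, 2),
    (3, 4),
    (1, 2, 3),
    (1, 2, 4),
    (1, 3, 4),
    (2, 3, 4),
    (1, 2, 3, 4),
)
#: the focused pair family around the best triple
PAIR_FAMILY_COMBINATIONS = ((1, 4), (2, 4))


def soft_vote(member_probabilities: list[np.ndarray]) -> np.ndarray:
    """Equal-weight soft vote: elementwise mean of member probabilities."""
    if not member_probabilities:
        raise ValueError("soft_vote needs at least one member")
    arrs = [np.asarray(p, dtype=float) for p in member_probabilities]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("member probability vectors must have equal length")
    return np.mean(np.stack(arrs), axis=0)


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per participant, stratified on the binary labels."""
    labels = np.asarray(labels).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for stratification")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot form {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[va] = fold
    return assignment


def compute_metrics(
    y_true: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Five binary-classification metrics in percent.

    AUC is the rank-based area under the ROC curve with midrank tie
    handling; the other metrics use the fixed probability threshold.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if len(y) != len(p):
        raise ValueError("y_true and probabilities must align")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class y_true")
    pred = (p >= threshold).astype(int)
    return {
        "accuracy": 100.0 * accuracy_score(y, pred),
        "auc": 100.0 * roc_auc_score(y, p),
        "recall": 100.0 * recall_score(y, pred, zero_division=0),
        "precision": 100.0 * precision_score(y, pred, zero_division=0),
        "f1": 100.0 * f1_score(y, pred, zero_division=0),
    }


@dataclass
class MetricsReport:
    """Mean ± SD (percent) per configuration over repetitions."""

    table: pd.DataFrame  # index = configuration, columns metric_mean/metric_sd
    per_repetition: dict[str, pd.DataFrame]  # config -> (rep x metric) values
    n_repetitions: int
    n_folds: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def default_nonprogressive_subsets(N: int) -> dict[str, tuple[int, ...]]:
    """The four baseline input-step subsets, scaled to N steps.

    At N = 7 these are the canonical t1–t6, t4–t6, (t2, t4, t6) and
    (t3, t6) configurations, each predicting step N.
    """
    return {
        "all_steps": tuple(range(1, N)),
        "recent_three": tuple(range(N - 3, N)),
        "every_other": tuple(range(N - 5, N, 2)),
        "two_steps": (N - 4, N - 1),
    }


def run_experiment(
    panel: CohortPanel,
    labels: LabelSeries,
    config: TrainConfig,
    n_repetitions: int = 10,
    n_folds: int = 5,
    window_n: int = 3,
    ensembles: tuple[tuple[int, ...], ...] = TABLE3_COMBINATIONS,
    include_pair_family: bool = False,
    include_recurrent_baselines: bool = True,
    threshold: float = 0.5,
    seed: int = 0,
    log=None,
) -> MetricsReport:
    """Full evaluation sweep over submodels, baselines and ensembles.

    The panel must be complete (imputed, feature-selected).  For every
    repetition, participants are stratified into ``n_folds`` folds on the
    final step's label; per fold, the four progressive submodels, the
    four non-progressive baselines and (optionally) GRU/RNN baselines are
    trained on the remaining folds and scored on the held-out fold, and
    every requested submodel combination is soft-voted.
    """
    if not panel.mask.all():
        raise ValueError("run_experiment expects an imputed (complete) panel")
    if include_pair_family:
        ensembles = tuple(ensembles) + PAIR_FAMILY_COMBINATIONS
    N = panel.n_steps
    y_last = labels.labels[:, -1]
    sequences = submodel_sequences(N, n=window_n)
    subsets = default_nonprogressive_subsets(N)

    per_rep: dict[str, list[dict[str, float]]] = {}
    for rep in range(n_repetitions):
        rep_seed = int((seed + 7919 * (rep + 1)) % 2_147_483_647)
        folds = stratified_kfold(y_last, k=n_folds, seed=rep_seed)
        fold_scores: dict[str, list[dict[str, float]]] = {}
        for fold in range(n_folds):
            va_idx = np.flatnonzero(folds == fold)
            tr_idx = np.flatnonzero(folds != fold)
            tr_panel, va_panel = _standardized_split(panel, tr_idx, va_idx)
            tr_labels, va_labels = labels.subset(tr_idx), labels.subset(va_idx)
            fold_seed = int((rep_seed + 104729 * (fold + 1)) % 2_147_483_647)
            cfg = replace(config, seed=fold_seed)

            probs: dict[int, np.ndarray] = {}
            y_val = y_last[va_idx]
            for sm, seq in sequences.items():
                tr_tasks = materialize(tr_panel, tr_labels, seq)
                va_tasks = materialize(va_panel, va_labels, seq)
                state = progressive_train(list(zip(tr_tasks, va_tasks)), cfg)
                p = state.to_classifier().predict_proba(va_tasks[-1].inputs)
                probs[sm] = p
                _collect(fold_scores, f"submodel_{sm}", compute_metrics(y_val, p, threshold))

            for name, steps in subsets.items():
                tr_t = make_task(tr_panel, tr_labels, steps, N)
                va_t = make_task(va_panel, va_labels, steps, N)
                state = train_task(None, tr_t, va_t, cfg)
                p = state.to_classifier().predict_proba(va_t.inputs)
                _collect(
                    fold_scores,
                    f"nonprogressive_{name}",
                    compute_metrics(y_val, p, threshold),
                )

            if include_recurrent_baselines:
                tr_t = make_task(tr_panel, tr_labels, subsets["all_steps"], N)
                va_t = make_task(va_panel, va_labels, subsets["all_steps"], N)
                for cell in ("gru", "rnn"):
                    state = train_task(None, tr_t, va_t, replace(cfg, cell_kind=cell))
                    p = state.to_classifier().predict_proba(va_t.inputs)
                    _collect(
                        fold_scores,
                        f"baseline_{cell}",
                        compute_metrics(y_val, p, threshold),
                    )

            for combo in ensembles:
                p = soft_vote([probs[m] for m in combo])
                name = "ensemble_" + "+".join(str(m) for m in combo)
                _collect(fold_scores, name, compute_metrics(y_val, p, threshold))

            if log is not None:
                log(f"repetition {rep + 1}/{n_repetitions} fold {fold + 1}/{n_folds} done")

        for name, scores in fold_scores.items():
            rep_mean = {m: float(np.mean([s[m] for s in scores])) for m in METRICS}
            per_rep.setdefault(name, []).append(rep_mean)

    if n_repetitions * n_folds == 1:
        warnings.warn(
            "single repetition and fold: reported SDs are 0", stacklevel=2
        )

    per_rep_frames = {
        name: pd.DataFrame(rows) for name, rows in per_rep.items()
    }
    rows = {}
    for name, df in per_rep_frames.items():
        row = {}
        for m in METRICS:
            row[f"{m}_mean"] = float(df[m].mean())
            row[f"{m}_sd"] = float(df[m].std(ddof=1)) if len(df) > 1 else 0.0
        rows[name] = row
    table = pd.DataFrame(rows).T
    table.index.name = "configuration"
    return MetricsReport(
        table=table,
        per_repetition=per_rep_frames,
        n_repetitions=n_repetitions,
        n_folds=n_folds,
    )


def _collect(store, name, metrics) -> None:
    store.setdefault(name, []).append(metrics)


def _standardized_split(panel, tr_idx, va_idx):
    """Split participants and z-score features on the training split only."""
    flat = panel.values[tr_idx].reshape(-1, panel.n_features)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)

    def _scaled(idx):
        sub = panel.subset_participants(idx)
        sub.values = (sub.values - mean) / sd
        return sub

    return _scaled(tr_idx), _scaled(va_idx)
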