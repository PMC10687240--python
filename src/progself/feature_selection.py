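"""L1-penalized feature selection with a missingness prefilter.

Features with 80 % or more missing values at any time-step are dropped
first (the bound is strict: a feature survives only if its missing
fraction is < ``max_missing`` at *every* step).  The surviving, imputed
design is standardized and an L1-penalized regression of the binary
label on the features is fitted over a penalty grid; the penalty is
chosen by cross-validated loss and the nonzero-coefficient support is
the selected feature set, ranked by absolute coefficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import KFold

from .labeling import UNDEFINED_LABEL, LabelSeries
from .panel import CohortPanel

DEFAULT_GRID = tuple(np.logspace(-3.5, -0.5, 16))


@dataclass
class LassoResult:
    penalty_grid: tuple[float, ...]
    chosen_penalty: float
    coefficients: pd.Series  # signed, standardized scale, indexed by feature
    cv_losses: dict[float, float] = field(default_factory=dict)

    @property
    def selected_features(self) -> list[str]:
        """Nonzero-coefficient features, by |coefficient| descending.

        Ties break deterministically on the feature name.
        """
        nz = self.coefficients[self.coefficients != 0.0]
        order = sorted(nz.index, key=lambda f: (-abs(nz[f]), f))
        return order

    def report(self) -> pd.DataFrame:
        sel = set(self.selected_features)
        rank = {f: i + 1 for i, f in enumerate(self.selected_features)}
        df = pd.DataFrame(
            {
                "feature": self.coefficients.index,
                "coefficient": self.coefficients.to_numpy(),
            }
        )
        df["selected"] = df["feature"].isin(sel)
        df["rank"] = df["feature"].map(rank).astype("Int64")
        return df.sort_values(
            ["selected", "rank"], ascending=[False, True]
        ).reset_index(drop=True)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "penalty_grid": list(self.penalty_grid),
                    "chosen_penalty": self.chosen_penalty,
                    "cv_losses": {str(k): v for k, v in self.cv_losses.items()},
                    "coefficients": self.coefficients.to_dict(),
                    "selected_features": self.selected_features,
                }
            )
        )


def missingness_filter(
    panel: CohortPanel, max_missing: float = 0.8
) -> CohortPanel:
    """Keep features whose missing fraction is < max_missing at every step."""
    missing_frac = 1.0 - panel.mask.mean(axis=0)  # (T, F)
    keep = (missing_frac < max_missing).all(axis=0)
    if not keep.any():
        raise ValueError(
            f"no features have < {max_missing:.0%} missing values at every step"
        )
    names = [f for f, k in zip(panel.feature_names, keep) if k]
    return panel.subset_features(names)


def build_design_table(
    panel: CohortPanel, labels: LabelSeries, layout: str = "per_step"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Flatten the panel into a (rows x features, labels) design.

    ``per_step`` (default): one row per participant-time-step over steps
    1..N-1, paired with that step's label — uses every labelled instance.
    ``last_step``: one row per participant with the step N-1 features,
    paired with the final step's label.
    """
    if not panel.mask.all():
        raise ValueError("design table requires an imputed (complete) panel")
    N = panel.n_steps
    if layout == "per_step":
        rows = panel.values[:, : N - 1, :].reshape(-1, panel.n_features)
        y = labels.labels[:, : N - 1].reshape(-1)
    elif layout == "last_step":
        rows = panel.values[:, N - 2, :]
        y = labels.labels[:, N - 1]
    else:
        raise ValueError(f"unknown design layout {layout!r}")
    if (y == UNDEFINED_LABEL).any():
        raise ValueError("design rows with undefined labels")
    return pd.DataFrame(rows, columns=panel.feature_names), y.astype(float)


def lasso_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    family: str = "linear",
) -> LassoResult:
    """Cross-validated L1 penalty choice and support extraction.

    ``family="linear"`` fits L1 linear regression on the 0/1 label;
    ``family="logistic"`` fits L1 logistic regression (penalty mapped to
    ``C = 1/(n * alpha)``).  Constant features are dropped with a warning
    before standardization.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("empty penalty grid")
    if len(features) != len(labels):
        raise ValueError("features and labels must align row-wise")
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)

    sds = X.std(axis=0)
    const = sds < 1e-12
    if const.any():
        dropped = [f for f, c in zip(features.columns, const) if c]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        features = features.loc[:, ~const]
        X, sds = X[:, ~const], sds[~const]
    names = list(features.columns)
    Xs = (X - X.mean(axis=0)) / sds

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))
    cv_losses = {}
    cv_se = {}
    for alpha in grid:
        losses = []
        for tr, va in splits:
            model = _fit(Xs[tr], y[tr], alpha, family, len(y))
            pred = model.predict(Xs[va]) if family == "linear" else model.predict_proba(Xs[va])[:, 1]
            losses.append(float(np.mean((pred - y[va]) ** 2)))
        cv_losses[alpha] = float(np.mean(losses))
        cv_se[alpha] = float(np.std(losses, ddof=1) / np.sqrt(len(losses)))
    # one-standard-error rule: the sparsest (largest) penalty whose CV loss
    # is within one SE of the minimum
    best = min(grid, key=lambda a: (cv_losses[a], a))
    cutoff = cv_losses[best] + cv_se[best]
    chosen = max(a for a in grid if cv_losses[a] <= cutoff)

    model = _fit(Xs, y, chosen, family, len(y))
    coef = model.coef_.ravel()
    return LassoResult(
        penalty_grid=grid,
        chosen_penalty=chosen,
        coefficients=pd.Series(coef, index=names, name="coefficient"),
        cv_losses=cv_losses,
    )


def _fit(X, y, alpha, family, n_total):
    if family == "linear":
        m = Lasso(alpha=alpha, max_iter=5000)
        m.fit(X, y)
        return m
    if family == "logistic":
        m = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=1.0 / (n_total * alpha), max_iter=2000
        )
        m.fit(X, y.astype(int))
        return m
    raise ValueError(f"unknown family {family!r}")
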