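"""Per-time-step diabetes labelling and cohort inclusion rules.

A participant is labelled diabetic at a time-step if at least one ADA-style
criterion holds: HbA1c >= 6.5 %, fasting plasma glucose >= 126 mg/dL,
120-min OGTT glucose >= 200 mg/dL, or any of the three diabetes-related
survey flags is set.  Participants already diabetic at the first wave are
excluded from the analysis cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import BIOMARKER_ROLES, SURVEY_FLAG_NAMES, CohortPanel

#: sentinel for a participant-step where no criterion was observable
UNDEFINED_LABEL = -1


@dataclass
class DiagnosticCriteria:
    """Inclusive diagnostic thresholds (ADA guidelines)."""

    hba1c_threshold: float = 6.5  # percent, whole blood
    fasting_glucose_threshold: float = 126.0  # mg/dL, plasma
    ogtt120_threshold: float = 200.0  # mg/dL, plasma
    survey_flag_names: tuple[str, ...] = SURVEY_FLAG_NAMES

    def __post_init__(self) -> None:
        for v in (
            self.hba1c_threshold,
            self.fasting_glucose_threshold,
            self.ogtt120_threshold,
        ):
            if v <= 0:
                raise ValueError("diagnostic thresholds must be strictly positive")


@dataclass
class LabelSeries:
    """Binary outcome labels per participant and time-step."""

    labels: np.ndarray  # (P, T) int in {0, 1} (or UNDEFINED_LABEL)
    participant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        valid = np.isin(self.labels, (0, 1, UNDEFINED_LABEL))
        if not valid.all():
            raise ValueError("labels must be 0, 1 or the undefined marker")

    @property
    def prevalence(self) -> np.ndarray:
        """Per-step fraction of positive labels among defined labels."""
        defined = self.labels != UNDEFINED_LABEL
        pos = (self.labels == 1).sum(axis=0)
        return pos / defined.sum(axis=0)

    @property
    def has_undefined(self) -> bool:
        return bool((self.labels == UNDEFINED_LABEL).any())

    def subset(self, idx: np.ndarray) -> "LabelSeries":
        return LabelSeries(self.labels[idx], self.participant_ids[idx])

    def to_csv(self, path: str | Path) -> None:
        P, T = self.labels.shape
        pd.DataFrame(
            {
                "participant_id": np.repeat(self.participant_ids, T),
                "time_step": np.tile(np.arange(1, T + 1), P),
                "label": self.labels.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelSeries":
        df = pd.read_csv(path)
        pids = df["participant_id"].drop_duplicates().to_numpy()
        wide = df.pivot(index="participant_id", columns="time_step", values="label")
        wide = wide.loc[pids]
        return cls(wide.to_numpy(), pids)


def derive_labels(
    panel: CohortPanel, criteria: DiagnosticCriteria | None = None
) -> LabelSeries:
    """Label each participant-step by OR over the diagnostic criteria.

    Unobserved biomarkers (mask False) simply drop out of the OR; a
    participant-step at which no biomarker is observed and all survey flags
    are false gets the explicit undefined marker.
    """
    criteria = criteria or DiagnosticCriteria()
    missing_roles = [r for r in BIOMARKER_ROLES if r not in panel.biomarker_index]
    if missing_roles:
        raise ValueError(f"panel lacks biomarker columns for roles: {missing_roles}")

    thresholds = {
        "hba1c": criteria.hba1c_threshold,
        "fasting_glucose": criteria.fasting_glucose_threshold,
        "ogtt120": criteria.ogtt120_threshold,
    }
    P, T, _ = panel.values.shape
    positive = np.zeros((P, T), dtype=bool)
    any_observed = panel.survey_flags.any(axis=2)  # flags are always "observed"
    flag_positive = panel.survey_flags.any(axis=2)
    positive |= flag_positive
    for role, thr in thresholds.items():
        col = panel.biomarker_index[role]
        obs = panel.mask[:, :, col]
        any_observed |= obs
        positive |= obs & (panel.values[:, :, col] >= thr)

    labels = positive.astype(int)
    # survey flags are three-valued booleans and always defined; a step is
    # undefined only when no biomarker was observed *and* no flag is set
    undefined = ~any_observed
    labels[undefined] = UNDEFINED_LABEL
    return LabelSeries(labels, panel.participant_ids)


def exclude_baseline_positives(
    panel: CohortPanel, labels: LabelSeries
) -> tuple[CohortPanel, LabelSeries]:
    """Drop participants already diabetic at the first time-step."""
    y1 = labels.labels[:, 0]
    keep = y1 != 1
    if not keep.any():
        raise ValueError("all participants are baseline-positive; empty cohort")
    idx = np.flatnonzero(keep)
    return panel.subset_participants(idx), labels.subset(idx)


def summarize_prevalence(labels: LabelSeries) -> pd.DataFrame:
    """Per-step counts of each label and the positive percentage.

    Percentages use half-up rounding to 2 decimals, the convention of
    printed cohort tables.
    """
    lab = labels.labels
    T = lab.shape[1]
    n0 = (lab == 0).sum(axis=0)
    n1 = (lab == 1).sum(axis=0)
    pct = np.array(
        [_round_half_up(100.0 * p / (p + n), 2) if (p + n) else np.nan
         for p, n in zip(n1, n0)]
    )
    return pd.DataFrame(
        {
            "time_step": np.arange(1, T + 1),
            "label_0": n0,
            "label_1": n1,
            "label_1_pct": pct,
        }
    )


def prevalence_percent(n_negative: int, n_positive: int) -> float:
    """Positive percentage of a single step's counts, 2-decimal half-up."""
    total = n_negative + n_positive
    if total == 0:
        raise ValueError("empty step")
    return _round_half_up(100.0 * n_positive / total, 2)


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
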