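"""Core longitudinal panel containers and their text-file round trip.

A cohort panel is a ``participants x time-steps x features`` block of
continuous measurements with a parallel boolean observation mask, plus a
small set of per-step binary survey flags that participate in outcome
labelling.  Time-steps are abstract 1-based biannual waves ``t_1..t_N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: names of the three diabetes-related survey items ("last 2 years" recall)
SURVEY_FLAG_NAMES = (
    "diagnosis_experience",
    "ongoing_treatment",
    "insulin_therapy",
)

#: roles of the diagnostic biomarker columns
BIOMARKER_ROLES = ("hba1c", "fasting_glucose", "ogtt120")


@dataclass
class CohortConfig:
    """Shape and calibration targets for a synthetic longitudinal cohort.

    Parameters
    ----------
    n_participants, n_steps, n_features
        Panel dimensions.  ``n_features`` includes the three diagnostic
        biomarker columns.
    n_informative
        Number of non-biomarker features linearly coupled to the latent
        glycemia trajectory (and therefore predictive of the outcome).
    target_prevalence_first, target_prevalence_last
        Outcome prevalence the generator calibrates to at the first and
        last time-step, as fractions in (0, 1).
    missing_rate_range
        Per-feature missing fraction range for MCAR mask injection.
    seed
        Seed for all randomness in generation.
    """

    n_participants: int = 3379
    n_steps: int = 7
    n_features: int = 56
    n_informative: int = 10
    target_prevalence_first: float = 0.0385
    target_prevalence_last: float = 0.1642
    missing_rate_range: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_steps <= 0:
            raise ValueError("n_participants and n_steps must be positive")
        if self.n_features < len(BIOMARKER_ROLES):
            raise ValueError(
                f"n_features must be at least {len(BIOMARKER_ROLES)} "
                "(the diagnostic biomarker columns)"
            )
        if not (0 <= self.n_informative <= self.n_features - len(BIOMARKER_ROLES)):
            raise ValueError("n_informative must fit among non-biomarker features")
        for p in (self.target_prevalence_first, self.target_prevalence_last):
            if not 0.0 < p < 1.0:
                raise ValueError("prevalence targets must lie in (0, 1)")
        if self.target_prevalence_first > self.target_prevalence_last:
            raise ValueError(
                "prevalence must be non-decreasing over time: "
                "target_prevalence_first must not exceed target_prevalence_last"
            )
        lo, hi = self.missing_rate_range
        if not (0.0 <= lo <= hi <= 0.95):
            raise ValueError("missing_rate_range must satisfy 0 <= lo <= hi <= 0.95")


@dataclass
class CohortPanel:
    """Participant x time-step x feature panel with observation mask."""

    participant_ids: np.ndarray  # (P,)
    values: np.ndarray  # (P, T, F) float
    mask: np.ndarray  # (P, T, F) bool, True = observed
    feature_names: list[str]
    biomarker_index: dict[str, int]  # role -> column index
    survey_flags: np.ndarray  # (P, T, 3) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim != 3:
            raise ValueError("values must be (participants, steps, features)")
        if len(self.feature_names) != self.values.shape[2]:
            raise ValueError("feature_names length mismatch")
        if self.survey_flags.shape != (*self.values.shape[:2], len(SURVEY_FLAG_NAMES)):
            raise ValueError("survey_flags must be (P, T, 3)")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("values must be finite wherever mask is True")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def subset_participants(self, idx: np.ndarray) -> "CohortPanel":
        return CohortPanel(
            participant_ids=self.participant_ids[idx],
            values=self.values[idx],
            mask=self.mask[idx],
            feature_names=list(self.feature_names),
            biomarker_index=dict(self.biomarker_index),
            survey_flags=self.survey_flags[idx],
        )

    def subset_features(self, names: list[str]) -> "CohortPanel":
        """Restrict to the named feature columns (order preserved as given)."""
        col = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in col]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        idx = [col[f] for f in names]
        bio = {
            role: idx.index(i)
            for role, i in self.biomarker_index.items()
            if i in idx
        }
        return CohortPanel(
            participant_ids=self.participant_ids,
            values=self.values[:, :, idx],
            mask=self.mask[:, :, idx],
            feature_names=list(names),
            biomarker_index=bio,
            survey_flags=self.survey_flags,
        )

    # ----- text round trip ------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write long-format CSV plus a JSON sidecar of panel metadata."""
        path = Path(path)
        P, T, F = self.values.shape
        pid = np.repeat(self.participant_ids, T * F)
        step = np.tile(np.repeat(np.arange(1, T + 1), F), P)
        feat = np.tile(np.array(self.feature_names, dtype=object), P * T)
        df = pd.DataFrame(
            {
                "participant_id": pid,
                "time_step": step,
                "feature": feat,
                "value": self.values.ravel(),
                "observed": self.mask.ravel().astype(int),
            }
        )
        df.to_csv(path, index=False)
        sidecar = {
            "feature_names": self.feature_names,
            "biomarker_index": self.biomarker_index,
            "survey_flag_names": list(SURVEY_FLAG_NAMES),
            "survey_flags": self.survey_flags.astype(int).tolist(),
            "participant_ids": [int(p) for p in self.participant_ids],
            "n_steps": T,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortPanel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path)
        feature_names = meta["feature_names"]
        pids = np.array(meta["participant_ids"])
        T, F = meta["n_steps"], len(feature_names)
        P = len(pids)
        order = {p: i for i, p in enumerate(pids)}
        fidx = {f: i for i, f in enumerate(feature_names)}
        values = np.full((P, T, F), np.nan)
        mask = np.zeros((P, T, F), dtype=bool)
        pi = df["participant_id"].map(order).to_numpy()
        ti = df["time_step"].to_numpy() - 1
        fi = df["feature"].map(fidx).to_numpy()
        values[pi, ti, fi] = df["value"].to_numpy()
        mask[pi, ti, fi] = df["observed"].to_numpy().astype(bool)
        return cls(
            participant_ids=pids,
            values=values,
            mask=mask,
            feature_names=feature_names,
            biomarker_index=meta["biomarker_index"],
            survey_flags=np.array(meta["survey_flags"], dtype=bool),
        )
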