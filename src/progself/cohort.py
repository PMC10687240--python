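"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a biannual community cohort used
for diabetes-onset prediction: a latent per-participant glycemia
trajectory (random walk with drift) drives three diagnostic biomarker
columns (HbA1c, fasting glucose, 120-min OGTT glucose) and, through the
diagnostic thresholds, the outcome labels.  A configurable subset of the
remaining features is linearly coupled to the latent trajectory
(informative); the rest are correlated Gaussian noise.  Disease is
absorbing: once a participant crosses a diagnostic threshold, the
trajectory keeps them above it, so prevalence is non-decreasing over
time.  Drift and baseline level are calibrated by bisection so the
derived-label prevalence matches the first- and last-step targets.

Missingness is injected separately as an MCAR mask with per-feature
rates; labels always derive from the pre-mask values (ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labeling import DiagnosticCriteria
from .panel import BIOMARKER_ROLES, SURVEY_FLAG_NAMES, CohortConfig, CohortPanel

# latent -> biomarker affine maps (intercept, slope, noise SD); slopes put
# the diagnostic threshold near latent level ~1.7-1.8 for all three
_BIOMARKER_MAPS = {
    "hba1c": (5.70, 0.45, 0.10),
    "fasting_glucose": (102.0, 14.0, 3.0),
    "ogtt120": (145.0, 32.0, 8.0),
}
# probability a given survey flag is set, given diagnosis in the prior wave
_FLAG_PROBS = (0.6, 0.4, 0.15)
_LATENT_STEP_SD = 0.20
_DRIFT_HETEROGENEITY = 0.15
_CALIBRATION_TOL = 0.01  # 1 percentage point contract
_MAX_BISECT = 60


@dataclass
class GeneratorTruth:
    """Ground-truth bookkeeping of one generated cohort."""

    latent: np.ndarray  # (P, T)
    informative_coupling: dict[str, float]  # feature -> signed slope on latent
    baseline_level: float
    drift: float


class CalibrationError(RuntimeError):
    pass


def generate_cohort(config: CohortConfig) -> CohortPanel:
    """Generate a fully observed cohort panel (mask all True)."""
    return generate_cohort_with_truth(config)[0]


def generate_cohort_with_truth(
    config: CohortConfig,
) -> tuple[CohortPanel, GeneratorTruth]:
    P, T = config.n_participants, config.n_steps
    n_bio = len(BIOMARKER_ROLES)
    n_inf = config.n_informative
    n_noise = config.n_features - n_bio - n_inf
    if n_noise < 0:
        raise ValueError("n_features too small for requested informative count")

    rng = np.random.default_rng([config.seed, 0])
    draws = {
        "base": rng.standard_normal(P),
        "drift": rng.standard_normal(P),
        "step": rng.standard_normal((P, T)),
        "bio": rng.standard_normal((P, T, n_bio)),
        "inf": rng.standard_normal((P, T, max(n_inf, 1))),
        "flags": rng.uniform(size=(P, T, len(SURVEY_FLAG_NAMES))),
    }
    couplings = np.empty(n_inf)
    if n_inf:
        couplings = rng.uniform(0.6, 1.2, size=n_inf) * np.where(
            np.arange(n_inf) % 2 == 0, 1.0, -1.0
        )
    # correlated noise block: low-rank factors + idiosyncratic noise
    k = min(3, n_noise) if n_noise else 0
    loadings = rng.uniform(-0.8, 0.8, size=(n_noise, k)) if n_noise else None
    factors = rng.standard_normal((P, T, k)) if n_noise else None
    noise_idio = rng.standard_normal((P, T, n_noise)) if n_noise else None

    base_level = _bisect(
        lambda b: _simulate_prevalence(config, draws, b, 0.0)[0],
        config.target_prevalence_first,
        lo=-8.0,
        hi=3.0,
        what="first-step prevalence",
        target_name=f"{config.target_prevalence_first:.4f}",
    )
    drift = _bisect(
        lambda m: _simulate_prevalence(config, draws, base_level, m)[1],
        config.target_prevalence_last,
        lo=-1.5,
        hi=1.5,
        what="last-step prevalence",
        target_name=f"{config.target_prevalence_last:.4f}",
    )

    latent, bio = _simulate(config, draws, base_level, drift)

    values = np.empty((P, T, config.n_features))
    feature_names = list(BIOMARKER_ROLES)
    values[:, :, :n_bio] = bio
    inf_names = [f"inf_{j + 1:02d}" for j in range(n_inf)]
    for j in range(n_inf):
        values[:, :, n_bio + j] = (
            couplings[j] * latent + 0.8 * draws["inf"][:, :, j]
        )
    feature_names += inf_names
    if n_noise:
        values[:, :, n_bio + n_inf :] = (
            np.einsum("ptk,fk->ptf", factors, loadings) + 0.6 * noise_idio
        )
        feature_names += [f"noise_{j + 1:02d}" for j in range(n_noise)]

    diagnosed = _diagnosed_steps(bio)
    flags = np.zeros((P, T, len(SURVEY_FLAG_NAMES)), dtype=bool)
    for t in range(1, T):
        prior = diagnosed[:, t - 1]
        for j, p in enumerate(_FLAG_PROBS):
            flags[:, t, j] = prior & (draws["flags"][:, t, j] < p)

    panel = CohortPanel(
        participant_ids=np.arange(1, P + 1),
        values=values,
        mask=np.ones_like(values, dtype=bool),
        feature_names=feature_names,
        biomarker_index={r: i for i, r in enumerate(BIOMARKER_ROLES)},
        survey_flags=flags,
    )
    truth = GeneratorTruth(
        latent=latent,
        informative_coupling=dict(zip(inf_names, couplings)),
        baseline_level=base_level,
        drift=drift,
    )
    return panel, truth


def inject_missingness(panel: CohortPanel, config: CohortConfig) -> CohortPanel:
    """Mask entries completely at random with per-feature rates.

    Rates are drawn uniformly from ``config.missing_rate_range``; the
    input panel must be fully observed.  Values are retained under the
    mask (they remain the labelling ground truth).
    """
    if not panel.mask.all():
        raise ValueError("inject_missingness expects a fully observed panel")
    lo, hi = config.missing_rate_range
    if not (0.0 <= lo <= hi <= 0.95):
        raise ValueError("missing rates must lie in [0, 0.95]")
    rng = np.random.default_rng([config.seed, 1])
    rates = rng.uniform(lo, hi, size=panel.n_features)
    u = rng.uniform(size=panel.values.shape)
    mask = u >= rates[None, None, :]
    return CohortPanel(
        participant_ids=panel.participant_ids,
        values=panel.values.copy(),
        mask=mask,
        feature_names=list(panel.feature_names),
        biomarker_index=dict(panel.biomarker_index),
        survey_flags=panel.survey_flags.copy(),
    )


# ----- internals ----------------------------------------------------------


def _simulate(config, draws, base_level, drift):
    """Latent trajectories and biomarkers for given calibration knobs."""
    P, T = config.n_participants, config.n_steps
    latent = np.empty((P, T))
    latent[:, 0] = base_level + draws["base"]
    per_drift = drift + _DRIFT_HETEROGENEITY * draws["drift"]
    for t in range(1, T):
        latent[:, t] = (
            latent[:, t - 1] + per_drift + _LATENT_STEP_SD * draws["step"][:, t]
        )

    crit = DiagnosticCriteria()
    thresholds = np.array(
        [
            crit.hba1c_threshold,
            crit.fasting_glucose_threshold,
            crit.ogtt120_threshold,
        ]
    )
    bio = np.empty((P, T, len(BIOMARKER_ROLES)))
    diagnosed = np.zeros(P, dtype=bool)
    for t in range(T):
        # absorbing state: diagnosed participants stay in diagnostic range
        latent[:, t] = np.where(diagnosed, np.maximum(latent[:, t], 1.9), latent[:, t])
        for j, role in enumerate(BIOMARKER_ROLES):
            a, b, s = _BIOMARKER_MAPS[role]
            bio[:, t, j] = a + b * latent[:, t] + s * draws["bio"][:, t, j]
        bio[diagnosed, t, 1] = np.maximum(
            bio[diagnosed, t, 1], thresholds[1]
        )  # fasting glucose held at/above threshold once diagnosed
        diagnosed |= (bio[:, t, :] >= thresholds[None, :]).any(axis=1)
    return latent, bio


def _diagnosed_steps(bio: np.ndarray) -> np.ndarray:
    crit = DiagnosticCriteria()
    thresholds = np.array(
        [
            crit.hba1c_threshold,
            crit.fasting_glucose_threshold,
            crit.ogtt120_threshold,
        ]
    )
    pos = (bio >= thresholds[None, None, :]).any(axis=2)
    return np.logical_or.accumulate(pos, axis=1)


def _simulate_prevalence(config, draws, base_level, drift):
    _, bio = _simulate(config, draws, base_level, drift)
    diag = _diagnosed_steps(bio)
    return diag[:, 0].mean(), diag[:, -1].mean()


def _bisect(f, target, lo, hi, what, target_name):
    """Monotone-increasing bisection of f to hit target within tolerance."""
    flo, fhi = f(lo), f(hi)
    # targets at (or within tolerance of) the attainable boundary are kept;
    # e.g. zero drift cannot push last-step prevalence below first-step
    if target <= flo:
        if flo - target <= _CALIBRATION_TOL:
            return lo
        raise CalibrationError(
            f"prevalence target {target_name} for {what} unreachable: "
            f"attainable range [{flo:.4f}, {fhi:.4f}]"
        )
    if target >= fhi:
        if target - fhi <= _CALIBRATION_TOL:
            return hi
        raise CalibrationError(
            f"prevalence target {target_name} for {what} unreachable: "
            f"attainable range [{flo:.4f}, {fhi:.4f}]"
        )
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm - target) <= _CALIBRATION_TOL / 4:
            return mid
        if fm < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(f(mid) - target) > _CALIBRATION_TOL:
        raise CalibrationError(
            f"bisection failed to reach {what} target {target_name} "
            f"within {_MAX_BISECT} iterations"
        )
    return mid
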