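import numpy as np
import pytest

from progself.panel import CohortConfig, CohortPanel


def make_panel(values, mask=None, flags=None, biomarkers=None, names=None):
    """Convenience constructor for small hand-built panels."""
    values = np.asarray(values, dtype=float)
    P, T, F = values.shape
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    if flags is None:
        flags = np.zeros((P, T, 3), dtype=bool)
    if names is None:
        names = [f"f{i}" for i in range(F)]
    return CohortPanel(
        participant_ids=np.arange(1, P + 1),
        values=values,
        mask=np.asarray(mask, dtype=bool),
        feature_names=names,
        biomarker_index=biomarkers or {},
        survey_flags=np.asarray(flags, dtype=bool),
    )


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_participants=400,
        n_steps=7,
        n_features=12,
        n_informative=5,
        target_prevalence_first=0.04,
        target_prevalence_last=0.16,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from progself.cohort import generate_cohort_with_truth

    return generate_cohort_with_truth(small_config)
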