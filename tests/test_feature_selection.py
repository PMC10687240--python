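"""Missingness prefilter and L1 support selection."""

import numpy as np
import pandas as pd
import pytest

from progself.feature_selection import (
    build_design_table,
    lasso_select,
    missingness_filter,
)
from progself.labeling import LabelSeries

from conftest import make_panel


class TestMissingnessFilter:
    def _panel(self, miss_frac_by_feature_step):
        """miss_frac given as (F, T) missing fractions over P=100."""
        arr = np.asarray(miss_frac_by_feature_step)
        F, T = arr.shape
        P = 100
        mask = np.ones((P, T, F), dtype=bool)
        for f in range(F):
            for t in range(T):
                k = int(round(arr[f, t] * P))
                mask[:k, t, f] = False
        return make_panel(np.zeros((P, T, F)), mask=mask)

    def test_bound_is_strict(self):
        """Exactly 80% missing at one step drops the feature."""
        panel = self._panel([[0.8, 0.0], [0.79, 0.0]])
        out = missingness_filter(panel, 0.8)
        assert out.feature_names == ["f1"]

    def test_every_step_must_pass(self):
        panel = self._panel([[0.1, 0.9], [0.1, 0.1]])
        out = missingness_filter(panel, 0.8)
        assert out.feature_names == ["f1"]

    def test_fully_observed_identity(self):
        panel = self._panel([[0.0, 0.0], [0.0, 0.0]])
        out = missingness_filter(panel, 0.8)
        assert out.feature_names == panel.feature_names

    def test_all_dropped_raises(self):
        panel = self._panel([[0.9, 0.9]])
        with pytest.raises(ValueError):
            missingness_filter(panel, 0.8)

    def test_randomized_masks_match_bruteforce(self):
        rng = np.random.default_rng(0)
        P, T, F = 60, 5, 12
        mask = rng.uniform(size=(P, T, F)) > rng.uniform(0.5, 0.95, size=F)
        panel = make_panel(np.zeros((P, T, F)), mask=mask)
        # brute-force oracle: recount per feature and step
        surviving = []
        for f in range(F):
            ok = True
            for t in range(T):
                n_missing = sum(1 for p in range(P) if not mask[p, t, f])
                if n_missing / P >= 0.8:
                    ok = False
            if ok:
                surviving.append(f"f{f}")
        try:
            got = missingness_filter(panel, 0.8).feature_names
        except ValueError:
            got = []
        assert got == surviving


def _signal_design(seed, n=2000, k_inf=5, k_noise=45):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k_inf + k_noise))
    coefs = np.array([1.0, -0.8, 0.9, -1.1, 0.7])
    logit = X[:, :k_inf] @ coefs - 1.0
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(float)
    names = [f"inf_{i}" for i in range(k_inf)] + [
        f"noise_{i}" for i in range(k_noise)
    ]
    return pd.DataFrame(X, columns=names), y, coefs


class TestLassoSelect:
    def test_full_shrinkage_with_huge_penalty(self):
        X, y, _ = _signal_design(0, n=300)
        res = lasso_select(X, y, grid=(1e3,), seed=0)
        assert res.selected_features == []

    def test_support_monotone_in_penalty(self):
        X, y, _ = _signal_design(1, n=500)
        sizes = []
        for alpha in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):
            res = lasso_select(X, y, grid=(alpha,), seed=0)
            sizes.append(len(res.selected_features))
        assert sizes == sorted(sizes, reverse=True)

    def test_signs_match_generator_couplings(self):
        X, y, coefs = _signal_design(2)
        res = lasso_select(X, y, seed=0)
        for i, c in enumerate(coefs):
            got = res.coefficients[f"inf_{i}"]
            assert got != 0 and np.sign(got) == np.sign(c)

    def test_ranking_by_absolute_coefficient(self):
        X, y, _ = _signal_design(3, n=800)
        res = lasso_select(X, y, seed=0)
        mags = [abs(res.coefficients[f]) for f in res.selected_features]
        assert mags == sorted(mags, reverse=True)
        report = res.report()
        assert list(report.loc[report["selected"], "feature"]) == res.selected_features

    def test_constant_feature_dropped_with_warning(self):
        X, y, _ = _signal_design(4, n=300)
        X["const"] = 1.0
        with pytest.warns(UserWarning, match="const"):
            res = lasso_select(X, y, grid=(1e-2,), seed=0)
        assert "const" not in res.coefficients.index

    def test_empty_grid_rejected(self):
        X, y, _ = _signal_design(5, n=100)
        with pytest.raises(ValueError):
            lasso_select(X, y, grid=(), seed=0)

    def test_logistic_family_also_recovers_support(self):
        X, y, _ = _signal_design(6, n=1000)
        res = lasso_select(X, y, seed=0, family="logistic")
        found = sum(1 for f in res.selected_features if f.startswith("inf_"))
        assert found >= 4


class TestDesignTable:
    def _fixture(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.standard_normal((10, 7, 3)))
        labels = LabelSeries(rng.integers(0, 2, (10, 7)), panel.participant_ids)
        return panel, labels

    def test_per_step_layout_uses_first_six_steps(self):
        panel, labels = self._fixture()
        X, y = build_design_table(panel, labels, layout="per_step")
        assert X.shape == (60, 3)
        assert np.array_equal(y, labels.labels[:, :6].reshape(-1).astype(float))

    def test_last_step_layout(self):
        panel, labels = self._fixture()
        X, y = build_design_table(panel, labels, layout="last_step")
        assert X.shape == (10, 3)
        assert np.array_equal(y, labels.labels[:, 6].astype(float))
        assert np.allclose(X.to_numpy(), panel.values[:, 5, :])
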