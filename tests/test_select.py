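import numpy as np
import pandas as pd
import pytest

from multisurv.formats import FeatureMatrix
from multisurv.labels import LabelSet, NONSURVIVOR, SURVIVOR
from multisurv.select import (
    boruta_rank,
    correlation_filter,
    lasso_auc_profile,
    zero_variance_filter,
)


def _fm(values, columns=None) -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    cols = columns or [f"f{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"S{i}" for i in range(values.shape[0])],
                      columns=cols)
    return FeatureMatrix(df, omics="mrna", method="raw")


def _labels(y) -> LabelSet:
    return LabelSet(730, {f"S{i}": (NONSURVIVOR if v else SURVIVOR)
                          for i, v in enumerate(y)}, {})


def oracle_greedy_corr(values: pd.DataFrame, cutoff: float) -> list[str]:
    """Independent exhaustive implementation of the greedy correlation pruning."""
    cols = list(values.columns)
    removed = []
    while True:
        corr = values[cols].corr().abs()
        np.fill_diagonal(corr.values, 0)
        best, pair = 0.0, None
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                if corr.iloc[a, b] > best:
                    best, pair = corr.iloc[a, b], (a, b)
        if pair is None or best <= cutoff:
            return removed
        a, b = pair
        mean_a = corr.iloc[a].sum() / (len(cols) - 1)
        mean_b = corr.iloc[b].sum() / (len(cols) - 1)
        drop = a if mean_a > mean_b else b if mean_b > mean_a else max(a, b)
        removed.append(cols.pop(drop))


class TestZeroVariance:
    def test_constant_column_removed_and_idempotent(self):
        fm = _fm([[0, 1.0, 3], [0, 2.0, 3], [0, 1.5, 3]])
        out = zero_variance_filter(fm)
        assert out.feature_ids == ["f1"]
        assert zero_variance_filter(out).feature_ids == ["f1"]

    def test_nearly_constant_column_kept(self):
        col = np.zeros(100)
        col[17] = 1.0
        fm = _fm(np.column_stack([col, np.arange(100.0)]))
        assert zero_variance_filter(fm).feature_ids == ["f0", "f1"]


class TestCorrelationFilter:
    def test_identical_columns_one_removed(self):
        x = np.random.default_rng(0).normal(size=20)
        fm = _fm(np.column_stack([x, x, np.random.default_rng(1).normal(size=20)]))
        out, removed = correlation_filter(fm, 0.9)
        assert len(removed) == 1 and removed[0] in ("f0", "f1")
        assert out.shape[1] == 2

    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(5)
        fm = _fm(rng.normal(size=(200, 10)))
        out, removed = correlation_filter(fm, 0.9)
        assert removed == []

    def test_three_feature_chain_drops_middle(self):
        # Exact construction: r(A,B)=0.95, r(B,C)=0.92, r(A,C)=0.8 (the largest
        # value below the cutoff compatible with positive semidefiniteness).
        # B has the largest mean |r| and is removed first, after which no pair
        # exceeds the cutoff.
        rng = np.random.default_rng(2)
        n = 40
        raw = rng.normal(size=(n, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        e1, e2, e3 = q.T
        A = e1
        C = 0.8 * e1 + np.sqrt(1 - 0.64) * e2
        b_coef = (0.92 - 0.8 * 0.95) / (1 - 0.64)
        a_coef = 0.95 - 0.8 * b_coef
        c_coef = np.sqrt(1 - a_coef**2 - b_coef**2 - 2 * a_coef * b_coef * 0.8)
        B = a_coef * A + b_coef * C + c_coef * e3
        fm = _fm(np.column_stack([A, B, C]), columns=["A", "B", "C"])
        corr = fm.values.corr()
        assert corr.loc["A", "B"] == pytest.approx(0.95)
        assert corr.loc["B", "C"] == pytest.approx(0.92)
        assert corr.loc["A", "C"] == pytest.approx(0.80)
        out, removed = correlation_filter(fm, 0.9)
        assert removed == ["B"]
        assert out.feature_ids == ["A", "C"]

    def test_matches_exhaustive_oracle_and_leaves_no_offending_pair(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = int(rng.integers(3, 13))
            base = rng.normal(size=(40, p))
            # plant some collinearity
            for _ in range(int(rng.integers(0, 4))):
                i, j = rng.integers(0, p, 2)
                base[:, i] = base[:, j] + 0.1 * rng.normal(size=40)
            fm = _fm(base)
            out, removed = correlation_filter(fm, 0.9)
            assert removed == oracle_greedy_corr(fm.values, 0.9)
            corr = out.values.corr().abs().to_numpy()
            np.fill_diagonal(corr, 0)
            assert corr.max() <= 0.9


class TestLassoProfile:
    def test_strongest_penalty_selects_nothing(self):
        rng = np.random.default_rng(0)
        fm = _fm(rng.normal(size=(60, 8)))
        y = rng.integers(0, 2, 60)
        prof = lasso_auc_profile(fm, _labels(y), n_folds=3, n_penalties=10, seed=0)
        assert prof.points["n_nonzero"].iloc[0] == 0

    def test_planted_feature_drives_auc_to_one(self):
        rng = np.random.default_rng(1)
        n = 80
        y = np.array([0] * 40 + [1] * 40)
        X = rng.normal(size=(n, 6))
        X[:, 2] = y * 4 + rng.normal(scale=0.3, size=n)  # near-perfect predictor
        prof = lasso_auc_profile(_fm(X), _labels(y), n_folds=5, n_penalties=25, seed=0)
        picked = prof.points["n_nonzero"] >= 1
        assert prof.points.loc[picked, "mean_cv_auc"].max() > 0.95
        assert all("f2" in sel for sel in
                   [s for s, p in zip(prof.selected_features, picked) if p])

    def test_single_class_rejected(self):
        fm = _fm(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="single class"):
            lasso_auc_profile(fm, _labels([1] * 10), n_folds=2)


class TestBoruta:
    def test_label_copy_confirmed_noise_rejected(self):
        rng = np.random.default_rng(3)
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 21))
        X[:, 0] = y + 0.01 * rng.normal(size=n)
        fm = _fm(X)
        res = boruta_rank(fm, _labels(y), max_runs=99, alpha=0.01, seed=0, n_trees=60)
        assert res.decision["f0"] == "Confirmed"
        noise = res.decision.drop("f0")
        assert (noise == "Rejected").mean() >= 0.95
        assert (noise == "Confirmed").sum() == 0
        assert res.runs_performed <= 99
        assert (res.hit_counts <= res.runs_performed).all()

    def test_empty_matrix_zero_runs(self):
        fm = _fm(np.zeros((10, 0)))
        res = boruta_rank(fm, _labels([0, 1] * 5), max_runs=50, seed=0)
        assert res.runs_performed == 0 and len(res.decision) == 0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60)
        X = rng.normal(size=(60, 8))
        X[:, 1] = y + 0.1 * rng.normal(size=60)
        fm = _fm(X)
        r1 = boruta_rank(fm, _labels(y), max_runs=40, seed=9, n_trees=40)
        r2 = boruta_rank(fm, _labels(y), max_runs=40, seed=9, n_trees=40)
        pd.testing.assert_series_equal(r1.decision, r2.decision)
        pd.testing.assert_frame_equal(r1.importance_history, r2.importance_history)

    def test_permutation_importance_variant(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 80)
        X = rng.normal(size=(80, 5))
        X[:, 0] = y + 0.05 * rng.normal(size=80)
        res = boruta_rank(_fm(X), _labels(y), max_runs=30, seed=1, n_trees=40,
                          importance="permutation_z")
        assert res.decision["f0"] == "Confirmed"

    def test_decisions_partition_features(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 50)
        fm = _fm(rng.normal(size=(50, 6)))
        res = boruta_rank(fm, _labels(y), max_runs=25, seed=2, n_trees=30)
        assert set(res.confirmed) | set(res.tentative) | set(res.rejected) \
            == set(fm.feature_ids)

    def test_too_few_runs_rejected(self):
        fm = _fm(np.zeros((4, 1)))
        with pytest.raises(ValueError, match="max_runs"):
            boruta_rank(fm, _labels([0, 1, 0, 1]), max_runs=5)
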