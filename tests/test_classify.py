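import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from csfnet.classify import (auc_score, delong_ci, lasso_cv, refit_and_evaluate,
                             stability_selection, _fit_l1_path, _lambda_grid,
                             _standardize)


def mann_whitney_auc(scores, labels):
    """Brute-force AUC: pairwise comparison with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 40)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        scores = np.round(rng.standard_normal(n), 1)   # force some ties
        assert auc_score(scores, labels) == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12)

    def test_perfect_predictor(self):
        y = np.array([0] * 30 + [1] * 30)
        auc, lo, hi = delong_ci(y.astype(float), y)
        assert auc == 1.0 and lo <= auc <= hi

    def test_random_scores_near_half(self):
        inside = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 200)
            s = rng.standard_normal(200)
            inside += 0.4 <= auc_score(s, y) <= 0.6
        assert inside >= 9

    def test_delong_ci_contains_auc_and_covers(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 80)
            if len(np.unique(y)) < 2:
                continue
            s = rng.standard_normal(80) + 0.8 * y
            auc, lo, hi = delong_ci(s, y)
            assert lo <= auc <= hi
            assert 0 <= lo and hi <= 1


class TestLassoCv:
    def test_path_shrinks_with_lambda(self, rng):
        x = rng.standard_normal((100, 15))
        y = (rng.uniform(size=100) < 1 / (1 + np.exp(-x[:, 0]))).astype(int)
        xs, _, _ = _standardize(x)
        grid = _lambda_grid(xs, y, n_lambda=20)
        coefs, _ = _fit_l1_path(xs, y, grid)
        l1 = np.abs(coefs).sum(axis=1)          # grid is descending in lambda
        assert l1[0] <= l1[-1] + 1e-8
        assert np.abs(coefs[0]).max() < 1e-6    # all zero at lambda_max

    def test_informative_feature_selected_with_sign(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 20))
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-2 * x[:, 0]))).astype(int)
        df = pd.DataFrame(x, columns=[f"F{i}" for i in range(20)])
        lam, coef = lasso_cv(df, pd.Series(y), fold_seed=3)
        assert coef["F0"] > 0.5

    def test_null_data_fits_near_null_models(self):
        """Outcome independent of features: the CV-selected model is empty or
        tiny (the behaviour of the reference cross-validated L1 path)."""
        all_zero, supports = 0, []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((150, 40))
            y = rng.integers(0, 2, 150)
            _, coef = lasso_cv(pd.DataFrame(x), pd.Series(y), fold_seed=seed)
            nz = int((coef.iloc[1:].abs() > 1e-8).sum())
            supports.append(nz)
            all_zero += nz == 0
        assert all_zero >= 2
        assert np.mean(supports) < 10

    def test_duplicated_feature_coefficient_sum(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 5))
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-2 * x[:, 0]))).astype(int)
        dup = np.column_stack([x[:, 0], x[:, 0], x[:, 1:]])
        _, cd = lasso_cv(pd.DataFrame(dup, columns=list("abcdef")),
                         pd.Series(y), fold_seed=5)
        _, cs = lasso_cv(pd.DataFrame(x, columns=list("acdef")),
                         pd.Series(y), fold_seed=5)
        assert cd["a"] + cd["b"] == pytest.approx(cs["a"], abs=2e-2)

    def test_single_class_errors(self, rng):
        x = rng.standard_normal((30, 5))
        with pytest.raises(ValueError):
            lasso_cv(pd.DataFrame(x), pd.Series(np.ones(30, dtype=int)),
                     fold_seed=0)


class TestStabilitySelection:
    def test_probabilities_are_multiples_of_inverse_count(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((80, 20))
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-2 * x[:, 0]))).astype(int)
        res = stability_selection(pd.DataFrame(x), pd.Series(y),
                                  n_subsamples=20, seed=0)
        scaled = res.selection_probability * 20
        assert np.allclose(scaled, np.round(scaled))

    def test_threshold_arithmetic(self):
        """With 50 subsamples and a 0.65 threshold a feature needs at least
        33 selections (strict > on 32.5)."""
        probs = pd.Series({"a": 33 / 50, "b": 32 / 50, "c": 34 / 50})
        from csfnet.classify import StabilityResult
        res = StabilityResult(probs, 0.65, 50, 0.5, 0)
        assert set(res.stable_features) == {"a", "c"}

    def test_bit_reproducible(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((100, 30))
        y = (rng.uniform(size=100) < 1 / (1 + np.exp(-x[:, 0]))).astype(int)
        df = pd.DataFrame(x)
        a = stability_selection(df, pd.Series(y), n_subsamples=15, seed=9)
        b = stability_selection(df, pd.Series(y), n_subsamples=15, seed=9)
        pd.testing.assert_series_equal(a.selection_probability,
                                       b.selection_probability)

    def test_informative_features_stable(self):
        hits = 0
        for seed in range(4):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((150, 100))
            eta = 2 * x[:, 0] + 2 * x[:, 1]
            y = (rng.uniform(size=150) < 1 / (1 + np.exp(-eta))).astype(int)
            df = pd.DataFrame(x, columns=[f"F{i}" for i in range(100)])
            stable = set(stability_selection(df, pd.Series(y),
                                             seed=seed).stable_features)
            hits += {"F0", "F1"} <= stable
        assert hits >= 3

    def test_pure_noise_stable_set_empty(self):
        empties = 0
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal((150, 100))
            y = rng.integers(0, 2, 150)
            res = stability_selection(pd.DataFrame(x), pd.Series(y), seed=seed)
            empties += len(res.stable_features) == 0
        assert empties >= 3

    def test_tiny_subsample_errors(self, rng):
        x = rng.standard_normal((6, 4))
        y = pd.Series([0, 1, 0, 1, 0, 1])
        with pytest.raises(ValueError):
            stability_selection(pd.DataFrame(x), y, subsample_frac=0.1, seed=0)


class TestRefitAndEvaluate:
    @staticmethod
    def _data(rng, n_train=120, n_test=100, effect=2.0):
        n = n_train + n_test
        f = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-effect * f))).astype(int)
        df = pd.DataFrame({
            "prot": f + 0.3 * rng.standard_normal(n),
            "age": rng.normal(70, 6, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "apoe4_count": rng.integers(0, 2, n).astype(float),
        }, index=[f"S{i}" for i in range(n)])
        split = pd.Series(["train"] * n_train + ["test"] * n_test, index=df.index)
        return df, pd.Series(y, index=df.index), split

    def test_informative_model_beats_baseline(self, rng):
        df, y, split = self._data(rng)
        out = refit_and_evaluate(df, y, split, ["prot"])
        assert out["stable"].auc > out["baseline"].auc
        assert out["stable"].ci_lower <= out["stable"].auc <= out["stable"].ci_upper

    def test_independent_predictor_near_chance(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df, y, split = self._data(rng, effect=0.0, n_test=200)
            out = refit_and_evaluate(df, y, split, ["prot"],
                                     covariates=("age", "sex", "apoe4_count"))
            aucs.append(out["stable"].auc)
        inside = sum(0.4 <= a <= 0.6 for a in aucs)
        assert inside >= 8

    def test_single_class_test_set_errors(self, rng):
        df, y, split = self._data(rng)
        y.loc[split == "test"] = 1
        with pytest.raises(ValueError, match="single class"):
            refit_and_evaluate(df, y, split, ["prot"])

    def test_roc_points_monotone(self, rng):
        df, y, split = self._data(rng)
        out = refit_and_evaluate(df, y, split, ["prot"])
        roc = out["stable"].roc
        assert (roc["sensitivity"].diff().dropna() >= 0).all()
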