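import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from csfnet.containers import ExpressionMatrix
from csfnet.network import (NetworkConfig, _merge_decision, _partition_with_summaries,
                            bicor_matrix, build_network, detect_modules,
                            eigenproteins, kme, merge_modules, pick_soft_threshold,
                            scale_free_fit, signed_adjacency, tom)
from tests.conftest import make_matrix, planted_blocks


def random_adjacency(rng, n):
    c = rng.uniform(-1, 1, (n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    return signed_adjacency(c, 6)


def tom_brute_force(a):
    """Triple-loop topological overlap, straight from the definition."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


class TestBicor:
    def test_self_and_negation(self, rng):
        x = rng.standard_normal((50, 2))
        x[:, 1] = -x[:, 0]
        c = bicor_matrix(make_matrix(x))
        assert c.iloc[0, 0] == pytest.approx(1.0)
        assert c.iloc[0, 1] == pytest.approx(-1.0)

    def test_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(3)
        cov = [[1, 0.6], [0.6, 1]]
        x = rng.multivariate_normal([0, 0], cov, size=500)
        b = bicor_matrix(make_matrix(x)).iloc[0, 1]
        p = np.corrcoef(x.T)[0, 1]
        assert abs(b - p) < 0.05

    def test_robust_to_single_gross_outlier(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal(100)
        x = np.column_stack([f, 0.9 * f + np.sqrt(1 - 0.81) * rng.standard_normal(100)])
        x = np.vstack([x, [40.0, -40.0]])
        b = bicor_matrix(make_matrix(x)).iloc[0, 1]
        p = np.corrcoef(x.T)[0, 1]
        assert abs(b - 0.9) < 0.1
        assert p < 0.5

    def test_zero_mad_falls_back_to_pearson(self, rng):
        x = rng.standard_normal((40, 2))
        x[:, 1] = np.round(x[:, 1] * 0)  # constant-ish: mad 0 and constant
        x[0, 1] = 1.0                    # mad still 0 but not constant
        with pytest.warns(UserWarning, match="zero MAD"):
            c = bicor_matrix(make_matrix(x))
        assert np.isfinite(c.to_numpy()).all()

    def test_bounds(self, rng):
        c = bicor_matrix(make_matrix(rng.standard_normal((30, 10)))).to_numpy()
        assert (np.abs(c) <= 1 + 1e-12).all()
        assert np.allclose(np.diag(c), 1.0)


class TestSignedAdjacency:
    def test_closed_forms(self):
        c = np.array([[1.0, 1.0, -1.0, 0.0],
                      [1.0, 1.0, 0.0, 0.0],
                      [-1.0, 0.0, 1.0, 0.0],
                      [0.0, 0.0, 0.0, 1.0]])
        a = signed_adjacency(c, 12)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0)
        assert a[0, 3] == pytest.approx(1.0 / 4096)

    @given(st.integers(0, 1_000_000))
    @settings(max_examples=20, deadline=None)
    def test_higher_beta_shrinks(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(-1, 1, (8, 8))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        a6, a12 = signed_adjacency(c, 6), signed_adjacency(c, 12)
        assert (a12 <= a6 + 1e-12).all()
        assert (a12 >= 0).all() and (a12 <= 1).all()
        assert np.allclose(a12, a12.T)


class TestScaleFreeFit:
    @staticmethod
    def _rank_one_adjacency(w):
        """Adjacency a_ij = w_i w_j so connectivity k_i ~ w_i * sum(w)."""
        w = np.asarray(w, dtype=float) / np.max(w)
        a = np.outer(w, w)
        np.fill_diagonal(a, 1.0)
        return a

    def test_power_law_scores_high(self):
        # pareto(alpha=1.5) weights -> connectivity density p(k) ~ k^-1.5
        u = (np.arange(2000) + 0.5) / 2000
        w = (1 - u) ** (-2.0)
        r2 = scale_free_fit(self._rank_one_adjacency(w))
        assert r2 > 0.95

    def test_constant_connectivity_scores_zero(self):
        a = np.full((50, 50), 0.3)
        np.fill_diagonal(a, 1.0)
        assert scale_free_fit(a) == 0.0

    def test_increasing_law_scores_zero(self):
        # weights bunched near the top: density increases with connectivity
        u = (np.arange(500) + 0.5) / 500
        w = 1 + 9 * u ** 0.2
        assert scale_free_fit(self._rank_one_adjacency(w)) == 0.0


class TestTom:
    def test_matches_brute_force(self):
        for seed in range(3):
            a = random_adjacency(np.random.default_rng(seed), 20)
            assert np.allclose(tom(a), tom_brute_force(a), atol=1e-12)

    def test_three_node_toy(self):
        a = np.array([[1.0, 0.8, 0.4],
                      [0.8, 1.0, 0.2],
                      [0.4, 0.2, 1.0]])
        t = tom(a)
        assert t[0, 1] == pytest.approx(0.88 / 1.2, abs=1e-12)

    def test_complete_graph_is_all_ones(self):
        a = np.ones((6, 6))
        assert np.allclose(tom(a), 1.0)

    def test_isolated_pair_zero(self):
        a = np.eye(4)
        t = tom(a)
        assert t[0, 1] == 0.0

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=15, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        a = random_adjacency(np.random.default_rng(seed), 12)
        t = tom(a)
        assert np.allclose(t, t.T)
        assert (t >= 0).all() and (t <= 1 + 1e-12).all()


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(3)
        em, truth = planted_blocks(rng, 100, [50, 50])
        part = build_network(em)
        assert adjusted_rand_score(truth.to_numpy(), part.labels.to_numpy()) >= 0.9

    def test_small_block_dissolved_at_min_size(self):
        rng = np.random.default_rng(1)
        em, _ = planted_blocks(rng, 54, [10], n_background=90)
        cor = bicor_matrix(em)
        t = tom(signed_adjacency(cor.to_numpy(), 12))
        part = detect_modules(t, NetworkConfig(min_module_size=15), em.protein_ids)
        assert all(size >= 15 for size in part.sizes())
        assert not any(size == 10 for size in part.sizes())

    def test_noise_yields_no_modules(self):
        outcomes = []
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal((54, 150))
            em = make_matrix(x)
            t = tom(signed_adjacency(bicor_matrix(em).to_numpy(), 12))
            part = detect_modules(t, NetworkConfig(), em.protein_ids)
            outcomes.append(len(part.module_ids))
        assert max(outcomes) == 0

    def test_invariant_to_protein_permutation(self):
        rng = np.random.default_rng(8)
        em, _ = planted_blocks(rng, 60, [30, 25], n_background=20)
        t = tom(signed_adjacency(bicor_matrix(em).to_numpy(), 12))
        part = detect_modules(t, NetworkConfig(), em.protein_ids)
        perm = rng.permutation(em.n_proteins)
        em2 = ExpressionMatrix(em.values.iloc[:, perm], em.scale_tag)
        t2 = tom(signed_adjacency(bicor_matrix(em2).to_numpy(), 12))
        part2 = detect_modules(t2, NetworkConfig(), em2.protein_ids)
        merged = pd.concat([part.labels, part2.labels], axis=1, keys=["a", "b"])
        assert adjusted_rand_score(merged["a"], merged["b"]) == pytest.approx(1.0)

    def test_deep_split_sensitivity(self):
        """Nested sub-blocks resolved at deep_split 4 are absorbed at 0."""
        rng = np.random.default_rng(7)
        f1, f2, shared = rng.standard_normal((3, 60))
        x = rng.standard_normal((60, 140)) * 0.6
        x[:, :30] += 1.0 * shared[:, None] + 0.6 * f1[:, None]
        x[:, 30:60] += 1.0 * shared[:, None] + 0.6 * f2[:, None]
        em = make_matrix(x)
        t = tom(signed_adjacency(bicor_matrix(em).to_numpy(), 12))
        coarse = detect_modules(t, NetworkConfig(deep_split=0), em.protein_ids)
        fine = detect_modules(t, NetworkConfig(deep_split=4), em.protein_ids)
        assert len(fine.module_ids) > len(coarse.module_ids)


class TestEigenproteins:
    def test_identical_series_module(self, rng):
        series = rng.standard_normal(50)
        x = np.tile(series[:, None], (1, 8))
        em = make_matrix(x)
        labels = pd.Series(1, index=em.protein_ids)
        eig, pve = eigenproteins(em, labels)
        assert pve["M1"] == pytest.approx(1.0)
        assert abs(np.corrcoef(eig["M1"], series)[0, 1]) == pytest.approx(1.0)

    def test_sign_convention(self, rng):
        for seed in range(5):
            em, labels = planted_blocks(np.random.default_rng(seed), 60, [20, 15])
            eig, _ = eigenproteins(em, labels)
            for m in ("M1", "M2"):
                members = labels.index[labels == int(m[1])]
                z = em.values[members].apply(lambda c: (c - c.mean()) / c.std())
                assert np.corrcoef(eig[m], z.mean(axis=1))[0, 1] >= 0

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(100)
        x = f[:, None] + 0.5 * rng.standard_normal((100, 50))
        em = make_matrix(x)
        eig, _ = eigenproteins(em, pd.Series(1, index=em.protein_ids))
        assert np.corrcoef(eig["M1"], f)[0, 1] ** 2 >= 0.8

    def test_degenerate_module_errors(self):
        em = make_matrix(np.ones((10, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            eigenproteins(em, pd.Series(1, index=em.protein_ids))


class TestKme:
    def test_bounds_and_independence(self):
        rng = np.random.default_rng(6)
        em, labels = planted_blocks(rng, 200, [30])
        extra = rng.standard_normal((200, 1))
        df = em.values.copy()
        df["indep"] = extra
        em2 = ExpressionMatrix(df, "residual")
        eig, _ = eigenproteins(em2, labels.reindex(df.columns).fillna(0).astype(int))
        k = kme(em2, eig)
        assert (k.to_numpy() <= 1).all() and (k.to_numpy() >= -1).all()
        assert abs(k.loc["indep", "M1"]) < 0.2

    def test_perfect_loading_protein(self, rng):
        series = rng.standard_normal(80)
        x = np.tile(series[:, None], (1, 10))
        em = make_matrix(x)
        eig, _ = eigenproteins(em, pd.Series(1, index=em.protein_ids))
        k = kme(em, eig)
        assert k.iloc[0, 0] == pytest.approx(1.0)


class TestMerge:
    def test_split_factor_merges(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            f = rng.standard_normal(80)
            x = f[:, None] + 0.5 * rng.standard_normal((80, 60))
            em = make_matrix(x)
            labels = pd.Series([1] * 30 + [2] * 30, index=em.protein_ids)
            part = _partition_with_summaries(em, labels)
            merged = merge_modules(part, em, NetworkConfig())
            assert len(merged.module_ids) == 1

    def test_independent_factors_not_merged(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            em, labels = planted_blocks(rng, 80, [30, 30])
            part = _partition_with_summaries(em, labels)
            merged = merge_modules(part, em, NetworkConfig())
            assert len(merged.module_ids) == 2

    def test_exact_quarter_boundary_not_merged(self):
        own = pd.Series([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2],
                        index=[f"P{i}" for i in range(8)])
        other = pd.DataFrame({"M2": [0.95, 0.7, 0.6, 0.5, 0, 0, 0, 0]},
                             index=own.index)  # exactly 1 of top 4 better
        assert _merge_decision(own, other, {2: 10}, 0.5, 0.25) is None
        other.loc["P1", "M2"] = 0.85            # now 2 of 4: strictly > 25%
        assert _merge_decision(own, other, {2: 10}, 0.5, 0.25) == 2

    def test_plurality_target_tie_breaks_to_larger(self):
        own = pd.Series([0.5, 0.5, 0.5, 0.5], index=list("abcd"))
        other = pd.DataFrame({"M2": [0.9, 0.9, 0.0, 0.0],
                              "M3": [0.0, 0.0, 0.9, 0.9]}, index=own.index)
        assert _merge_decision(own, other, {2: 30, 3: 50}, 1.0, 0.25) == 3

    def test_merge_terminates_and_relabels_by_size(self):
        rng = np.random.default_rng(9)
        em, labels = planted_blocks(rng, 70, [40, 20])
        part = _partition_with_summaries(em, labels)
        merged = merge_modules(part, em, NetworkConfig())
        sizes = merged.sizes()
        assert list(sizes.index) == sorted(sizes.index)
        assert (sizes.sort_index().diff().dropna() <= 0).all()


class TestPickSoftThreshold:
    def test_table_and_recommendation(self):
        rng = np.random.default_rng(4)
        em, _ = planted_blocks(rng, 60, [40, 30], n_background=30)
        betas = [2, 4, 6, 12]
        table, rec = pick_soft_threshold(em, betas, target_r2=0.0)
        assert len(table) == len(betas)
        assert rec == 2          # zero target -> smallest candidate
        table2, rec2 = pick_soft_threshold(em, betas, target_r2=0.8)
        assert rec2 is None or rec2 in betas

    def test_empty_candidates_error(self):
        em = make_matrix(np.random.default_rng(0).standard_normal((30, 25)))
        with pytest.raises(ValueError):
            pick_soft_threshold(em, [])


def test_end_to_end_planted_recovery(small_cohorts):
    """Full pipeline on the shared simulated cohorts recovers the planted
    partition among module proteins."""
    cfg, (disc, _, _, samples, _, truth) = small_cohorts
    from csfnet.qc import adjust
    cov = samples.loc[disc.sample_ids, ["age", "sex", "storage_time", "study_origin"]]
    res = adjust(disc, cov, n_svd=0)
    part = build_network(res)
    mask = truth.labels > 0
    ari = adjusted_rand_score(truth.labels[mask], part.labels[mask])
    assert ari >= 0.7
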