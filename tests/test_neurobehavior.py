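import numpy as np
import pandas as pd
import pytest
from scipy import stats

from capdyn.neurobehavior import (crossval_predict, fit_association,
                                  pca_permutation_test, prepare_behavior,
                                  splithalf_reproducibility, subgroup_ttests)


def _table(values, rt_flags=None):
    values = np.asarray(values, dtype=float)
    cols = [f"v{j}" for j in range(values.shape[1])]
    table = pd.DataFrame(values, columns=cols,
                         index=[f"s{i}" for i in range(values.shape[0])])
    meta = pd.DataFrame({
        "variable": cols,
        "domain": ["d"] * len(cols),
        "is_reaction_time": rt_flags if rt_flags is not None else [False] * len(cols),
    })
    return table, meta


class TestPrepareBehavior:
    def test_rt_columns_are_reciprocal_transformed(self):
        table, meta = _table([[2.0, 1.0], [4.0, 2.0], [8.0, 3.0]],
                             rt_flags=[True, False])
        out = prepare_behavior(table, meta)
        # 1/RT = [0.5, 0.25, 0.125] then standardized
        want = np.array([0.5, 0.25, 0.125])
        want = (want - want.mean()) / want.std()
        assert np.allclose(out["v0"], want)

    def test_all_columns_standardized(self, rng):
        table, meta = _table(rng.uniform(1, 5, (20, 6)))
        out = prepare_behavior(table, meta)
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert np.allclose(out.std(ddof=0), 1, atol=1e-12)

    def test_double_preparation_is_refused(self, rng):
        table, meta = _table(rng.uniform(1, 5, (10, 3)))
        out = prepare_behavior(table, meta)
        with pytest.raises(ValueError, match="already prepared"):
            prepare_behavior(out, meta)

    def test_nonpositive_rt_names_variable_and_subject(self):
        table, meta = _table([[1.0], [-2.0]], rt_flags=[True])
        with pytest.raises(ValueError, match="v0.*s1"):
            prepare_behavior(table, meta)

    def test_constant_column_rejected(self, rng):
        vals = rng.uniform(1, 5, (10, 3))
        vals[:, 1] = 2.0
        table, meta = _table(vals)
        with pytest.raises(ValueError, match="v1"):
            prepare_behavior(table, meta)


class TestPcaPermutationTest:
    def test_planted_rank_one_factor_gets_minimal_p(self, rng):
        factor = rng.standard_normal(40)
        loadings = rng.standard_normal(12)
        X = np.outer(factor, loadings) + 0.1 * rng.standard_normal((40, 12))
        table, meta = _table(X)
        res = pca_permutation_test(table, n_perm=200, seed=0)
        assert res["p_values"][0] == pytest.approx(1 / 201)
        assert 0 in res["significant"]

    def test_deterministic_under_seed(self, rng):
        table, meta = _table(rng.standard_normal((20, 8)))
        a = pca_permutation_test(table, n_perm=100, seed=3)
        b = pca_permutation_test(table, n_perm=100, seed=3)
        assert np.array_equal(a["p_values"], b["p_values"])

    def test_p_values_in_unit_interval(self, rng):
        table, _ = _table(rng.standard_normal((15, 6)))
        res = pca_permutation_test(table, n_perm=100, seed=1)
        assert ((res["p_values"] > 0) & (res["p_values"] <= 1)).all()

    def test_small_n_perm_rejected(self, rng):
        table, _ = _table(rng.standard_normal((10, 4)))
        with pytest.raises(ValueError):
            pca_permutation_test(table, n_perm=10, seed=0)


class TestSplithalfReproducibility:
    def test_strong_planted_factor_is_reproducible(self, rng):
        factor = rng.standard_normal(60)
        loadings = rng.standard_normal(15)
        X = np.outer(factor, loadings) + 0.1 * rng.standard_normal((60, 15))
        table, _ = _table(X)
        out = splithalf_reproducibility(table, n_perm=50, n_components=1, seed=0)
        assert out.loc[0, "similarity_mean"] >= 0.9

    def test_pure_noise_has_low_similarity(self, rng):
        table, _ = _table(rng.standard_normal((60, 40)))
        out = splithalf_reproducibility(table, n_perm=50, n_components=1, seed=0)
        # random unit vectors in 40 dims: |r| concentrates near 1/sqrt(40)
        assert out.loc[0, "similarity_mean"] < 0.5

    def test_rank_exceeding_half_sample_flagged(self, rng):
        table, _ = _table(rng.standard_normal((10, 6)))
        with pytest.raises(ValueError, match="rank"):
            splithalf_reproducibility(table, n_perm=10, n_components=5, seed=0)


class TestFitAssociation:
    def _inputs(self, rng, n=300, beta=0.5, noise=0.1):
        neural = pd.DataFrame(rng.standard_normal((n, 3)),
                              columns=["n1", "n2", "n3"],
                              index=[f"s{i}" for i in range(n)])
        cov = pd.DataFrame({"age": rng.integers(22, 38, n).astype(float),
                            "sex": rng.integers(0, 2, n).astype(float)},
                           index=neural.index)
        y = pd.Series(beta * neural["n1"] + noise * rng.standard_normal(n),
                      index=neural.index, name="y")
        return y, neural, cov

    def test_planted_coefficient_recovered_within_three_se(self, rng):
        y, neural, cov = self._inputs(rng)
        rep = fit_association(y, neural, cov)
        row = rep.params.loc["n1"]
        assert abs(row["beta"] - 0.5) < 3 * row["se"]
        for noise_pred in ("n2", "n3", "age", "sex"):
            assert rep.params.loc[noise_pred, "partial_r2"] < 0.02

    def test_exact_fit_gives_partial_r2_one(self, rng):
        y, neural, cov = self._inputs(rng, beta=1.0, noise=0.0)
        rep = fit_association(y, neural, cov)
        assert rep.params.loc["n1", "partial_r2"] == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_partial_r2_equals_squared_partial_correlation(self, rng):
        y, neural, cov = self._inputs(rng, beta=0.3, noise=1.0)
        rep = fit_association(y, neural, cov)
        X = pd.concat([neural, cov], axis=1).to_numpy()
        yv = y.to_numpy()
        import statsmodels.api as sm
        for j, name in enumerate(["n1", "n2", "n3", "age", "sex"]):
            others = np.delete(X, j, axis=1)
            ry = yv - sm.OLS(yv, sm.add_constant(others)).fit().fittedvalues
            rx = X[:, j] - sm.OLS(X[:, j], sm.add_constant(others)).fit().fittedvalues
            want = stats.pearsonr(ry, rx)[0] ** 2
            assert rep.params.loc[name, "partial_r2"] == pytest.approx(want, abs=1e-10)

    def test_collinear_predictors_rejected(self, rng):
        y, neural, cov = self._inputs(rng, n=50)
        neural["n3"] = 2 * neural["n1"] + 1e-12 * rng.standard_normal(50)
        with pytest.raises(ValueError, match="collinear"):
            fit_association(y, neural, cov)

    def test_too_few_cases_rejected(self, rng):
        y, neural, cov = self._inputs(rng, n=12)
        with pytest.raises(ValueError, match="too few"):
            fit_association(y, neural, cov)


class TestCrossvalPredict:
    def _tables(self, rng, n=80, link=1.0):
        latent = rng.standard_normal(n)
        neural = np.outer(latent, rng.standard_normal(10)) \
            + 0.3 * rng.standard_normal((n, 10))
        behav = link * np.outer(latent, rng.standard_normal(8)) \
            + 0.3 * rng.standard_normal((n, 8))
        idx = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"age": rng.integers(22, 38, n).astype(float),
                            "sex": rng.integers(0, 2, n).astype(float)}, index=idx)
        return (pd.DataFrame(neural, index=idx), pd.DataFrame(behav, index=idx),
                cov)

    def test_planted_link_beats_null(self, rng):
        neural, behav, cov = self._tables(rng, link=1.0)
        res = crossval_predict(neural, behav, cov, n_perm=40, seed=0)
        assert res["heldout_r2"].mean() > 0
        assert res["heldout_r2"].mean() > res["null_r2"].mean()

    def test_deterministic_under_seed(self, rng):
        neural, behav, cov = self._tables(rng)
        a = crossval_predict(neural, behav, cov, n_perm=10, seed=5)
        b = crossval_predict(neural, behav, cov, n_perm=10, seed=5)
        assert np.array_equal(a["heldout_r2"], b["heldout_r2"])

    def test_too_few_subjects_rejected(self, rng):
        neural, behav, cov = self._tables(rng, n=10)
        with pytest.raises(ValueError):
            crossval_predict(neural, behav, cov, n_perm=5, seed=0)


class TestSubgroupTtests:
    def test_family_size_bookkeeping(self, rng):
        scores = pd.DataFrame(rng.standard_normal((30, 15)),
                              columns=[f"PC{i+1}" for i in range(15)],
                              index=[f"s{i}" for i in range(30)])
        groups = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10,
                           index=scores.index)
        out = subgroup_ttests(scores, groups, n_components_tested=15)
        assert (out["family_size"] == 45).all()
        assert len(out) == 45
        ok = out["p"].notna()
        assert (out.loc[ok, "p_bonferroni"] >= out.loc[ok, "p"]).all()

    def test_planted_shift_detected_with_high_power(self, rng):
        hits = 0
        for trial in range(50):
            a = rng.standard_normal(100)
            b = rng.standard_normal(100) + 1.0
            scores = pd.DataFrame({"PC1": np.r_[a, b]},
                                  index=[f"s{i}" for i in range(200)])
            groups = pd.Series(["A"] * 100 + ["B"] * 100, index=scores.index)
            out = subgroup_ttests(scores, groups)
            if out["p"].iloc[0] < 0.05:
                hits += 1
        assert hits / 50 > 0.99 - 1e-9

    def test_tiny_subgroup_rejected(self, rng):
        scores = pd.DataFrame({"PC1": rng.standard_normal(10)},
                              index=[f"s{i}" for i in range(10)])
        groups = pd.Series(["A"] * 8 + ["B"] * 2, index=scores.index)
        with pytest.raises(ValueError):
            subgroup_ttests(scores, groups)
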