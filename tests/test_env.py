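"""VIF screening, RDA hierarchical partitioning, Mantel tests, OLS lines."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from slossgen.env import (
    euclidean_distance_matrix,
    fit_glm,
    hellinger,
    mantel_suite,
    mantel_test,
    rda_hierpart,
    transform_env,
    vif_screen,
)


def make_env(n, k, rng, corr=None):
    x = rng.normal(size=(n, k))
    if corr is not None:
        x[:, 1] = corr * x[:, 0] + np.sqrt(1 - corr**2) * x[:, 1]
    return pd.DataFrame(x, columns=[f"v{i}" for i in range(k)])


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 40
        x = np.zeros((n, 2))
        x[: n // 2, 0] = 1
        x[::2, 1] = 1  # exactly orthogonal to the centred first column
        x = x - x.mean(axis=0)
        env = pd.DataFrame(x, columns=["a", "b"])
        res = vif_screen(env, n_perm=9, seed=0)
        assert res.vif["a"] == pytest.approx(1.0)
        assert res.vif["b"] == pytest.approx(1.0)

    def test_known_correlation_closed_form(self, rng):
        # enforce sample correlation exactly 0.8 via Gram-Schmidt
        n = 200
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= (b @ a) / n * a  # orthogonalise
        b = b / b.std()
        x = 0.8 * a + np.sqrt(1 - 0.64) * b
        env = pd.DataFrame({"a": a, "x": x})
        res = vif_screen(env, n_perm=9, seed=0)
        assert res.vif["a"] == pytest.approx(1 / (1 - 0.64), rel=1e-6)

    def test_duplicated_column_infinite_and_excluded(self, rng):
        env = make_env(30, 2, rng)
        env["dup"] = env["v0"]
        res = vif_screen(env, n_perm=9, seed=0)
        assert np.isinf(res.vif["dup"]) or np.isinf(res.vif["v0"])
        assert len(res.excluded) >= 1
        assert "v1" in res.retained

    def test_matches_statsmodels_vif(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        env = make_env(50, 4, rng, corr=0.7)
        res = vif_screen(env, threshold=1e9, n_perm=9, seed=0)
        x = sm.add_constant(env.to_numpy())
        for j, col in enumerate(env.columns):
            want = variance_inflation_factor(x, j + 1)
            assert res.vif[col] == pytest.approx(want, rel=1e-8)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            vif_screen(make_env(4, 3, rng))


class TestHierPart:
    def test_single_predictor_contribution_is_marginal_r2(self, rng):
        env = make_env(25, 1, rng)
        y = pd.DataFrame(rng.normal(size=(25, 6)))
        res = rda_hierpart(y, env, n_perm=49, seed=1, transform="raw")
        assert res.contributions[0] == pytest.approx(res.r2_full, abs=1e-12)

    def test_orthogonal_predictors_additive(self):
        # balanced +/-1 design: columns exactly orthogonal after centring
        signs = np.array(list(itertools.product([-1, 1], repeat=2)) * 5, float)
        env = pd.DataFrame(signs, columns=["a", "b"])
        rng = np.random.default_rng(2)
        y = pd.DataFrame(
            1.5 * signs[:, [0]] - 0.7 * signs[:, [1]] + rng.normal(0, 1, (20, 3))
        )
        res = rda_hierpart(y, env, n_perm=49, seed=0, transform="raw")
        r2_a = rda_hierpart(y, env[["a"]], n_perm=9, seed=0, transform="raw").r2_full
        r2_b = rda_hierpart(y, env[["b"]], n_perm=9, seed=0, transform="raw").r2_full
        assert res.contributions[0] == pytest.approx(r2_a, abs=1e-10)
        assert res.contributions[1] == pytest.approx(r2_b, abs=1e-10)
        assert res.r2_full == pytest.approx(r2_a + r2_b, abs=1e-10)

    def test_k3_matches_all_orderings_enumeration(self, rng):
        """Average incremental R^2 over the 6 explicit orderings."""
        env = make_env(20, 3, rng, corr=0.5)
        y = pd.DataFrame(rng.normal(size=(20, 4)))
        res = rda_hierpart(y, env, n_perm=9, seed=0, transform="raw")

        def r2_of(subset):
            if not subset:
                return 0.0
            sub = env.iloc[:, list(subset)]
            return rda_hierpart(y, sub, n_perm=0, seed=0, transform="raw").r2_full

        for j in range(3):
            incs = []
            for order in itertools.permutations(range(3)):
                pos = order.index(j)
                before = set(order[:pos])
                incs.append(r2_of(before | {j}) - r2_of(before))
            assert res.contributions[j] == pytest.approx(np.mean(incs), abs=1e-10)

    def test_contributions_conserve_full_r2(self, rng):
        for k in (2, 3, 4):
            env = make_env(22, k, rng, corr=0.6)
            y = pd.DataFrame(rng.normal(size=(22, 5)))
            res = rda_hierpart(y, env, n_perm=9, seed=0, transform="raw")
            assert res.contributions.sum() == pytest.approx(res.r2_full, abs=1e-8)

    def test_hellinger_rows_unit_norm(self, rng):
        counts = pd.DataFrame(rng.integers(0, 10, size=(6, 8)) + 1)
        h = hellinger(counts)
        assert np.allclose((h**2).sum(axis=1), 1.0)

    def test_f_statistic_definition(self, rng):
        env = make_env(28, 6, rng)
        y = pd.DataFrame(rng.normal(size=(28, 10)))
        res = rda_hierpart(y, env, n_perm=9, seed=0, transform="raw")
        df1, df2 = res.df
        assert (df1, df2) == (6, 21)
        want = (res.r2_full / 6) / ((1 - res.r2_full) / 21)
        assert res.f_statistic == pytest.approx(want)

    def test_too_many_predictors_refused(self, rng):
        env = make_env(40, 13, rng)
        y = pd.DataFrame(rng.normal(size=(40, 3)))
        with pytest.raises(ValueError, match="12"):
            rda_hierpart(y, env)


class TestMantel:
    def d(self, vals):
        m = np.array(vals, float)
        return (m + m.T) / 2 if not np.allclose(m, m.T) else m

    def random_distance(self, rng, n):
        pts = rng.normal(size=(n, 2))
        diff = pts[:, None] - pts[None, :]
        return np.sqrt((diff**2).sum(-1))

    def test_self_correlation_one(self, rng):
        d1 = self.random_distance(rng, 6)
        res = mantel_test(d1, d1, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_reversed_matrix_minus_one(self, rng):
        d1 = self.random_distance(rng, 6)
        d2 = d1.max() - d1
        np.fill_diagonal(d2, 0.0)
        res = mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_exhaustive_enumeration_n4(self, rng):
        """Monte-Carlo p converges to the exact 24-permutation p."""
        import itertools as it

        d1 = self.random_distance(rng, 4)
        d2 = self.random_distance(rng, 4)
        tril = np.tril_indices(4, -1)
        v1 = d1[tril]
        r_obs = np.corrcoef(v1, d2[tril])[0, 1]
        count = sum(
            np.corrcoef(v1, d2[np.ix_(p, p)][tril])[0, 1] >= r_obs - 1e-12
            for p in map(list, it.permutations(range(4)))
        )
        p_exact = count / 24
        res = mantel_test(d1, d2, n_perm=19_999, seed=3)
        assert abs(res.p - p_exact) < 0.02

    def test_invariant_to_common_relabelling(self, rng):
        d1 = self.random_distance(rng, 7)
        d2 = self.random_distance(rng, 7)
        perm = rng.permutation(7)
        a = mantel_test(d1, d2, n_perm=499, seed=5)
        b = mantel_test(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)],
                        n_perm=499, seed=5)
        assert a.r == pytest.approx(b.r)
        assert abs(a.p - b.p) < 0.05

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as skbio_mantel

        d1 = self.random_distance(rng, 8)
        d2 = 0.7 * d1 + 0.3 * self.random_distance(rng, 8)
        np.fill_diagonal(d2, 0.0)
        r_sk = skbio_mantel(d1, d2, permutations=0, alternative="greater")[0]
        res = mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(float(r_sk), abs=1e-10)

    def test_constant_vector_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(d, d, n_perm=9)

    def test_asymmetric_rejected(self, rng):
        d1 = self.random_distance(rng, 4)
        bad = d1.copy()
        bad[0, 1] += 1
        with pytest.raises(ValueError, match="symmetric"):
            mantel_test(d1, bad)


class TestGlm:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res = fit_glm(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_log10_transform(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        res = fit_glm(np.array([0.0, 1.0, 2.0, 3.0]), x, transform="log10")
        assert res.slope == pytest.approx(1.0)

    def test_missing_values_dropped_with_warning(self):
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        x = np.arange(5, dtype=float)
        with pytest.warns(UserWarning, match="missing"):
            res = fit_glm(y, x)
        assert res.n == 4

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_glm(np.arange(4.0), np.ones(4))

    def test_type_one_error_calibrated(self):
        """Null slope test rejects at ~5% over permuted data (n=28)."""
        rng = np.random.default_rng(99)
        n_rep, n = 2000, 28
        hits = 0
        for _ in range(n_rep):
            res = fit_glm(rng.normal(size=n), rng.normal(size=n))
            hits += res.p_value < 0.05
        rate = hits / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3.5 * se

    def test_richness_increases_with_area_on_synthetic(self, default_system, default_view):
        haps, _ = default_view
        h = (haps.occurrence > 0).sum(axis=0)
        res = fit_glm(
            h.to_numpy(float),
            default_system.islands.loc[h.index, "AREA"].to_numpy(),
            transform="log10",
        )
        assert res.slope > 0
        assert res.p_value < 0.05


class TestSuitePlumbing:
    def test_transform_env_log10(self):
        env = pd.DataFrame({"AREA": [1.0, 10.0], "FRE": [1, 2]})
        out = transform_env(env)
        assert out["AREA"].tolist() == [0.0, 1.0]
        assert out["FRE"].tolist() == [1.0, 2.0]

    def test_euclidean_distance_standardized(self):
        vals = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        d = euclidean_distance_matrix(vals)
        assert d.loc["a", "c"] == pytest.approx(2 * d.loc["a", "b"])
        assert np.allclose(np.diag(d), 0)

    def test_mantel_suite_shape(self, default_system, default_view):
        haps, tree = default_view
        from slossgen.haplotypes import diversity_table
        from slossgen.phylo import pd_by_island

        div = diversity_table(
            haps,
            default_system.alignment,
            default_system.island_map,
            pd_by_island(tree, haps.occurrence),
        )
        env = default_system.islands[["AREA", "COA", "ISD", "ISW", "POP", "FRE"]]
        out = mantel_suite(env, div, n_perm=49, seed=1)
        assert set(out["metric"]) <= {"H", "Hd", "Pi", "PD"}
        assert len(out) == 6 * len(set(out["metric"]))
        assert out["r"].between(-1, 1).all()
        assert out["p"].between(0, 1).all()
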