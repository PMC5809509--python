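"""Environmental ordination, OLS/AIC, stepwise, Mantel, MRM and
variation partitioning."""

import numpy as np
import pandas as pd
import pytest

from elevphylo import (
    DataError,
    PairwiseDistance,
    build_distances,
    choose_poly_model,
    env_pca,
    mantel,
    mrm,
    ols_poly,
    simple_ols_screen,
    stepwise_forward,
    variation_partition,
)


def _env(n=10, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    e = 250.0 + 100.0 * np.arange(n)
    df = pd.DataFrame({
        "elevation": e,
        "RArea": 7.0 - 0.002 * e + rng.normal(0, 0.05, n),
        "c1": 15.0 - 0.006 * e + rng.normal(0, 0.2, n),
        "c2": 6.9 + 0.0004 * e + rng.normal(0, 0.02, n),
        "h1": rng.normal(5, 1, n),
        "h2": rng.normal(40, 5, n),
    }, index=[int(b) for b in e - 50])
    return df


class TestEnvPca:
    def test_pc_columns_attached(self):
        env = env_pca(_env(), ["c1", "c2"], ["h1", "h2"])
        for col in ("PC1_clim", "PC1_hetero", "PC2_hetero"):
            assert col in env.columns

    def test_collinear_climate_gives_dominant_axis(self):
        env = _env()
        env["c1"] = 15.0 - 0.006 * env["elevation"]
        env["c2"] = 2.0 * env["c1"]
        out = env_pca(env, ["c1", "c2"], ["h1", "h2"])
        # PC1 of two perfectly collinear climate variables carries all
        # variance, hence is itself collinear with elevation
        r = np.corrcoef(out["PC1_clim"], out["elevation"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_bands(self):
        with pytest.raises(DataError):
            env_pca(_env(n=2), ["c1"], ["h1"])


class TestDistances:
    def test_elevational_difference(self):
        env = env_pca(_env(), ["c1", "c2"], ["h1", "h2"])
        ds = build_distances(env)
        a, b = str(env.index[0]), str(env.index[5])
        assert ds.ele.get(a, b) == pytest.approx(500.0)

    def test_identical_bands_zero(self):
        env = env_pca(_env(), ["c1", "c2"], ["h1", "h2"])
        ds = build_distances(env)
        for m in ds.as_dict().values():
            assert np.all(np.diag(m.D) == 0)

    def test_habitat_matches_euclidean_loop(self):
        env = env_pca(_env(seed=3), ["c1", "c2"], ["h1", "h2"])
        ds = build_distances(env)
        H = env[["PC1_hetero", "PC2_hetero"]].to_numpy()
        for i in range(len(env)):
            for j in range(len(env)):
                expect = np.hypot(*(H[i] - H[j]))
                assert ds.habit.D[i, j] == pytest.approx(expect, abs=1e-10)

    def test_missing_column_error(self):
        with pytest.raises(DataError, match="PC1_clim"):
            build_distances(_env())


class TestOlsPoly:
    def test_exact_linear(self):
        x = pd.Series(np.arange(10.0))
        fit = ols_poly(2.0 * x, x, degree=1)
        assert fit.coef["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_exact_quadratic_beats_linear(self):
        x = pd.Series(np.arange(10.0))
        y = (x - x.mean()) ** 2
        lin, quad, best = choose_poly_model(y, x)
        assert best == "quadratic"
        assert quad.r2 == pytest.approx(1.0)
        assert quad.aic < lin.aic

    def test_noise_free_linear_prefers_linear(self):
        x = pd.Series(np.arange(12.0))
        lin, quad, best = choose_poly_model(1.0 + 0.5 * x, x)
        assert best == "linear"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        x = pd.Series(rng.uniform(0, 100, 15))
        y = pd.Series(rng.normal(size=15))
        fit = ols_poly(y, x, degree=2)
        xc = x - x.mean()
        X = np.column_stack([np.ones(15), xc, xc**2])
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        np.testing.assert_allclose(fit.coef.to_numpy(), beta, atol=1e-8)

    def test_aic_difference_invariant_to_scaling(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.uniform(0, 10, 12))
        y = pd.Series(rng.normal(size=12))
        d1 = ols_poly(y, x, 1).aic - ols_poly(y, x, 2).aic
        d2 = ols_poly(100 * y, x, 1).aic - ols_poly(100 * y, x, 2).aic
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_degenerate_design(self):
        x = pd.Series([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(DataError):
            ols_poly(pd.Series([1.0, 2.0, 3.0, 4.0]), x, degree=2)


class TestScreen:
    def test_self_prediction_r2_one(self):
        env = _env()
        y = env["RArea"]
        scr = simple_ols_screen(y, env, predictors=["RArea"])
        assert scr.loc["RArea", "r2"] == pytest.approx(1.0)

    def test_orthogonal_predictor_r2_zero(self):
        env = _env().iloc[:8].copy()
        # construct a predictor whose covariance with y is exactly zero
        y = pd.Series(np.arange(8.0), index=env.index)
        yc = (y - y.mean()).to_numpy()
        w = np.random.default_rng(9).normal(size=8)
        v = w - (w @ yc) / (yc @ yc) * yc
        env["orth"] = v
        scr = simple_ols_screen(y, env, predictors=["orth"])
        assert scr.loc["orth", "r2"] < 1e-12

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        env = _env(seed=4)
        y = pd.Series(rng.normal(size=len(env)), index=env.index)
        scr = simple_ols_screen(y, env, predictors=["c1", "h1"])
        for name in ("c1", "h1"):
            r = np.corrcoef(y, env[name])[0, 1]
            assert scr.loc[name, "r2"] == pytest.approx(r**2, abs=1e-10)


class TestStepwise:
    def test_true_predictor_selected_first(self):
        rng = np.random.default_rng(0)
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 4)),
                         columns=["a", "b", "c", "d"])
        y = 3.0 * X["b"] + rng.normal(scale=1.0, size=n)
        fit = stepwise_forward(pd.Series(y), X)
        assert "b" in fit.terms
        assert fit.terms[1] == "b"  # after the constant

    def test_alpha_zero_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=20))
        fit = stepwise_forward(y, X, alpha_enter=0.0)
        assert fit.extra["intercept_only"]

    def test_noise_first_entry_rate_bounded(self):
        """With pure-noise candidates the chance that anything enters is
        roughly bounded by alpha * n_candidates."""
        rng = np.random.default_rng(2)
        entered = 0
        reps = 120
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
            y = pd.Series(rng.normal(size=25))
            fit = stepwise_forward(y, X, alpha_enter=0.05)
            entered += not fit.extra["intercept_only"]
        assert entered / reps < 0.30  # loose bound on 3 * 0.05 plus noise


def _dist_from_points(pts, labels=None) -> PairwiseDistance:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = labels or [f"i{k}" for k in range(len(pts))]
    return PairwiseDistance(labels, D)


class TestMantel:
    def test_identical_matrices_r_one(self):
        d = _dist_from_points(np.random.default_rng(0).uniform(0, 9, 6))
        r, _ = mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_reversal_r_minus_one(self):
        d = _dist_from_points(np.random.default_rng(1).uniform(0, 9, 6))
        rev = PairwiseDistance(d.labels, np.where(np.eye(6, dtype=bool),
                                                  0.0, d.D.max() - d.D))
        r, _ = mantel(rev, d, n_perm=99, seed=0, exhaustive=True)
        assert r < -0.9

    def test_exhaustive_matches_sampled(self):
        rng = np.random.default_rng(2)
        dy = _dist_from_points(rng.uniform(0, 5, 5))
        dx = _dist_from_points(rng.uniform(0, 5, 5), labels=dy.labels)
        r_ex, p_ex = mantel(dy, dx, exhaustive=True)
        r_s, p_s = mantel(dy, dx, n_perm=50000, seed=3, exhaustive=False)
        assert r_ex == pytest.approx(r_s)
        se = np.sqrt(p_ex * (1 - p_ex) / 50000)
        assert abs(p_s - p_ex) < 3 * se + 1 / 50001

    def test_constant_distances_error(self):
        D = np.full((5, 5), 2.0)
        np.fill_diagonal(D, 0.0)
        c = PairwiseDistance(list("abcde"), D)
        with pytest.raises(DataError):
            mantel(c, c, n_perm=9, seed=0)


class TestMrm:
    def test_single_predictor_reduces_to_mantel(self):
        rng = np.random.default_rng(3)
        dy = _dist_from_points(rng.uniform(0, 5, 7))
        dx = _dist_from_points(rng.uniform(0, 5, 7), labels=dy.labels)
        r, _ = mantel(dy, dx, n_perm=99, seed=0)
        res = mrm(dy, {"x": dx}, n_perm=99, seed=0)
        assert np.sqrt(res["r2"]) == pytest.approx(abs(r), abs=1e-10)
        assert np.sign(res["coef"]["x"]) == np.sign(r)

    def test_exact_linear_combination_recovered(self):
        rng = np.random.default_rng(4)
        d1 = _dist_from_points(rng.uniform(0, 5, 8))
        d2 = _dist_from_points(rng.uniform(0, 5, 8), labels=d1.labels)
        Dy = 2.0 * d1.D + 0.5 * d2.D
        dy = PairwiseDistance(d1.labels, Dy)
        res = mrm(dy, {"a": d1, "b": d2}, n_perm=49, seed=0)
        assert res["r2"] == pytest.approx(1.0)
        assert res["coef"]["a"] == pytest.approx(2.0, abs=1e-8)
        assert res["coef"]["b"] == pytest.approx(0.5, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_normal_equations_on_triangles(self, seed):
        rng = np.random.default_rng(seed)
        dy = _dist_from_points(rng.uniform(0, 5, 9))
        d1 = _dist_from_points(rng.uniform(0, 5, 9), labels=dy.labels)
        d2 = _dist_from_points(rng.uniform(0, 5, 9), labels=dy.labels)
        res = mrm(dy, {"a": d1, "b": d2}, n_perm=9, seed=0)
        iu = np.triu_indices(9, 1)
        X = np.column_stack([np.ones(len(iu[0])), d1.D[iu], d2.D[iu]])
        beta = np.linalg.solve(X.T @ X, X.T @ dy.D[iu])
        np.testing.assert_allclose(res["coef"].to_numpy(), beta, atol=1e-8)

    def test_collinear_predictors_error_names_pair(self):
        rng = np.random.default_rng(5)
        d1 = _dist_from_points(rng.uniform(0, 5, 6))
        d2 = PairwiseDistance(d1.labels, 2.0 * d1.D)
        dy = _dist_from_points(rng.uniform(0, 5, 6), labels=d1.labels)
        with pytest.raises(DataError, match="a.*b|b.*a"):
            mrm(dy, {"a": d1, "b": d2}, n_perm=9, seed=0)


class TestVariationPartition:
    def _groups(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        A = pd.DataFrame({"a1": rng.normal(size=n)})
        B = pd.DataFrame({"b1": rng.normal(size=n)})
        C = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        return {"A": A, "B": B, "C": C}

    def test_single_source_orthogonal_groups(self):
        n = 40
        rng = np.random.default_rng(1)
        # mutually orthogonal columns, also orthogonal to the intercept
        M = np.column_stack([np.ones(n), rng.normal(size=(n, 4))])
        Q, _ = np.linalg.qr(M)
        groups = {"A": pd.DataFrame({"a": Q[:, 1]}),
                  "B": pd.DataFrame({"b": Q[:, 2]}),
                  "C": pd.DataFrame({"c": Q[:, 3]})}
        y = pd.Series(5.0 * Q[:, 1] + 0.01 * Q[:, 4])
        out = variation_partition(y, groups)
        assert out["unique"]["B"] == pytest.approx(0.0, abs=1e-8)
        assert out["unique"]["C"] == pytest.approx(0.0, abs=1e-8)
        assert out["combined"] == pytest.approx(0.0, abs=1e-8)
        assert out["unique"]["A"] > 0.99

    def test_duplicated_groups_share_everything(self):
        rng = np.random.default_rng(2)
        n = 30
        a = rng.normal(size=n)
        groups = {"A": pd.DataFrame({"a": a}),
                  "B": pd.DataFrame({"b": a + 1e-9 * rng.normal(size=n)}),
                  "C": pd.DataFrame({"c": rng.normal(size=n)})}
        y = pd.Series(2.0 * a + 0.1 * rng.normal(size=n))
        out = variation_partition(y, groups)
        assert out["unique"]["A"] == pytest.approx(0.0, abs=1e-3)
        assert out["unique"]["B"] == pytest.approx(0.0, abs=1e-3)
        assert out["combined"] > 0.9 * out["r2_full"]

    @pytest.mark.parametrize("seed", range(3))
    def test_subset_r2_matches_independent_fits(self, seed):
        rng = np.random.default_rng(seed)
        groups = self._groups(seed=seed)
        y = pd.Series(rng.normal(size=30))
        out = variation_partition(y, groups)
        for combo, r2 in out["subset_r2"].items():
            X = pd.concat([groups[g] for g in combo], axis=1).to_numpy()
            X = np.column_stack([np.ones(30), X])
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            resid = y.to_numpy() - X @ beta
            tss = np.sum((y - y.mean()) ** 2)
            assert r2 == pytest.approx(1 - resid @ resid / tss, abs=1e-8)

    def test_fraction_identity(self):
        rng = np.random.default_rng(7)
        groups = self._groups(seed=7)
        y = pd.Series(rng.normal(size=30))
        out = variation_partition(y, groups)
        total = (sum(out["unique"].values()) + out["combined"]
                 + out["residual"])
        assert total == pytest.approx(1.0, abs=1e-10)


class TestMantelCrossCheck:
    def test_r_matches_scikit_bio(self):
        """Independent implementation check: scikit-bio's Mantel statistic
        on the same pair of matrices."""
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(6)
        dy = _dist_from_points(rng.uniform(0, 5, 8))
        dx = _dist_from_points(rng.uniform(0, 5, 8), labels=dy.labels)
        r_ours, p_ours = mantel(dy, dx, n_perm=9999, seed=1)
        r_sk, p_sk, _ = skbio_mantel(DistanceMatrix(dy.D, dy.labels),
                                     DistanceMatrix(dx.D, dx.labels),
                                     method="pearson", permutations=9999,
                                     alternative="two-sided")
        assert r_ours == pytest.approx(float(r_sk), abs=1e-10)
        # both p-values are permutation estimates of the same quantity
        assert p_ours == pytest.approx(float(p_sk), abs=0.02)
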