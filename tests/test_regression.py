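import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from melanoclime.regression import (
    grouped_interaction_fit,
    hierarchical_partitioning,
    morans_correlogram,
    morans_first_class_permutation,
    ols_fit,
    severity_models,
    trend_surface_fit,
    zscale,
)
from oracles import hierpart_by_orderings, ols_normal_equations


class TestZScale:
    def test_mean_zero_sd_one(self):
        out, _ = zscale(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a"].std(ddof=0) == pytest.approx(1.0)

    def test_already_scaled_unchanged(self):
        x = pd.DataFrame({"a": [-1.224744871391589, 0.0, 1.224744871391589]})
        out, _ = zscale(x)
        assert np.allclose(out["a"], x["a"], atol=1e-12)

    def test_round_trip(self):
        x = pd.DataFrame({"a": [3.0, 9.0, 27.0], "b": [0.1, 0.4, 0.2]})
        out, sc = zscale(x)
        pd.testing.assert_frame_equal(sc.inverse(out), x)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            zscale(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = ols_fit(3 + 2 * x, pd.DataFrame({"x": x}))
        assert res.coef == pytest.approx([3.0, 2.0])
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_and_statsmodels(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        y = 1 + X @ [2.0, -1.0, 0.5] + rng.standard_normal(50)
        res = ols_fit(y.to_numpy(), X)
        beta, se, r2 = ols_normal_equations(y.to_numpy(), X.to_numpy())
        assert np.allclose(res.coef, beta, atol=1e-10)
        assert np.allclose(res.se, se, atol=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        smres = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        assert np.allclose(res.p, smres.pvalues, atol=1e-10)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.standard_normal(30)})
        y = 2 * X["x"].to_numpy() + rng.standard_normal(30)
        res1 = ols_fit(y, X)
        perm = rng.permutation(30)
        res2 = ols_fit(y[perm], X.iloc[perm].reset_index(drop=True))
        assert np.allclose(res1.coef, res2.coef)
        assert res1.r_squared == pytest.approx(res2.r_squared)

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError):
            ols_fit(np.arange(4.0), X)


class TestTrendSurface:
    def _spatial_data(self, seed=0, n=400, latent=True):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10, (n, 2))
        X = pd.DataFrame({"x1": rng.standard_normal(n)})
        latent_field = 2.0 * np.sin(coords[:, 0]) + np.cos(1.3 * coords[:, 1])
        y = 2.0 * X["x1"].to_numpy() + (latent_field if latent else 0.0) \
            + 0.3 * rng.standard_normal(n)
        return y, X, coords

    def test_pure_linear_signal_matches_ols_within_two_se(self):
        y, X, coords = self._spatial_data(seed=3, latent=False)
        ts = trend_surface_fit(y, X, coords)
        ols = ols_fit(y, X)
        assert abs(ts.term("x1")["slope"] - ols.term("x1")["slope"]) < 2 * ols.term("x1")["se"]

    def test_r_squared_never_below_no_surface_model(self):
        for seed in range(4):
            y, X, coords = self._spatial_data(seed=seed)
            ts = trend_surface_fit(y, X, coords)
            assert ts.r_squared >= ols_fit(y, X).r_squared - 1e-10

    def test_infinite_smoothing_limit_is_penalty_null_space_fit(self):
        # as smoothing -> infinity only the penalty's null space survives:
        # (near-)planar index-linear trends of the two coordinates
        from melanoclime import regression as R

        y, X, coords = self._spatial_data(seed=5)
        ts = trend_surface_fit(y, X, coords, smoothing=1e10)
        n = len(y)
        kx, ky = 10, 10
        Bx = R._bspline_basis(R._unit_scale(coords[:, 0]), kx)
        By = R._bspline_basis(R._unit_scale(coords[:, 1]), ky)
        Z = (Bx[:, :, None] * By[:, None, :]).reshape(n, kx * ky)
        P = np.kron(R._second_diff_penalty(kx), np.eye(ky)) \
            + np.kron(np.eye(kx), R._second_diff_penalty(ky))
        c = Z.sum(axis=0, keepdims=True)
        _, _, Vt = np.linalg.svd(c, full_matrices=True)
        Q = Vt[1:].T
        Pc = Q.T @ P @ Q
        w, V = np.linalg.eigh(Pc)
        null = (Z @ Q) @ V[:, w < 1e-8 * w.max()]
        Xp = pd.concat([X.reset_index(drop=True),
                        pd.DataFrame(null, columns=[f"n{i}" for i in range(null.shape[1])])],
                       axis=1)
        limit = ols_fit(y, Xp)
        assert np.allclose(ts.fitted, limit.fitted, atol=1e-5)
        # and the surviving trend is approximately planar in the coordinates
        approx = ols_fit(ts.fitted, pd.DataFrame(
            {"cx": coords[:, 0], "cy": coords[:, 1],
             "cxy": coords[:, 0] * coords[:, 1], "x1": X["x1"]}))
        assert approx.r_squared > 0.999

    def test_surface_absorbs_latent_spatial_field(self):
        y, X, coords = self._spatial_data(seed=7, latent=True)
        ts = trend_surface_fit(y, X, coords)
        ols = ols_fit(y, X)
        assert ts.r_squared > ols.r_squared + 0.2
        assert ts.term("x1")["slope"] == pytest.approx(2.0, abs=0.1)

    def test_basis_larger_than_n_rejected(self):
        y, X, coords = self._spatial_data(n=50)
        with pytest.raises(ValueError):
            trend_surface_fit(y, X, coords, n_basis=(10, 10))


class TestHierarchicalPartitioning:
    def test_single_predictor_equals_marginal_r2(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.standard_normal(40)})
        y = X["a"].to_numpy() + rng.standard_normal(40)
        hp = hierarchical_partitioning(y, X)
        assert hp.independent[0] == pytest.approx(ols_fit(y, X).r_squared, abs=1e-12)

    def test_orthogonal_predictors_get_marginal_contributions(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)})
        y = 2 * X["a"].to_numpy() + 1 * X["b"].to_numpy()
        hp = hierarchical_partitioning(y, X)
        for j, c in enumerate(X.columns):
            assert hp.independent[j] == pytest.approx(
                ols_fit(y, X[[c]]).r_squared, abs=1e-8)

    def test_matches_brute_force_over_orderings(self):
        rng = np.random.default_rng(2)
        for rep in range(5):
            X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
            y = X @ rng.normal(0, 1, 4) + rng.standard_normal(30)
            hp = hierarchical_partitioning(y.to_numpy(), X)
            oracle = hierpart_by_orderings(y.to_numpy(), X)
            assert np.allclose(hp.independent, oracle, atol=1e-10)
            assert hp.independent.sum() == pytest.approx(hp.full_r_squared, abs=1e-10)

    def test_combinatorial_guard(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((20, 9)))
        X.columns = [f"v{i}" for i in range(9)]
        with pytest.raises(ValueError):
            hierarchical_partitioning(np.zeros(20), X)


class TestGroupedInteractions:
    def test_two_groups_with_opposite_slopes(self):
        rng = np.random.default_rng(3)
        n = 200
        g = np.repeat(["u", "v"], n // 2)
        x = rng.standard_normal(n)
        y = np.where(g == "u", 2.0 * x, -2.0 * x) + 0.5 * rng.standard_normal(n)
        res = grouped_interaction_fit(y, pd.DataFrame({"x": x}), g, min_group_size=10)
        est = res.estimates.set_index("group")
        su, sv = est.loc["u", "slope"], est.loc["v", "slope"]
        assert su > 0 > sv
        assert abs(su - 2.0 * x[g == "u"].std(ddof=0)) < 2 * est.loc["u", "se"]

    def test_small_group_excluded_at_threshold(self):
        rng = np.random.default_rng(4)
        g = ["big"] * 30 + ["small"] * 9
        x = rng.standard_normal(39)
        res = grouped_interaction_fit(x * 2, pd.DataFrame({"x": x}), g, min_group_size=10)
        assert "small" in res.excluded_groups
        assert set(res.estimates["group"]) == {"big"}

    def test_single_group_matches_plain_fit(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        y = 1 + 3 * x + 0.1 * rng.standard_normal(50)
        res = grouped_interaction_fit(y, pd.DataFrame({"x": x}), ["g"] * 50,
                                      min_group_size=1, z_scale=False)
        plain = ols_fit(y, pd.DataFrame({"x": x}))
        assert res.estimates["slope"].iloc[0] == pytest.approx(plain.term("x")["slope"])
        assert res.r_squared == pytest.approx(plain.r_squared)


class TestSeverityModels:
    def _data(self, interaction, seed=0, n_per_family=30, n_families=4):
        rng = np.random.default_rng(seed)
        rows = []
        for f in range(n_families):
            light = rng.uniform(90, 240, n_per_family)
            evi = rng.uniform(0.1, 0.8, n_per_family)
            zl = (light - light.mean()) / light.std()
            ze = (evi - evi.mean()) / evi.std()
            sev = 2 + interaction * zl * ze + 0.3 * rng.standard_normal(n_per_family)
            for i in range(n_per_family):
                rows.append({"species_id": f"f{f}s{i}", "family": f"fam{f}",
                             "severity": max(sev[i], 0.0), "lightness": light[i],
                             "EVI": evi[i]})
        return pd.DataFrame(rows)

    def test_family_size_threshold_nine(self):
        d = self._data(0.5, n_per_family=9)
        small = self._data(0.5, seed=1, n_per_family=8, n_families=1)
        small["family"] = "tiny"
        small["species_id"] = "t" + small["species_id"]
        per_family, _ = severity_models(pd.concat([d, small], ignore_index=True))
        assert "tiny" in per_family.excluded_groups
        assert set(per_family.estimates["group"]) == {f"fam{i}" for i in range(4)}

    def test_planted_positive_interaction_recovered(self):
        hits = 0
        for seed in range(10):
            d = self._data(0.8, seed=seed)
            per_family, _ = severity_models(d)
            hits += (per_family.estimates["slope"] > 0).mean() >= 0.75
        assert hits >= 8

    def test_null_interaction_false_positive_rate_near_alpha(self):
        sig = []
        for seed in range(30):
            d = self._data(0.0, seed=seed, n_families=2)
            per_family, _ = severity_models(d)
            sig.extend((per_family.estimates["p"] < 0.05).tolist())
        assert np.mean(sig) < 0.15  # nominal 0.05 plus Monte-Carlo slack


class TestMoransI:
    def test_iid_noise_within_permutation_band(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 20, (150, 2))
        z = rng.standard_normal(150)
        obs, nm, nsd = morans_first_class_permutation(z, coords, class_width=3.0,
                                                      n_perm=199, seed=1)
        assert abs(obs - nm) < 3 * nsd

    def test_smooth_gradient_has_strong_first_class_autocorrelation(self):
        xs, ys = np.meshgrid(np.arange(12.0), np.arange(12.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        z = coords[:, 0] + coords[:, 1]
        cg = morans_correlogram(z, coords, n_classes=8)
        assert cg.morans_i[0] > 0.5

    def test_two_points_single_class_is_finite(self):
        cg = morans_correlogram([1.0, -1.0], [[0, 0], [1, 0]], n_classes=1)
        assert np.isfinite(cg.morans_i[0])
        assert cg.expected == pytest.approx(-1.0)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            morans_correlogram([1.0, 1.0, 1.0], [[0, 0], [1, 0], [2, 0]], n_classes=1)

    def test_classes_partition_the_distance_range(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 10, (60, 2))
        z = rng.standard_normal(60)
        cg = morans_correlogram(z, coords, n_classes=6)
        assert len(cg.bounds) == 7
        assert cg.n_pairs.sum() == 60 * 59 // 2
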