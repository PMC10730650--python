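import random

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cholesky

from melanoclime.phylo import (
    fit_pagel_lambda,
    graft_missing_species,
    lambda_transform,
    lynch_decompose,
    pagel_loglik,
    pgls_fit,
    prune_to_species,
    read_newick,
    vcv_from_tree,
    write_newick,
)
from melanoclime.regression import ols_fit
from oracles import brute_force_vcv, mvn_profile_loglik_dense, random_ultrametric_tree


def _bm_trait(tree, seed, scale=1.0):
    cov = vcv_from_tree(tree)
    L = cholesky(cov.matrix + 1e-12 * np.eye(len(cov.tips)), lower=True)
    rng = np.random.default_rng(seed)
    return pd.Series(scale * (L @ rng.standard_normal(len(cov.tips))), index=cov.tips), cov


class TestCovariance:
    def test_two_tip_star(self):
        t = read_newick("(A:1,B:1);", from_string=True)
        cov = vcv_from_tree(t)
        assert np.allclose(cov.matrix, np.eye(2))

    def test_three_tip_worked_example(self):
        t = read_newick("((A:1,B:1):1,C:2);", from_string=True)
        cov = vcv_from_tree(t)
        idx = {l: i for i, l in enumerate(cov.tips)}
        M = cov.matrix
        assert M[idx["A"], idx["A"]] == M[idx["B"], idx["B"]] == M[idx["C"], idx["C"]] == 2
        assert M[idx["A"], idx["B"]] == 1
        assert M[idx["A"], idx["C"]] == 0

    def test_negative_branch_rejected(self):
        t = read_newick("((A:1,B:-1):1,C:2);", from_string=True)
        with pytest.raises(ValueError):
            vcv_from_tree(t)

    def test_matches_pairwise_mrca_brute_force_on_random_trees(self):
        rng = random.Random(11)
        for _ in range(20):
            t = random_ultrametric_tree(rng.randint(10, 30), rng)
            cov = vcv_from_tree(t)
            C_bf, labels = brute_force_vcv(t)
            order = [labels.index(lbl) for lbl in cov.tips]
            assert np.allclose(cov.matrix, C_bf[np.ix_(order, order)], atol=1e-12)


class TestLambdaTransform:
    def setup_method(self):
        self.t = read_newick("((A:1,B:1):1,C:2);", from_string=True)
        self.cov = vcv_from_tree(self.t)

    def test_identity_at_one(self):
        assert np.allclose(lambda_transform(self.cov, 1.0), self.cov.matrix)

    def test_diagonal_at_zero(self):
        out = lambda_transform(self.cov, 0.0)
        assert np.allclose(out, np.diag(np.diag(self.cov.matrix)))

    def test_halving_off_diagonals(self):
        out = lambda_transform(self.cov, 0.5)
        idx = {l: i for i, l in enumerate(self.cov.tips)}
        assert out[idx["A"], idx["B"]] == 0.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lambda_transform(self.cov, 1.2)

    def test_preserves_positive_semidefiniteness(self):
        rng = random.Random(3)
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            t = random_ultrametric_tree(15, rng)
            out = lambda_transform(vcv_from_tree(t), lam)
            assert np.linalg.eigvalsh(out).min() > -1e-10


class TestPagelLambda:
    def test_star_tree_unidentifiable(self):
        t = read_newick("(A:1,B:1,C:1,D:1);", from_string=True)
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=["A", "B", "C", "D"])
        fit = fit_pagel_lambda(y, t)
        assert not fit.identifiable
        assert fit.lambda_hat == 0.0

    def test_loglik_matches_dense_mvn_evaluation(self):
        rng = random.Random(5)
        for _ in range(10):
            n = rng.randint(3, 6)
            t = random_ultrametric_tree(n, rng)
            cov = vcv_from_tree(t)
            nprng = np.random.default_rng(rng.randint(0, 10**6))
            y = pd.Series(nprng.normal(10, 3, n), index=cov.tips)
            for lam in (0.0, 0.5, 1.0):
                mine = pagel_loglik(y, cov, lam)
                dense = mvn_profile_loglik_dense(y.to_numpy(), lambda_transform(cov, lam))
                assert mine == pytest.approx(dense, abs=1e-8)

    def test_brownian_trait_recovers_high_lambda(self):
        t = random_ultrametric_tree(200, random.Random(17))
        y, _ = _bm_trait(t, seed=17)
        assert fit_pagel_lambda(y, t).lambda_hat >= 0.9

    def test_constant_trait_rejected(self):
        t = random_ultrametric_tree(5, random.Random(1))
        y = pd.Series(1.0, index=[lf.taxon.label for lf in t.leaf_node_iter()])
        with pytest.raises(ValueError):
            fit_pagel_lambda(y, t)


class TestLynchDecomposition:
    def test_additivity_and_monotone_loglik(self):
        t = random_ultrametric_tree(60, random.Random(2))
        y, cov = _bm_trait(t, seed=2, scale=5.0)
        y = y + np.random.default_rng(3).normal(0, 2, len(y))
        dec = lynch_decompose(y, t)
        assert np.max(np.abs(dec.raw - (dec.grand_mean + dec.P + dec.S))) < 1e-8
        assert np.all(np.diff(dec.loglik_trace) >= -1e-7 * np.abs(dec.loglik_trace[:-1]))
        assert dec.sigma2_phylo >= 0 and dec.sigma2_resid >= 0

    def test_pure_brownian_trait_has_small_residual_share(self):
        t = random_ultrametric_tree(200, random.Random(8))
        y, _ = _bm_trait(t, seed=8, scale=10.0)
        dec = lynch_decompose(y, t)
        share = dec.sigma2_resid / (dec.sigma2_phylo + dec.sigma2_resid)
        assert share < 0.1

    def test_matches_independent_em_oracle_on_four_tips(self):
        # independently coded EM in the observation basis (dense matrices,
        # no eigendecomposition), run in lockstep from the same start: the
        # variance-component trajectories must coincide step for step
        t = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);", from_string=True)
        y = pd.Series([3.0, 2.4, -1.0, 0.5], index=["A", "B", "C", "D"])
        cov = vcv_from_tree(t)
        C = cov.matrix
        yv = y.loc[cov.tips].to_numpy()
        n = 4
        n_steps = 50
        s2a = s2e = float(yv.var() / 2)
        one = np.ones(n)
        Ci = np.linalg.inv(C)
        for _ in range(n_steps):
            V = s2a * C + s2e * np.eye(n)
            Vi = np.linalg.inv(V)
            mu = (one @ Vi @ yv) / (one @ Vi @ one)
            r = yv - mu
            a_hat = s2a * C @ Vi @ r
            Va = s2a * C - s2a * C @ Vi @ (s2a * C)
            e_hat = r - a_hat
            Ve = s2e * np.eye(n) - s2e**2 * Vi
            s2a = (a_hat @ Ci @ a_hat + np.trace(Ci @ Va)) / n
            s2e = (e_hat @ e_hat + np.trace(Ve)) / n
        dec = lynch_decompose(y, t, tol=0.0, max_iter=n_steps)
        assert dec.sigma2_phylo == pytest.approx(s2a, rel=1e-10)
        assert dec.sigma2_resid == pytest.approx(s2e, rel=1e-10)
        assert np.max(np.abs(dec.raw - (dec.grand_mean + dec.P + dec.S))) < 1e-8

    def test_too_few_species_rejected(self):
        t = read_newick("((A:1,B:1):1,C:2);", from_string=True)
        y = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "C"])
        with pytest.raises(ValueError):
            lynch_decompose(y, t)


class TestPGLS:
    def setup_method(self):
        self.tree = random_ultrametric_tree(80, random.Random(9))
        self.cov = vcv_from_tree(self.tree)
        rng = np.random.default_rng(9)
        self.X = pd.DataFrame({"x": rng.standard_normal(80)}, index=self.cov.tips)
        self.y = pd.Series(2 * self.X["x"] + 3 + rng.standard_normal(80),
                           index=self.cov.tips)

    def test_lambda_zero_equals_ols(self):
        res = pgls_fit(self.y, self.X, self.tree, lam=0.0)
        ols = ols_fit(self.y.loc[res.meta["species"]].to_numpy(),
                      self.X.loc[res.meta["species"]])
        assert np.allclose(res.coef, ols.coef, atol=1e-10)
        assert np.allclose(res.se, ols.se, atol=1e-10)

    def test_lambda_one_equals_closed_form_gls(self):
        res = pgls_fit(self.y, self.X, self.tree, lam=1.0)
        C = self.cov.reorder(res.meta["species"]).matrix
        Ci = np.linalg.inv(C)
        M = np.column_stack([np.ones(80), self.X.loc[res.meta["species"], "x"]])
        yv = self.y.loc[res.meta["species"]].to_numpy()
        beta = np.linalg.solve(M.T @ Ci @ M, M.T @ Ci @ yv)
        assert np.allclose(res.coef, beta, atol=1e-10)

    def test_exact_linear_relation_recovered_for_any_lambda(self):
        y = pd.Series(2 * self.X["x"] + 3, index=self.X.index)
        for lam in (0.0, 0.3, 1.0):
            res = pgls_fit(y, self.X, self.tree, lam=lam)
            assert res.coef == pytest.approx([3.0, 2.0], abs=1e-8)
            assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_degrees_of_freedom_bookkeeping(self):
        res = pgls_fit(self.y, self.X, self.tree, lam="estimated")
        assert res.df_resid == res.n - 2
        assert 0 <= res.lambda_used <= 1

    def test_rank_deficient_design_rejected(self):
        X = self.X.copy()
        X["x2"] = 2 * X["x"]
        with pytest.raises(ValueError):
            pgls_fit(self.y, X, self.tree, lam=0.5)


class TestGrafting:
    def setup_method(self):
        self.tree = random_ultrametric_tree(
            12, random.Random(4),
            labels=[f"g{i % 4}_sp{i}" for i in range(12)])
        self.taxonomy = {f"g{i % 4}_sp{i}": f"g{i % 4}" for i in range(12)}

    def test_empty_missing_list_is_identity(self):
        out = graft_missing_species(self.tree, self.taxonomy, [], seed=0)
        assert {l.taxon.label for l in out.leaf_node_iter()} == \
               {l.taxon.label for l in self.tree.leaf_node_iter()}

    def test_deterministic_under_seed(self):
        miss = ["g1_new1", "g2_new2", "g3_new3"]
        tax = dict(self.taxonomy, g1_new1="g1", g2_new2="g2", g3_new3="g3")
        a = graft_missing_species(self.tree, tax, miss, seed=5)
        b = graft_missing_species(self.tree, tax, miss, seed=5)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")
        c = graft_missing_species(self.tree, tax, miss, seed=6)
        assert a.as_string(schema="newick") != c.as_string(schema="newick")

    def test_tip_count_and_positive_branches_and_ultrametric(self):
        miss = [f"g0_new{i}" for i in range(5)]
        tax = dict(self.taxonomy, **{m: "g0" for m in miss})
        out = graft_missing_species(self.tree, tax, miss, seed=1)
        assert len(out.leaf_nodes()) == 12 + 5
        assert all((e.length or 1) > 0 for e in out.preorder_edge_iter()
                   if e.head_node.parent_node is not None)
        depths = [lf.distance_from_root() for lf in out.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_graft_then_prune_recovers_covariance(self):
        miss = ["g1_newA", "g2_newB"]
        tax = dict(self.taxonomy, g1_newA="g1", g2_newB="g2")
        grafted = graft_missing_species(self.tree, tax, miss, seed=2)
        pruned = prune_to_species(grafted, [l.taxon.label for l in self.tree.leaf_node_iter()])
        c0 = vcv_from_tree(self.tree)
        c1 = vcv_from_tree(pruned).reorder(c0.tips)
        assert np.allclose(c0.matrix, c1.matrix, atol=1e-10)

    def test_unknown_genus_rejected(self):
        with pytest.raises(ValueError):
            graft_missing_species(self.tree, self.taxonomy, ["zz_new"], seed=0)

    def test_newick_round_trip(self, tmp_path):
        p = tmp_path / "t.nwk"
        write_newick(self.tree, p)
        back = read_newick(p)
        assert np.allclose(vcv_from_tree(back).reorder(vcv_from_tree(self.tree).tips).matrix,
                           vcv_from_tree(self.tree).matrix, atol=1e-9)
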