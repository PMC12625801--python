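"""GLS fitting, profile-ML lambda estimation, and model comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from oracles import gls_direct, loglik_direct, pic_slope

from phylomass import (
    SimulationConfig,
    compare_models,
    fit_model,
    gls_fit,
    profile_lambda_ml,
    simulate_traits,
    simulate_tree,
    vcv_from_tree,
)
from phylomass.tree import lambda_transform, parse_newick


def _random_instance(seed, n=12, p=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    A = rng.normal(size=(n, n))
    V = A @ A.T + n * np.eye(n)
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    return X, y, V


class TestGlsFit:
    def test_noiseless_line_is_ols(self):
        x = np.arange(5.0)
        X = np.column_stack([np.ones(5), x])
        y = 2 * x + 1
        res = gls_fit(X, y, np.eye(5))
        np.testing.assert_allclose(res.beta, [1.0, 2.0], atol=1e-12)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_inverse_oracle(self, seed):
        X, y, V = _random_instance(seed)
        res = gls_fit(X, y, V)
        beta, sigma2, cov_beta = gls_direct(X, y, V)
        np.testing.assert_allclose(res.beta, beta, rtol=1e-8)
        assert res.sigma2 == pytest.approx(sigma2, rel=1e-8)
        np.testing.assert_allclose(res.cov_beta, cov_beta, rtol=1e-7)
        assert res.loglik == pytest.approx(loglik_direct(X, y, V), rel=1e-10)

    def test_four_taxon_case(self):
        X, y, V = _random_instance(99, n=4, p=2)
        beta, _, _ = gls_direct(X, y, V)
        np.testing.assert_allclose(gls_fit(X, y, V).beta, beta, rtol=1e-9)

    def test_duplicated_column_raises_rank_error(self):
        X, y, V = _random_instance(1)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            gls_fit(X2, y, V)

    def test_non_positive_definite_v_raises(self):
        X, y, _ = _random_instance(2)
        with pytest.raises(ValueError, match="positive definite"):
            gls_fit(X, y, -np.eye(len(y)))


class TestProfileLambda:
    def test_star_tree_flat_profile_returns_zero(self):
        star = parse_newick("(A:1,B:1,C:1,D:1,E:1):0;")
        cov = vcv_from_tree(star)
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        y = rng.normal(size=5)
        prof = profile_lambda_ml(X, y, cov)
        assert prof.lambda_hat == 0.0
        assert prof.flat

    @pytest.mark.parametrize("seed", range(20))
    def test_optimizer_ties_grid_search(self, seed):
        tree = simulate_tree(25, seed=seed)
        cfg = SimulationConfig(n_extant=25, lambda_true=0.6, seed=seed)
        traits = simulate_traits(tree, cfg, rng=np.random.default_rng(seed))
        cov = vcv_from_tree(tree, traits["species"])
        X = np.column_stack([np.ones(25), np.log(traits["fcsa_mm2"])])
        y = np.log(traits["bm_kg"] * 1000.0).to_numpy()
        prof = profile_lambda_ml(X, y, cov)
        grid = np.linspace(0, 1, 101)
        lls = [gls_fit(X, y, lambda_transform(cov, g).V).loglik for g in grid]
        lam_grid = grid[int(np.argmax(lls))]
        assert abs(prof.lambda_hat - lam_grid) <= 0.01 + 1e-9
        assert prof.loglik >= max(lls) - 1e-8

    def test_lambda_one_recovery_on_large_tree(self):
        """λ̂ lands in [0.9, 1] in >= 90% of replicates when the truth is 1."""
        tree = simulate_tree(200, seed=42)
        cfg = SimulationConfig(n_extant=200, lambda_true=1.0, seed=0)
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            traits = simulate_traits(tree, cfg, rng=rng)
            fit = fit_model(traits, tree, "BM~FCSA")
            hits += int(0.9 <= fit.lambda_hat <= 1.0)
        assert hits >= 0.9 * n_rep


class TestFitModel:
    def test_lambda_zero_equals_ols(self, extant_tree, extant_traits):
        fit = fit_model(extant_traits, extant_tree, "BM~FCSA", lam=0.0)
        X = np.column_stack(
            [np.ones(len(extant_traits)), np.log(extant_traits["fcsa_mm2"])]
        )
        y = np.log(extant_traits["bm_kg"] * 1000.0)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, atol=1e-8)
        assert fit.adj_r2 == pytest.approx(ols.rsquared_adj, abs=1e-8)
        assert fit.fstat == pytest.approx(ols.fvalue, rel=1e-6)

    def test_lambda_one_slope_equals_contrasts_oracle(self, extant_tree, extant_traits):
        fit = fit_model(extant_traits, extant_tree, "BM~FCSA", lam=1.0)
        x = dict(zip(extant_traits["species"], np.log(extant_traits["fcsa_mm2"])))
        y = dict(
            zip(extant_traits["species"], np.log(extant_traits["bm_kg"] * 1000.0))
        )
        slope = pic_slope(extant_tree.resolve_polytomies(0), x, y)
        assert fit.params.iloc[1] == pytest.approx(slope, abs=1e-6)

    def test_multivariate_and_fl_models_fit(self, extant_tree, extant_traits):
        for formula in ("BM~FL", "BM~FCSA+FL"):
            fit = fit_model(extant_traits, extant_tree, formula)
            assert fit.df_resid == fit.n - len(fit.params)
            assert np.isfinite(fit.aic)
            assert fit.adj_r2 <= 1.0

    def test_species_missing_from_tree_raises(self, extant_tree, extant_traits):
        bad = extant_traits.copy()
        bad.loc[0, "species"] = "not a real taxon"
        with pytest.raises(ValueError, match="not in tree"):
            fit_model(bad, extant_tree)

    def test_unknown_formula_rejected(self, extant_tree, extant_traits):
        with pytest.raises(ValueError, match="unknown formula"):
            fit_model(extant_traits, extant_tree, "BM~HUMERUS")

    def test_nonpositive_trait_rejected(self, extant_tree, extant_traits):
        bad = extant_traits.copy()
        bad.loc[3, "bm_kg"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_model(bad, extant_tree)

    def test_whitening_equals_direct_gls(self, extant_tree, extant_traits):
        fit = fit_model(extant_traits, extant_tree, "BM~FCSA")
        X, y = fit.X, fit.y
        beta, sigma2, cov_beta = gls_direct(X, y, fit.V)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert fit.sigma2 == pytest.approx(sigma2, rel=1e-8)
        np.testing.assert_allclose(fit.cov_beta, cov_beta, rtol=1e-6)

    def test_branch_length_scale_equivariance(self, extant_traits, extant_tree):
        fit1 = fit_model(extant_traits, extant_tree, "BM~FCSA")
        scaled = parse_newick(extant_tree.write_newick())
        for nd in scaled._dtree.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length *= 7.3
        fit2 = fit_model(extant_traits, scaled, "BM~FCSA")
        np.testing.assert_allclose(
            fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-6
        )
        assert fit2.lambda_hat == pytest.approx(fit1.lambda_hat, abs=1e-4)
        assert fit2.sigma2 == pytest.approx(fit1.sigma2 / 7.3, rel=1e-4)

    def test_loglik_at_mle_beats_endpoints(self, extant_tree, extant_traits):
        free = fit_model(extant_traits, extant_tree, "BM~FCSA")
        for lam in (0.0, 1.0):
            pinned = fit_model(extant_traits, extant_tree, "BM~FCSA", lam=lam)
            assert free.loglik >= pinned.loglik - 1e-6


class TestCompareModels:
    def test_ranking_reproduces_published_order(self, extant_tree, extant_traits):
        """AICs like {18, 56, 20} for the three candidates rank 1, 3, 2."""
        fits = [
            fit_model(extant_traits, extant_tree, f)
            for f in ("BM~FCSA", "BM~FL", "BM~FCSA+FL")
        ]
        fits[0].aic, fits[1].aic, fits[2].aic = 18.0, 56.0, 20.0
        ranking = compare_models(fits)
        assert ranking.order == [0, 2, 1]
        assert ranking.best == 0
        assert ranking.delta_aic == [0.0, 38.0, 2.0]

    def test_exact_tie_prefers_fewer_parameters(self, extant_tree, extant_traits):
        f1 = fit_model(extant_traits, extant_tree, "BM~FCSA")
        f3 = fit_model(extant_traits, extant_tree, "BM~FCSA+FL")
        f1.aic = f3.aic = 10.0
        ranking = compare_models([f3, f1])
        assert ranking.best == 1

    def test_single_fit(self, extant_tree, extant_traits):
        f = fit_model(extant_traits, extant_tree, "BM~FCSA")
        ranking = compare_models([f])
        assert ranking.order == [0]

    def test_mismatched_taxa_rejected(self, extant_tree, extant_traits):
        f1 = fit_model(extant_traits, extant_tree, "BM~FCSA")
        f2 = fit_model(
            extant_traits.iloc[:40], extant_tree, "BM~FCSA"
        )
        with pytest.raises(ValueError, match="taxon"):
            compare_models([f1, f2])


def test_aic_uses_declared_parameter_count(extant_tree, extant_traits):
    fit = fit_model(extant_traits, extant_tree, "BM~FCSA")
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
    assert fit.k == len(fit.params) + 2
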