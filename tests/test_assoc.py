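"""Blockwise-inverse kernel and GLM/MLM/FarmCPU scans against naive oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gwaskit.assoc import (
    block_inverse, farmcpu_scan, genomic_inflation, glm_scan, mlm_scan,
)
from gwaskit.popstruct import EigenDecomposition, compute_grm, compute_pcs, eigen_grm
from gwaskit.simulate import SimConfig, simulate_genotypes, simulate_phenotype
from gwaskit.varcomp import VarianceComponents, reml_brent


class TestBlockInverse:
    def test_orthogonal_marker_collapses(self):
        rng = np.random.default_rng(0)
        W = np.column_stack([np.ones(20), rng.standard_normal(20)])
        x = rng.standard_normal(20)
        x -= W @ np.linalg.lstsq(W, x, rcond=None)[0]  # force w'x = 0
        wtw_inv = np.linalg.inv(W.T @ W)
        bi = block_inverse(wtw_inv, W.T @ x, float(x @ x))
        np.testing.assert_allclose(bi.M11, wtw_inv, atol=1e-12)
        np.testing.assert_allclose(bi.M12, 0, atol=1e-12)
        assert abs(bi.M22 - 1 / (x @ x)) < 1e-12

    def test_collinear_marker_degenerate(self):
        rng = np.random.default_rng(1)
        W = np.column_stack([np.ones(10), rng.standard_normal(10)])
        x = W[:, 1].copy()
        bi = block_inverse(np.linalg.inv(W.T @ W), W.T @ x, float(x @ x))
        assert bi.degenerate

    @pytest.mark.parametrize("k", [0, 1, 3, 5, 10])
    def test_matches_direct_inverse(self, k):
        """Assembled blocks equal the direct inverse of the full (k+2)x(k+2)
        cross-product, across the covariate sweep."""
        rng = np.random.default_rng(100 + k)
        n = 50
        for _ in range(50):
            W = np.column_stack([np.ones(n), rng.standard_normal((n, k))])
            x = rng.standard_normal(n)
            X = np.column_stack([W, x])
            direct = np.linalg.inv(X.T @ X)
            bi = block_inverse(np.linalg.inv(W.T @ W), W.T @ x, float(x @ x))
            kk = W.shape[1]
            np.testing.assert_allclose(bi.M11, direct[:kk, :kk], atol=1e-8)
            np.testing.assert_allclose(bi.M12, direct[:kk, kk], atol=1e-8)
            np.testing.assert_allclose(bi.M21, direct[kk, :kk], atol=1e-8)
            assert abs(bi.M22 - direct[kk, kk]) < 1e-8

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 6))
    def test_m12_is_m21_transpose(self, seed, k):
        rng = np.random.default_rng(seed)
        n = 30
        W = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))]) \
            if k > 1 else np.ones((n, 1))
        x = rng.standard_normal(n)
        bi = block_inverse(np.linalg.inv(W.T @ W), W.T @ x, float(x @ x))
        np.testing.assert_allclose(bi.M12, bi.M21)


class TestGLM:
    def test_exact_fit_reports_tiny_p(self):
        x = np.array([0.0, 1, 2, 1, 0, 2, 1, 1])
        y = 2 * x + 5
        res = glm_scan(y, x[None, :])
        assert abs(res.loc[0, "EFFECT"] - 2) < 1e-10
        assert 0 < res.loc[0, "PVALUE"] <= np.finfo(float).tiny

    def test_monomorphic_marker_missing(self):
        rng = np.random.default_rng(2)
        X = np.vstack([np.full(30, 2.0), rng.binomial(2, 0.4, 30)]).astype(float)
        res = glm_scan(rng.standard_normal(30), X)
        assert np.isnan(res.loc[0, "PVALUE"])
        assert np.isfinite(res.loc[1, "PVALUE"])

    def test_matches_naive_ols(self, oracles, tmp_path):
        """Every marker's effect/SE/p equals an independent full OLS refit."""
        cfg = SimConfig(n_samples=150, n_markers=400, seed=61, n_qtn=5, h2=0.4)
        store = simulate_genotypes(cfg, tmp_path / "store")
        pheno, _ = simulate_phenotype(store, cfg)
        y = pheno["trait1"].to_numpy()
        eig = eigen_grm(compute_grm(store))
        pcs = compute_pcs(eig, 3)
        res = glm_scan(y, store, pcs)
        W = np.column_stack([np.ones(cfg.n_samples), pcs])
        X = store.dosage_block(0, store.n_markers)
        X = np.where(np.isnan(X), np.nanmean(X, axis=1, keepdims=True), X)
        for i in range(0, cfg.n_markers, 17):
            if np.isnan(res.loc[i, "PVALUE"]):
                continue
            b, se, p = oracles["ols"](y, W, X[i])
            assert abs(res.loc[i, "EFFECT"] - b) <= 1e-10 * max(abs(b), 1e-12)
            assert abs(res.loc[i, "SE"] - se) <= 1e-10 * se
            assert abs(res.loc[i, "PVALUE"] - p) <= 1e-10 * max(p, 1e-12)

    def test_missing_dosages_mean_imputed(self, oracles):
        rng = np.random.default_rng(3)
        n = 40
        x = rng.binomial(2, 0.4, n).astype(float)
        x_missing = x.copy()
        x_missing[[3, 7]] = np.nan
        y = 0.5 * np.nan_to_num(x) + rng.standard_normal(n)
        res = glm_scan(y, x_missing[None, :])
        imputed = x_missing.copy()
        imputed[np.isnan(imputed)] = np.nanmean(x_missing)
        b, se, p = oracles["ols"](y, np.ones((n, 1)), imputed)
        assert abs(res.loc[0, "EFFECT"] - b) < 1e-10

    def test_worker_count_invariance(self, small_store):
        """Bitwise-identical result tables for 1 vs 4 workers."""
        store, pheno, *_ = small_store
        y = pheno["trait1"].to_numpy()
        r1 = glm_scan(y, store, block_size=64, n_workers=1)
        r4 = glm_scan(y, store, block_size=64, n_workers=4)
        pd.testing.assert_frame_equal(r1, r4)


class TestMLM:
    def test_h2_zero_reduces_to_glm(self, small_store):
        store, pheno, *_ = small_store
        y = pheno["trait1"].to_numpy()
        eig = eigen_grm(compute_grm(store))
        vc = VarianceComponents(0.0, 1.0, 0.0, "fixed")
        glm = glm_scan(y, store)
        mlm = mlm_scan(y, store, None, eig, vc)
        np.testing.assert_allclose(mlm["PVALUE"], glm["PVALUE"], atol=1e-10)

    def test_matches_dense_gls(self, oracles, tmp_path):
        """n=40 toy: effect/SE/p match the explicit V-inverse GLS oracle."""
        cfg = SimConfig(n_samples=40, n_markers=120, seed=71, n_qtn=3, h2=0.6,
                        min_qtn_spacing=0)
        store = simulate_genotypes(cfg, tmp_path / "store")
        pheno, _ = simulate_phenotype(store, cfg)
        y = pheno["trait1"].to_numpy()
        grm = compute_grm(store)
        eig = eigen_grm(grm)
        vc = reml_brent(y, np.ones((40, 1)), eig)
        res = mlm_scan(y, store, None, eig, vc)
        V = vc.h2 * grm.matrix + (1 - vc.h2) * np.eye(40)
        X = store.dosage_block(0, store.n_markers)
        W = np.ones((40, 1))
        for i in range(0, 120, 7):
            if np.isnan(res.loc[i, "PVALUE"]):
                continue
            b, se, p = oracles["gls"](y, W, X[i], V)
            assert abs(res.loc[i, "EFFECT"] - b) < 1e-8
            assert abs(res.loc[i, "SE"] - se) < 1e-8
            assert abs(res.loc[i, "PVALUE"] - p) < 1e-8

    def test_controls_family_inflation(self, tmp_path):
        """Sib-family polygenic null: MLM calibrated, covariate-free GLM inflated."""
        lam_glm, lam_mlm = [], []
        for rep in range(3):
            cfg = SimConfig(n_samples=400, n_markers=3000, seed=80 + rep,
                            family_size=5, h2=0.7)
            store = simulate_genotypes(cfg, tmp_path / f"store{rep}")
            pheno, _ = simulate_phenotype(store, cfg, polygenic=True)
            y = pheno["trait1"].to_numpy()
            eig = eigen_grm(compute_grm(store))
            vc = reml_brent(y, np.ones((cfg.n_samples, 1)), eig)
            lam_glm.append(genomic_inflation(glm_scan(y, store)["PVALUE"]))
            lam_mlm.append(genomic_inflation(
                mlm_scan(y, store, None, eig, vc)["PVALUE"]))
        assert np.median(lam_glm) > 1.2
        assert 0.9 < np.median(lam_mlm) < 1.1


class TestFarmCPU:
    def test_null_reduces_to_glm(self, small_store):
        """With nothing passing the entry threshold, FarmCPU is one GLM pass."""
        store, *_ = small_store
        rng = np.random.default_rng(5)
        y = rng.standard_normal(store.n_samples)
        glm = glm_scan(y, store)
        fcpu, info = farmcpu_scan(y, store)
        assert info["pseudo_qtns"] == []
        assert info["n_iterations"] == 1
        np.testing.assert_allclose(fcpu["PVALUE"], glm["PVALUE"], atol=1e-12)

    def test_terminates_on_stable_qtn_set(self, small_store):
        store, pheno, truth, cfg = small_store
        y = pheno["trait1"].to_numpy()
        res, info = farmcpu_scan(y, store, max_loop=10)
        assert 1 <= info["n_iterations"] <= 10

    def test_max_loop_validation(self, small_store):
        store, pheno, *_ = small_store
        with pytest.raises(ValueError, match="max_loop"):
            farmcpu_scan(pheno["trait1"].to_numpy(), store, max_loop=0)

    def test_finds_true_qtns(self, tmp_path):
        """Strong QTNs in a structured cohort are promoted to pseudo-QTNs and
        end up more significant than under plain GLM."""
        cfg = SimConfig(n_samples=500, n_markers=3000, seed=91, n_subpop=2,
                        fst=0.08, n_qtn=5, h2=0.4, effect_dist="equal")
        store = simulate_genotypes(cfg, tmp_path / "store")
        pheno, truth = simulate_phenotype(store, cfg)
        y = pheno["trait1"].to_numpy()
        res, info = farmcpu_scan(y, store)
        glm = glm_scan(y, store)
        qtn_idx = truth["qtn_index"]
        hits = sum(1 for q in qtn_idx if q in info["pseudo_qtns"])
        assert hits >= 3
        fc_p = res.loc[qtn_idx, "PVALUE"].to_numpy()
        glm_p = glm.loc[qtn_idx, "PVALUE"].to_numpy()
        assert np.median(np.log10(fc_p) - np.log10(glm_p)) < 0


class TestGenomicInflation:
    def test_uniform_null_near_one(self):
        rng = np.random.default_rng(7)
        lam = genomic_inflation(rng.uniform(size=10_000))
        assert 0.95 < lam < 1.05

    def test_constant_half_gives_one(self):
        assert abs(genomic_inflation(np.full(200, 0.5)) - 1) < 1e-12

    def test_monotone_in_significance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=1000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_too_few_pvalues(self):
        with pytest.raises(ValueError, match="100"):
            genomic_inflation(np.full(50, 0.5))


def test_glm_type1_error_calibrated(tmp_path):
    """Unstructured null: empirical type-I error at alpha=0.01 is nominal."""
    cfg = SimConfig(n_samples=500, n_markers=5000, seed=101)
    store = simulate_genotypes(cfg, tmp_path / "store")
    rng = np.random.default_rng(55)
    y = rng.standard_normal(cfg.n_samples)
    res = glm_scan(y, store)
    p = res["PVALUE"].dropna()
    rate = float((p < 0.01).mean())
    assert 0.005 < rate < 0.02
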