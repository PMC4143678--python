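"""Measured-genotype association: oracle equivalence, limits, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal

from egvkit.association import AssocModelSpec, FamilyCovariance, genome_scan, mga_test
from egvkit.egv import egv_error_variance
from egvkit.genotypes import GenotypeMatrix
from egvkit.pedigree import expected_relatedness
from egvkit.polygenic import fit_polygenic


def dense_ml_loglik(y, X, R, h2_grid=None):
    """Independent dense-likelihood oracle: optimize h2 by direct MVN density."""
    n = len(y)

    def nll(h2):
        # profile sigma_p2 and beta out by GLS at fixed h2
        V = h2 * R + (1 - h2) * np.eye(n)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        sp2 = float(r @ Vi @ r) / n
        return -multivariate_normal.logpdf(y, mean=X @ beta, cov=sp2 * V)

    res = minimize_scalar(nll, bounds=(1e-9, 1 - 1e-9), method="bounded",
                          options={"xatol": 1e-10})
    return -min(res.fun, nll(1e-12))


class TestMgaTest:
    def test_monomorphic_snp_skipped(self, small_study, small_eig):
        n = small_eig.n
        spec = AssocModelSpec(phi2=small_eig)
        rng = np.random.default_rng(0)
        res = mga_test(rng.standard_normal(n), np.ones(n), np.ones((n, 1)), spec)
        assert res.status == "skipped_monomorphic"

    def test_strong_effect_regression_limit(self, small_study, small_eig):
        """Trait built as 5 x dosage + tiny noise: effect and LRT recovered."""
        sd = small_study
        n = small_eig.n
        rng = np.random.default_rng(1)
        maf = sd.G.maf()
        k = int(np.argmax(maf))
        g = sd.G.dosages[:, k]
        y = 5.0 * g + 1e-3 * rng.standard_normal(n)
        spec = AssocModelSpec(phi2=small_eig)
        res = mga_test(y, g, np.ones((n, 1)), spec)
        assert res.beta_snp == pytest.approx(5.0, abs=1e-3)
        assert res.lrt > 30

    def test_lrt_matches_dense_oracle(self, small_study, small_eig):
        """Spectral-path LRT equals a dense-likelihood LRT to 1e-6."""
        sd = small_study
        n = small_eig.n
        rng = np.random.default_rng(2)
        R = (small_eig.U * small_eig.d) @ small_eig.U.T
        g_poly = small_eig.U @ (np.sqrt(small_eig.d * 0.5) * rng.standard_normal(n))
        y = g_poly + np.sqrt(0.5) * rng.standard_normal(n)
        maf = sd.G.maf()
        snp = sd.G.dosages[:, int(np.argsort(maf)[-2])]  # common, polymorphic
        X = np.ones((n, 1))
        spec = AssocModelSpec(phi2=small_eig)
        res = mga_test(y, snp, X, spec)
        snp_c = snp.copy()
        ll0 = dense_ml_loglik(y, X, R)
        ll1 = dense_ml_loglik(y, np.column_stack([X, snp_c]), R)
        lrt_oracle = max(0.0, 2 * (ll1 - ll0))
        assert res.lrt == pytest.approx(lrt_oracle, abs=1e-6)

    def test_null_loglik_equals_polygenic_fit(self, small_study, small_eig):
        """With eps = 0 the association null reduces to the polygenic model."""
        n = small_eig.n
        rng = np.random.default_rng(3)
        g_poly = small_eig.U @ (np.sqrt(small_eig.d * 0.4) * rng.standard_normal(n))
        y = 2.0 + g_poly + np.sqrt(0.6) * rng.standard_normal(n)
        X = np.ones((n, 1))
        cov = FamilyCovariance(AssocModelSpec(phi2=small_eig))
        ll, _, sp2, h2, eps = cov.fit(cov.rotate(y), cov.rotate(X))
        fit = fit_polygenic(y, X, small_eig)
        assert eps == 0.0
        assert ll == pytest.approx(fit.loglik, abs=1e-6)
        assert h2 == pytest.approx(fit.h2, abs=1e-4)

    def test_with_E_likelihood_not_worse(self, small_study, small_eig):
        """Adding the EGV error-variance component can only help the fit."""
        n = small_eig.n
        rng = np.random.default_rng(4)
        E = egv_error_variance(small_eig, 1.0, 1.0)
        y = rng.standard_normal(n) + small_eig.U @ (
            np.sqrt(small_eig.d * 0.3) * rng.standard_normal(n)
        )
        X = np.ones((n, 1))
        base = FamilyCovariance(AssocModelSpec(phi2=small_eig))
        with_e = FamilyCovariance(AssocModelSpec(phi2=small_eig, E=E, include_E=True))
        assert with_e.e_diag is not None  # commuting case -> diagonal fast path
        ll0 = base.fit(base.rotate(y), base.rotate(X))[0]
        ll1 = with_e.fit(with_e.rotate(y), with_e.rotate(X))[0]
        assert ll1 >= ll0 - 1e-6

    def test_dense_path_matches_diag_path(self, small_study, small_eig):
        """Forcing the dense covariance path reproduces the diagonal result."""
        n = small_eig.n
        rng = np.random.default_rng(5)
        E = egv_error_variance(small_eig, 1.0, 0.8)
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        diag = FamilyCovariance(AssocModelSpec(phi2=small_eig, E=E, include_E=True))
        dense = FamilyCovariance(AssocModelSpec(phi2=small_eig, E=E, include_E=True))
        dense.E_rot = np.diag(dense.e_diag)
        dense.e_diag = None
        nll_a = diag._negloglik(0.3, 0.2, diag.rotate(y), diag.rotate(X))[0]
        nll_b = dense._negloglik(0.3, 0.2, dense.rotate(y), dense.rotate(X))[0]
        assert nll_a == pytest.approx(nll_b, abs=1e-8)


class TestGenomeScan:
    def test_planted_signal_is_minimum_p(self, small_study, small_eig):
        sd = small_study
        n = small_eig.n
        rng = np.random.default_rng(6)
        maf = sd.G.maf()
        k = int(np.argmax(maf))
        g = sd.G.dosages[:, k]
        beta = np.sqrt(0.05 / g.var())  # 5% of unit trait variance
        y = beta * g * 4.0 + rng.standard_normal(n)
        sub = sd.G.subset_snps(np.arange(0, 120))
        if k >= 120:
            sub = sd.G.subset_snps(np.r_[np.arange(0, 119), k])
        spec = AssocModelSpec(phi2=small_eig)
        tab = genome_scan(y, sub, np.ones((n, 1)), spec)
        ok = tab[tab["status"] == "ok"]
        target = sd.G.snps.iloc[k]["snp"]
        best = ok.loc[ok["p"].idxmin(), "snp"]
        # the planted SNP (or a SNP in strong LD with it) wins
        from egvkit.evaluation import pairwise_r2
        bk = list(sub.snps["snp"].astype(str)).index(best)
        assert best == target or pairwise_r2(sub.dosages[:, bk], g) > 0.5

    def test_pure_noise_no_genomewide_hits(self, small_study, small_eig):
        rng = np.random.default_rng(7)
        n = small_eig.n
        sub = small_study.G.subset_snps(np.arange(100))
        spec = AssocModelSpec(phi2=small_eig)
        tab = genome_scan(rng.standard_normal(n), sub, np.ones((n, 1)), spec)
        assert int(tab["significant"].sum()) == 0

    def test_scan_equals_per_snp_tests_any_order(self, small_study, small_eig):
        """Scan rows match standalone per-SNP tests processed in reverse order."""
        rng = np.random.default_rng(8)
        n = small_eig.n
        y = rng.standard_normal(n)
        sub = small_study.G.subset_snps(np.arange(30))
        spec = AssocModelSpec(phi2=small_eig)
        tab = genome_scan(y, sub, np.ones((n, 1)), spec).set_index("snp")
        for k in reversed(range(sub.n_snps)):
            name = str(sub.snps.iloc[k]["snp"])
            res = mga_test(y, sub.dosages[:, k], np.ones((n, 1)), spec)
            if res.status == "ok":
                assert tab.loc[name, "lrt"] == pytest.approx(res.lrt, abs=1e-6)
            else:
                assert tab.loc[name, "status"] == res.status

    def test_type_one_error_calibrated_small(self, small_study, small_eig):
        """Null SNPs on a polygenic trait: empirical alpha near 0.05."""
        sd = small_study
        n = small_eig.n
        rng = np.random.default_rng(9)
        g_poly = small_eig.U @ (np.sqrt(small_eig.d * 0.4) * rng.standard_normal(n))
        y = g_poly + np.sqrt(0.6) * rng.standard_normal(n)
        # null SNPs: chromosome 2 while the trait is genotype-free
        sub = sd.G.subset_snps((sd.G.snps["chrom"] == "2").to_numpy())
        spec = AssocModelSpec(phi2=small_eig)
        tab = genome_scan(y, sub, np.ones((n, 1)), spec)
        ok = tab[tab["status"] == "ok"]
        alpha = float((ok["p"] < 0.05).mean())
        assert 0.01 < alpha < 0.12  # generous at this scale; tight check elsewhere
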