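import numpy as np
import pytest

from probgwas import design, mixed, simulate
from probgwas.fixed_effects import fit_linear, score_test_linear
from probgwas.mixed import (
    KinshipMatrix,
    fit_polygenic,
    genomic_kinship,
    mmscore_pipeline,
    mmscore_scan,
    mmscore_test,
    pedigree_kinship,
)

import oracles


def _trio_pedigree():
    # founders 0,1; children 2,3 (full sibs); 4 = child of 2 and founder 5...
    # keep it simple: gp couple, two sibs, one grandchild via sib 2 x founder 4
    ids = ["gpf", "gpm", "s1", "s2", "sp", "gc"]
    father = np.array([-1, -1, 0, 0, -1, 2])
    mother = np.array([-1, -1, 1, 1, -1, 4])
    gen = np.array([0, 0, 1, 1, 1, 2])
    return simulate.Pedigree(ids, father, mother, gen)


class TestPedigreeKinship:
    def test_textbook_coefficients(self):
        kin = pedigree_kinship(_trio_pedigree())
        phi = kin.phi
        i = {s: j for j, s in enumerate(kin.ids)}
        # phi = 2 x kinship: full sibs 2*(1/4), grandchild-grandparent 2*(1/8)
        assert phi[i["s1"], i["s2"]] == pytest.approx(0.5)
        assert phi[i["gc"], i["gpf"]] == pytest.approx(0.25)
        assert phi[i["gc"], i["s2"]] == pytest.approx(0.25)  # avuncular
        # founder self-relationship = 2 * 1/2
        assert phi[i["gpf"], i["gpf"]] == pytest.approx(1.0)
        # parent-offspring
        assert phi[i["s1"], i["gpf"]] == pytest.approx(0.5)

    def test_out_of_order_pedigree_rejected(self):
        class Bad:
            ids = ["a", "b"]
            father = np.array([1, -1])
            mother = np.array([-1, -1])

        with pytest.raises(ValueError, match="topologically"):
            pedigree_kinship(Bad())


class TestGenomicKinship:
    def test_unrelated_pairs_near_zero(self, rng):
        n, L = 40, 10_000
        G = rng.binomial(2, 0.5, (n, L)) / 2.0
        # at the true frequencies the estimator is unbiased; estimating the
        # frequencies from the sample itself adds the usual -1/n centering bias
        phi = genomic_kinship(G, freqs=np.full(L, 0.5)).phi
        off = phi[np.triu_indices(n, 1)]
        assert abs(off.mean()) < 0.01
        assert np.abs(off).max() < 0.1

    def test_duplicated_individual_matches_self(self, rng):
        G = rng.binomial(2, 0.3, (10, 5000)) / 2.0
        G = np.vstack([G, G[:1]])  # sample 10 duplicates sample 0
        phi = genomic_kinship(G).phi
        assert phi[0, 10] == pytest.approx(phi[0, 0], abs=0.05)

    def test_monomorphic_only_is_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            genomic_kinship(np.ones((5, 10)))

    def test_gene_dropped_sibs_recover_expected_kinship(self, family_data):
        ped, freqs, G = family_data
        est = genomic_kinship(G, freqs=freqs).phi
        expected = pedigree_kinship(ped).phi
        sib = (expected == 0.5) & ~np.eye(ped.n, dtype=bool)
        # with L=2500 loci the class mean is within a few hundredths
        assert est[sib].mean() == pytest.approx(0.5, abs=0.03)
        assert np.linalg.eigvalsh(est).min() > -1e-8

    def test_psd_estimator(self, rng):
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 300), (20, 300)) / 2.0
        assert np.linalg.eigvalsh(genomic_kinship(G).phi).min() > -1e-8


class TestPolygenicFit:
    def test_identity_phi_collapses_to_ols(self, rng):
        n = 120
        X = design.nuisance_design(rng.standard_normal((n, 1)))
        Y = X @ [1.0, 0.5] + rng.standard_normal(n)
        pf = fit_polygenic(Y, X, KinshipMatrix([str(i) for i in range(n)], np.eye(n)))
        assert pf.flagged  # h2 unidentifiable: flat likelihood
        np.testing.assert_allclose(
            pf.beta_x_hat, oracles.ols_normal_equations(Y, X), atol=1e-4
        )

    def test_recovers_heritability_in_families(self):
        ped = simulate.simulate_pedigree(80, seed=7)
        freqs = simulate.draw_founder_freqs(5200, seed=8)
        G = simulate.gene_drop(ped, freqs, seed=9)
        pheno, _, _ = simulate.simulate_trait(ped, G, seed=10,
                                              causal_idx=np.arange(200))
        pf = fit_polygenic(
            pheno.outcome, design.nuisance_design(pheno.covariates),
            pedigree_kinship(ped),
        )
        assert pf.h2_hat == pytest.approx(0.30, abs=0.08)
        assert not pf.flagged

    def test_optimum_beats_h2_zero(self, rng):
        ped = simulate.simulate_pedigree(30, seed=20)
        G = simulate.gene_drop(ped, simulate.draw_founder_freqs(1000, seed=21),
                               seed=22)
        pheno, _, _ = simulate.simulate_trait(ped, G, seed=23)
        X = design.nuisance_design(pheno.covariates)
        phi = pedigree_kinship(ped)
        pf = fit_polygenic(pheno.outcome, X, phi)
        ols = fit_linear(pheno.outcome, X)
        n = len(pheno.outcome)
        ll0 = -0.5 * (n * np.log(2 * np.pi)
                      + n * np.log((ols.residuals @ ols.residuals) / n) + n)
        assert pf.loglik >= ll0 - 1e-8

    def test_omega_inv_consistent_with_parameters(self, family_data):
        ped, freqs, G = family_data
        pheno, _, _ = simulate.simulate_trait(ped, G, seed=33)
        phi = pedigree_kinship(ped)
        pf = fit_polygenic(pheno.outcome, design.nuisance_design(pheno.covariates), phi)
        omega = pf.sigma2_hat * ((1 - pf.h2_hat) * np.eye(ped.n)
                                 + pf.h2_hat * phi.phi)
        np.testing.assert_allclose(pf.omega_inv @ omega, np.eye(ped.n), atol=1e-6)


class TestMmscore:
    def test_identity_omega_reduces_to_ols_on_residuals(self, rng):
        n = 100
        g = rng.uniform(0, 2, n)
        g = g - g.mean()
        r = rng.standard_normal(n)
        r = r - r.mean()
        res = mmscore_test(r, np.eye(n), g)
        beta_ols = float(g @ r / (g @ g))
        assert res.beta_g[0] == pytest.approx(beta_ols, abs=1e-12)

    def test_small_instance_matches_dense_gls_oracle(self, rng):
        n = 8
        a = rng.standard_normal((n, n))
        omega_inv = a @ a.T + n * np.eye(n)
        Xg = rng.uniform(0, 2, (n, 2))
        r = rng.standard_normal(n)
        res = mmscore_test(r, omega_inv, Xg)
        beta_oracle = oracles.gls_dense(r, Xg, omega_inv)
        np.testing.assert_allclose(res.beta_g, beta_oracle, atol=1e-10)
        v = Xg.T @ omega_inv @ Xg
        assert res.score_chi2 == pytest.approx(
            float(beta_oracle @ v @ beta_oracle), abs=1e-10
        )

    def test_zero_column_gives_na(self, rng):
        res = mmscore_test(rng.standard_normal(10), np.eye(10), np.zeros(10))
        assert np.isnan(res.score_chi2)

    def test_reduces_to_fixed_effects_score_test(self, rng):
        """With Omega = sigma2_0 I the mmscore scan equals the linear score
        test statistic."""
        n = 150
        g = rng.binomial(2, 0.3, (n, 5)).astype(float)
        Y = rng.standard_normal(n)
        Xx = np.ones((n, 1))
        null = fit_linear(Y, Xx)
        sigma2_0 = float(null.residuals @ null.residuals) / n
        scan = mmscore_scan(null.residuals, np.eye(n) / sigma2_0, g, X_x=Xx)
        for j in range(5):
            want, _ = score_test_linear(Y, g[:, j], Xx)
            assert scan.chi2[j] == pytest.approx(want, abs=1e-8)

    def test_internal_and_external_step1_agree(self, family_data):
        ped, freqs, G = family_data
        pheno, _, ci = simulate.simulate_trait(ped, G, seed=55)
        phi = pedigree_kinship(ped)
        dose = 2.0 * G[:, :50]
        scan_int, pfit = mmscore_pipeline(
            pheno.outcome, pheno.covariates, dose, phi=phi
        )
        scan_ext, _ = mmscore_pipeline(
            pfit.residuals, pheno.covariates, dose, omega_inv=pfit.omega_inv
        )
        # same fit handed over externally: identical per-SNP statistics
        np.testing.assert_allclose(scan_ext.chi2, scan_int.chi2, atol=1e-10)

    def test_scan_matches_per_snp_projection(self, family_data):
        ped, freqs, G = family_data
        pheno, _, _ = simulate.simulate_trait(ped, G, seed=56)
        phi = pedigree_kinship(ped)
        X = design.nuisance_design(pheno.covariates)
        pf = fit_polygenic(pheno.outcome, X, phi)
        dose = 2.0 * G[:, 100:110]
        scan = mmscore_scan(pf.residuals, pf.omega_inv, dose, X_x=X)
        W = pf.omega_inv
        for j in range(10):
            g = dose[:, j]
            gc = g - X @ np.linalg.solve(X.T @ W @ X, X.T @ W @ g)
            res = mmscore_test(pf.residuals, W, gc)
            assert scan.chi2[j] == pytest.approx(res.score_chi2, abs=1e-8)
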