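"""Kinship, PCA covariates, mixed-model GWAS, ancestral-haplotype HMM and
the weighted haplotype LRT."""

import numpy as np
import pandas as pd
import pytest

from lethalmap import assoc, simpop
from tests.conftest import tiny_population_config


def _pedigree(rows):
    return simpop.Pedigree(pd.DataFrame(
        rows, columns=["animal_id", "sire_id", "dam_id", "sex", "breed",
                       "generation"]))


class TestKinship:
    def test_unrelated_founders_give_identity(self):
        ped = _pedigree([(i, 0, 0, "M" if i % 2 else "F", "X", 0)
                         for i in range(1, 6)])
        kin = assoc.kinship_matrix(ped)
        assert np.allclose(kin.values, np.eye(5))

    def test_parent_offspring_relationship_is_half(self):
        ped = _pedigree([(1, 0, 0, "M", "X", 0), (2, 0, 0, "F", "X", 0),
                         (3, 1, 2, "M", "X", 1)])
        kin = assoc.kinship_matrix(ped)
        idx = {a: i for i, a in enumerate(kin.subject_ids)}
        assert kin.values[idx[1], idx[3]] == pytest.approx(0.5)
        assert kin.values[idx[3], idx[3]] == pytest.approx(1.0)

    def test_offspring_of_full_sibs_is_inbred(self):
        # full sibs share a_ij = 0.5; their offspring has F = 0.25,
        # diagonal 1.25 (path-counting oracle)
        ped = _pedigree([(1, 0, 0, "M", "X", 0), (2, 0, 0, "F", "X", 0),
                         (3, 1, 2, "M", "X", 1), (4, 1, 2, "F", "X", 1),
                         (5, 3, 4, "M", "X", 2)])
        kin = assoc.kinship_matrix(ped)
        idx = {a: i for i, a in enumerate(kin.subject_ids)}
        assert kin.values[idx[3], idx[4]] == pytest.approx(0.5)
        assert kin.values[idx[5], idx[5]] == pytest.approx(1.25)

    def test_subject_absent_rejected(self):
        ped = _pedigree([(1, 0, 0, "M", "X", 0)])
        with pytest.raises(ValueError, match="absent"):
            assoc.kinship_matrix(ped, subjects=[42])


class TestPca:
    def test_pc1_separates_two_populations(self, rng):
        n, m = 120, 400
        f1 = rng.uniform(0.1, 0.9, m)
        # strong drift in population 2
        f2 = np.clip(f1 + rng.normal(0, 0.25, m), 0.02, 0.98)
        g = np.vstack([rng.binomial(2, f1, (n // 2, m)),
                       rng.binomial(2, f2, (n // 2, m))]).astype(float)
        pcs = assoc.pca_covariates(g, k=4)
        labels = np.repeat([0, 1], n // 2)
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_homogeneous_population_has_no_dominant_pc(self, rng):
        n, m = 100, 500
        f = rng.uniform(0.2, 0.8, m)
        g = rng.binomial(2, f, (n, m)).astype(float)
        pcs = assoc.pca_covariates(g, k=4)
        share = pcs[:, 0].var() / g.shape[1]
        # no PC explains much more than the null expectation ~1/n
        assert pcs[:, 0].var() / (pcs ** 2).sum() < 0.5
        assert abs(np.corrcoef(pcs[:, 0], np.arange(n))[0, 1]) < 0.5

    def test_k_zero_gives_empty_covariates(self, rng):
        g = rng.binomial(2, 0.5, (10, 20)).astype(float)
        assert assoc.pca_covariates(g, k=0).shape == (10, 0)


@pytest.fixture(scope="module")
def bull_kinship():
    cfg = tiny_population_config(p=0.0, n_offspring=600, n_founder_m=80,
                                 n_founder_f=320, n_markers_50k=12)
    cohort = simpop.simulate_population(cfg, seed=3)
    ped = cohort.pedigree.table
    bulls = ped[ped["sex"] == "M"]["animal_id"].to_numpy()
    return assoc.kinship_matrix(cohort.pedigree, subjects=bulls)


class TestSnpMixedGwas:
    def test_type_one_error_is_calibrated(self, bull_kinship, rng):
        n = len(bull_kinship.subject_ids)
        L = np.linalg.cholesky(bull_kinship.values + 1e-8 * np.eye(n))
        h2 = 0.3
        pvals = []
        for _ in range(25):
            y = (L @ rng.normal(size=n)) * np.sqrt(h2) \
                + rng.normal(size=n) * np.sqrt(1 - h2)
            maf = rng.uniform(0.1, 0.5, 120)
            g = rng.binomial(2, maf, (n, 120)).astype(float)
            pvals.append(assoc.snp_mixed_gwas(y, g, None, bull_kinship)["p"])
        pv = np.concatenate([p.to_numpy() for p in pvals])
        rate = np.nanmean(pv < 0.05)
        assert 0.03 < rate < 0.07

    def test_planted_variant_detected(self, bull_kinship, rng):
        n = len(bull_kinship.subject_ids)
        L = np.linalg.cholesky(bull_kinship.values + 1e-8 * np.eye(n))
        detected = 0
        for _ in range(5):
            maf = rng.uniform(0.2, 0.5, 30)
            g = rng.binomial(2, maf, (n, 30)).astype(float)
            b = np.sqrt(0.08 / (2 * maf[0] * (1 - maf[0])))
            y = (L @ rng.normal(size=n)) * np.sqrt(0.3) \
                + rng.normal(size=n) * np.sqrt(0.7) + g[:, 0] * b
            res = assoc.snp_mixed_gwas(y, g, None, bull_kinship)
            detected += res["p"].iloc[0] < 1e-6
            assert res["p"].iloc[0] == res["p"].min()
        assert detected >= 4

    def test_collapses_to_ols_without_polygenic_variance(self, rng):
        # independent subjects: the REML profile should choose delta ~ 0 and
        # reproduce ordinary least squares
        n = 200
        kin = assoc.KinshipMatrix(np.arange(n), np.eye(n))
        g = rng.binomial(2, 0.4, (n, 5)).astype(float)
        y = rng.normal(size=n)
        res = assoc.snp_mixed_gwas(y, g, None, kin)
        for j in range(5):
            X = np.column_stack([np.ones(n), g[:, j]])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            assert res["beta"].iloc[j] == pytest.approx(beta[1], abs=1e-6)

    def test_reml_recovers_simulated_heritability(self, bull_kinship, rng):
        n = len(bull_kinship.subject_ids)
        L = np.linalg.cholesky(bull_kinship.values + 1e-8 * np.eye(n))
        h2 = 0.4
        ratios = []
        for _ in range(30):
            y = (L @ rng.normal(size=n)) * np.sqrt(h2) \
                + rng.normal(size=n) * np.sqrt(1 - h2)
            g = rng.binomial(2, 0.4, (n, 1)).astype(float)
            res = assoc.snp_mixed_gwas(y, g, None, bull_kinship)
            s_u, s_e = res["sigma2_u"].iloc[0], res["sigma2_e"].iloc[0]
            ratios.append(s_u / (s_u + s_e))
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - h2) < 3 * max(se, 0.02)

    def test_low_maf_markers_skipped(self, rng):
        n = 100
        kin = assoc.KinshipMatrix(np.arange(n), np.eye(n))
        g = np.zeros((n, 1))
        g[0, 0] = 1
        res = assoc.snp_mixed_gwas(rng.normal(size=n), g, None, kin)
        assert np.isnan(res["p"].iloc[0])


class TestBonferroni:
    def test_printed_thresholds(self):
        assert assoc.bonferroni_threshold(0.05, 50_000) == pytest.approx(1e-6)
        assert assoc.bonferroni_threshold(0.05, 1_000) == pytest.approx(5e-5)
        assert assoc.bonferroni_threshold(0.05, 1) == pytest.approx(0.05)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            assoc.bonferroni_threshold(1.5, 10)


class TestAncestralHmm:
    def test_two_cluster_haplotypes_recovered(self, rng):
        m = 80
        pos = np.arange(1, m + 1) * 50_000
        anc = rng.integers(0, 2, (2, m)).astype(np.uint8)
        owners = np.repeat(np.arange(60), 2)
        labels = rng.integers(0, 2, 120)
        haps = anc[labels].copy()
        noise = rng.random((120, m)) < 0.01
        haps[noise] ^= 1
        model = assoc.fit_ancestral_hmm(haps, pos, K=2, n_starts=2, seed=1,
                                        hap_owner=owners)
        post = model.posteriors()
        assign = post.argmax(axis=2)  # (m, H)
        agree = (assign == labels[None, :]).mean()
        assert max(agree, 1 - agree) >= 0.99

    def test_em_loglik_non_decreasing(self, rng):
        m = 40
        pos = np.arange(1, m + 1) * 50_000
        haps = rng.integers(0, 2, (40, m)).astype(np.uint8)
        lls = []
        for it in range(1, 7):
            model = assoc.fit_ancestral_hmm(haps, pos, K=4, n_starts=1,
                                            seed=9, n_iter=it, tol=0.0)
            lls.append(model.loglik)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_posteriors_normalised(self, rng):
        m = 30
        pos = np.arange(1, m + 1) * 50_000
        haps = rng.integers(0, 2, (20, m)).astype(np.uint8)
        model = assoc.fit_ancestral_hmm(haps, pos, K=3, n_starts=1, seed=2)
        post = model.posteriors()
        assert np.allclose(post.sum(axis=2), 1.0, atol=1e-10)

    def test_deletion_haplotypes_map_to_one_dominant_state(self, small_cohort):
        cohort = small_cohort
        pos = cohort.markers.positions
        d = cohort.deletion
        centre = (d.start_bp + d.end_bp) // 2
        win = (pos >= centre - 3_000_000) & (pos <= centre + 3_000_000)
        haps = cohort.phased.haplotypes[:, :, win].reshape(-1, int(win.sum()))
        owners = np.repeat(np.arange(cohort.phased.n_animals), 2)
        model = assoc.fit_ancestral_hmm(haps, pos[win], K=10, n_starts=1,
                                        seed=3, n_iter=15, hap_owner=owners)
        j = int(np.searchsorted(pos[win], centre))
        post = model.posteriors(min(j, int(win.sum()) - 1))
        flags = cohort.phased.del_flags.reshape(-1)
        mean_post = post[flags].mean(axis=0)
        assert mean_post.max() >= 0.90


class TestHaplotypeLrt:
    def _data(self, rng, n=250, K=8, effect=0.0):
        kin = assoc.KinshipMatrix(np.arange(n), np.eye(n))
        # dosages from random state assignment of 2n haplotypes
        hap_states = rng.integers(0, K, (n, 2))
        D = np.zeros((n, K))
        for c in range(2):
            np.add.at(D, (np.arange(n), hap_states[:, c]), 1.0)
        y = rng.normal(size=n) + effect * D[:, 0]
        w = rng.uniform(1.0, 5.0, n)
        return y, D, kin, w

    def test_null_type_one_error_moderate(self, rng):
        hits = 0
        R = 40
        for _ in range(R):
            y, D, kin, w = self._data(rng)
            fit = assoc.haplotype_lrt(y, D, None, kin, w)
            hits += fit.p_value < 0.05
        # chi2(1) at a variance boundary is anti-conservative; allow <= 0.15
        assert hits / R <= 0.15

    def test_signal_detected_and_state_effect_signed(self, rng):
        y, D, kin, w = self._data(rng, n=400, effect=-1.0)
        fit = assoc.haplotype_lrt(y, D, None, kin, w)
        assert fit.p_value < 1e-4
        assert int(np.argmin(fit.state_effects)) == 0

    def test_conditioning_on_causal_state_removes_signal(self, rng):
        y, D, kin, w = self._data(rng, n=400, effect=-1.0)
        fit = assoc.haplotype_lrt(y, np.delete(D, 0, axis=1), D[:, [0]],
                                  kin, w)
        assert fit.p_value > 0.01

    def test_lrt_nonnegative_and_zero_variance_gives_zero(self, rng):
        y, D, kin, w = self._data(rng)
        fit = assoc.haplotype_lrt(y, D, None, kin, w)
        assert fit.statistic >= 0.0

    def test_reml_matches_dense_oracle_on_small_data(self, rng):
        """The rotated/Woodbury restricted likelihood must agree with a
        direct dense-matrix evaluation (difference of two parameter points,
        so basis constants cancel)."""
        n, K = 30, 4
        A = np.eye(n)
        ped_noise = rng.normal(size=(n, n)) * 0.05
        A = A + ped_noise @ ped_noise.T  # PSD perturbation
        dd = np.sqrt(np.diag(A))
        A = A / np.outer(dd, dd) + np.eye(n) * 1e-6
        A = A / A[0, 0]
        np.fill_diagonal(A, 1.0)
        y = rng.normal(size=n)
        D = rng.integers(0, 2, (n, K)).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        X = np.ones((n, 1))
        kin = assoc.KinshipMatrix(np.arange(n), A)
        engine = assoc._TwoComponentREML(y, X, D, A, w)

        def dense_ll(gh, gu):
            Vt = gh * (D @ D.T) + gu * A + np.diag(1.0 / w)
            Viy = np.linalg.solve(Vt, y)
            ViX = np.linalg.solve(Vt, X)
            XtViX = X.T @ ViX
            beta = np.linalg.solve(XtViX, X.T @ Viy)
            r = y - X @ beta
            rss = float(r @ np.linalg.solve(Vt, r))
            sigma2 = rss / (n - 1)
            sgn, ld_v = np.linalg.slogdet(Vt)
            _, ld_xx = np.linalg.slogdet(XtViX)
            return -0.5 * ((n - 1) * (np.log(2 * np.pi * sigma2) + 1.0)
                           + ld_v + ld_xx)

        for gh, gu in [(0.5, 0.3), (2.0, 0.01), (1e-4, 1.0)]:
            diff_engine = engine.loglik(gh, gu)[0] - engine.loglik(1.0, 1.0)[0]
            diff_dense = dense_ll(gh, gu) - dense_ll(1.0, 1.0)
            assert diff_engine == pytest.approx(diff_dense, abs=1e-6)


class TestDuoPhase:
    def test_phases_where_mendel_determines(self):
        child = np.array([0, 1, 1, 2, -1], dtype=np.int8)
        sire = np.array([0, 0, 1, 2, 0], dtype=np.int8)
        out = assoc.duo_phase(child, sire)
        assert out[0, 0] == 0 and out[1, 0] == 0  # hom child
        assert out[0, 1] == 0 and out[1, 1] == 1  # het child, hom sire
        assert out[0, 2] == -1  # het child, het sire: undetermined
        assert out[0, 3] == 1 and out[1, 3] == 1
        assert out[0, 4] == -1
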