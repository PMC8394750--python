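"""GRM, pairwise relatedness and the mixed-model association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fstscan.association import (
    pairwise_ibd,
    reml_variance_components,
    snp_association,
    vanraden_grm,
)
from fstscan.simulate import SimConfig, simulate_cohort, simulate_parent_offspring

from conftest import make_matrix


@pytest.fixture(scope="module")
def hwe_cohort():
    cfg = SimConfig(n_samples=50, n_snps=5000, heritability=0.0, seed=77)
    g, _, _ = simulate_cohort(cfg)
    return g


class TestGrm:
    def test_clone_matches_diagonal(self, hwe_cohort):
        d = hwe_cohort.dosage[list(range(20)) + [0], :]
        grm = vanraden_grm(make_matrix(d))
        assert grm.matrix[0, 20] == pytest.approx(grm.matrix[0, 0], abs=1e-10)
        assert grm.matrix[20, 20] == pytest.approx(grm.matrix[0, 0], abs=1e-10)

    def test_unrelated_off_diagonal_near_structural_value(self, hwe_cohort):
        # centring by sample-estimated frequencies forces row sums toward 0,
        # so unrelated samples have mean off-diagonal ~ -mean(diag)/(n-1)
        grm = vanraden_grm(hwe_cohort)
        n = grm.matrix.shape[0]
        off = grm.matrix[~np.eye(n, dtype=bool)]
        diag = np.diag(grm.matrix)
        assert off.mean() == pytest.approx(-diag.mean() / (n - 1), abs=0.005)
        assert abs(off.mean()) < 0.025
        assert diag.mean() == pytest.approx(1.0, abs=0.2)

    def test_allele_relabel_invariance(self, hwe_cohort):
        g = hwe_cohort.take(snp_indices=range(500), sample_indices=range(30))
        grm1 = vanraden_grm(g).matrix
        d = g.dosage.copy()
        d[:, 10] = 2 - d[:, 10]  # flip one SNP's allele orientation
        g2 = make_matrix(d)
        grm2 = vanraden_grm(g2).matrix
        np.testing.assert_allclose(grm1, grm2, atol=1e-10)

    def test_positive_semidefinite(self, hwe_cohort):
        grm = vanraden_grm(hwe_cohort)
        eig = np.linalg.eigvalsh(grm.matrix)
        assert eig.min() >= -1e-8

    def test_symmetry(self, hwe_cohort):
        m = vanraden_grm(hwe_cohort).matrix
        np.testing.assert_allclose(m, m.T, atol=1e-10)

    def test_monomorphic_only_errors(self):
        g = make_matrix(np.zeros((5, 12), dtype=np.int8))
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_grm(g)


class TestPairwiseIbd:
    def test_exact_copy_pi_hat_one(self, hwe_cohort):
        g = make_matrix(hwe_cohort.dosage[[0, 0, 1, 2], :])
        pi, _ = pairwise_ibd(g)
        assert pi[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_unrelated_mean_small(self, hwe_cohort):
        g = hwe_cohort.take(sample_indices=range(25))
        _, mean_pi = pairwise_ibd(g)
        assert mean_pi < 0.05

    def test_parent_offspring_near_half(self):
        g = simulate_parent_offspring(15, n_snps=5000, seed=13)
        pi, _ = pairwise_ibd(g)
        po = np.array([pi[2 * k, 2 * k + 1] for k in range(15)])
        assert abs(po.mean() - 0.5) < 0.05


class TestReml:
    def test_identity_kinship_matches_ols_variance(self):
        rng = np.random.default_rng(0)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(size=n)
        sg2, se2 = reml_variance_components(y, X, np.eye(n))
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        ols_var = resid @ resid / (n - X.shape[1])
        assert sg2 + se2 == pytest.approx(ols_var, abs=1e-6)

    def test_null_heritability_recovered(self):
        # family-structured kinship (identifiable ratio): pure-noise traits.
        # The REML information bound gives SE(h2) ~ sqrt(2 / sum K_ij^2)
        # ~ 0.26 for 12 families of 5, so the null estimate is a point mass
        # at 0 plus a half-normal of that scale: the median sits at 0 and
        # ~95% of estimates stay below 1.7*SE ~ 0.45
        K = np.kron(np.eye(12), np.full((5, 5), 0.5) + 0.5 * np.eye(5))
        rng = np.random.default_rng(1)
        n = K.shape[0]
        X = np.ones((n, 1))
        ests = []
        for _ in range(100):
            y = rng.normal(size=n)
            sg2, se2 = reml_variance_components(y, X, K)
            ests.append(sg2 / (sg2 + se2))
        ests = np.array(ests)
        assert np.median(ests) < 0.05
        assert (ests < 0.45).mean() >= 0.90

    def test_heritable_signal_recovered(self):
        # traits drawn from the mixed model itself at h2 = 0.5 over a
        # family-structured kinship, where the ratio is identifiable
        K = np.kron(np.eye(40), np.full((5, 5), 0.5) + 0.5 * np.eye(5))
        L = np.linalg.cholesky(K)
        rng = np.random.default_rng(3)
        n = K.shape[0]
        X = np.ones((n, 1))
        hits = 0
        for _ in range(20):
            y = L @ rng.normal(size=n) + rng.normal(size=n)
            sg2, se2 = reml_variance_components(y, X, K)
            hits += abs(sg2 / (sg2 + se2) - 0.5) < 0.30
        # SE(h2) ~ sqrt(2 / sum K_ij^2) ~ 0.14 for 40 families of 5, so a
        # +/- 2 SE band should cover >= 90% of replicates
        assert hits >= 18

    def test_rank_deficient_design_rejected(self):
        n = 30
        X = np.ones((n, 2))
        with pytest.raises(ValueError, match="rank"):
            reml_variance_components(np.zeros(n), X, np.eye(n))


class TestSnpAssociation:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(4)
        n = 40
        d = rng.binomial(2, 0.4, (n, 20)).astype(np.int8)
        g = make_matrix(d)
        sex = np.array((["male", "female"] * (n // 2)))
        y = 2.0 * d[:, 3] + 0.7 * (sex == "male")
        out = snp_association(
            g, y, pd.Series(sex), np.eye(n), ["rs103"],
            variance_components=(0.0, 1.0),
        )
        assert out.loc[0, "beta"] == pytest.approx(2.0, abs=1e-8)
        assert out.loc[0, "p"] < 1e-12

    def test_sigma_g_zero_equals_ols(self):
        rng = np.random.default_rng(5)
        n = 50
        d = rng.binomial(2, 0.3, (n, 10)).astype(np.int8)
        g = make_matrix(d)
        sex = pd.Series((["male", "female"] * (n // 2)))
        y = rng.normal(size=n) + 0.3 * d[:, 0]
        out = snp_association(
            g, y, sex, np.eye(n), ["rs100"], variance_components=(0.0, 1.0)
        )
        X = np.column_stack([np.ones(n), (sex == "male").to_numpy(float), d[:, 0]])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[2, 2])
        t = beta[2] / se
        p_ols = 2 * sps.t.sf(abs(t), df=n - 3)
        assert out.loc[0, "beta"] == pytest.approx(beta[2], abs=1e-8)
        assert out.loc[0, "p"] == pytest.approx(p_ols, abs=1e-8)

    def test_sample_reorder_invariance(self, hwe_cohort):
        g = hwe_cohort.take(sample_indices=range(40), snp_indices=range(200))
        rng = np.random.default_rng(6)
        y = rng.normal(3.7, 0.5, 40)
        grm = vanraden_grm(g)
        out1 = snp_association(g, y, g.samples["sex"], grm, ["rs9000010"])
        perm = rng.permutation(40)
        g2 = g.take(sample_indices=perm)
        grm2 = vanraden_grm(g2)
        out2 = snp_association(
            g2, y[perm], g2.samples["sex"], grm2, ["rs9000010"]
        )
        assert out1.loc[0, "p"] == pytest.approx(out2.loc[0, "p"], rel=1e-8)

    def test_monomorphic_snp_missing_record(self):
        d = np.zeros((30, 5), dtype=np.int8)
        rng = np.random.default_rng(7)
        d[:, 1:] = rng.binomial(2, 0.4, (30, 4))
        g = make_matrix(d)
        y = rng.normal(size=30)
        out = snp_association(
            g, y, g.samples["sex"], np.eye(30), ["rs100", "rs101"],
            variance_components=(0.0, 1.0),
        )
        assert np.isnan(out.loc[0, "p"])
        assert not np.isnan(out.loc[1, "p"])

    def test_sex_confounding_shifts_beta(self):
        # construct a SNP correlated with sex and a sex-driven trait: omitting
        # the sex covariate inflates the SNP effect
        rng = np.random.default_rng(8)
        n = 200
        sex = np.array(["male"] * (n // 2) + ["female"] * (n // 2))
        d = np.zeros((n, 2), dtype=np.int8)
        d[:, 0] = np.where(
            sex == "male", rng.binomial(2, 0.8, n), rng.binomial(2, 0.2, n)
        )
        d[:, 1] = rng.binomial(2, 0.5, n)
        g = make_matrix(d)
        y = 1.0 * (sex == "male") + rng.normal(0, 0.3, n)
        with_sex = snp_association(
            g, y, pd.Series(sex), np.eye(n), ["rs100"],
            variance_components=(0.0, 1.0),
        ).loc[0, "beta"]
        # OLS oracle without the sex covariate (intercept + dosage only)
        X = np.column_stack([np.ones(n), d[:, 0].astype(float)])
        no_sex = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert abs(no_sex - with_sex) > 0.1

    def test_null_type_one_rate_calibrated(self, hwe_cohort):
        # trait drawn from the mixed-model null (polygenic + residual);
        # testing unlinked SNPs should reject at ~5%
        g = hwe_cohort
        grm = vanraden_grm(g)
        n = g.n_samples
        chol = np.linalg.cholesky(grm.matrix + 1e-6 * np.eye(n))
        rng = np.random.default_rng(9)
        rejections = 0
        trials = 400
        sex = g.samples["sex"]
        for i in range(trials):
            y = 0.7 * chol @ rng.normal(size=n) + 0.7 * rng.normal(size=n)
            sid = g.variants["snp_id"][int(rng.integers(g.n_snps))]
            out = snp_association(g, y, sex, grm, [sid])
            rejections += out.loc[0, "p"] <= 0.05
        assert abs(rejections / trials - 0.05) <= 0.025
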