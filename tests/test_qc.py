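"""Quality-control cascade: call rates, MAF, exact HWE test, LD pruning."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fstscan.qc import (
    QCThresholds,
    apply_qc,
    hwe_exact_test,
    ld_prune,
    pairwise_r2,
    sample_call_rate,
    snp_stats,
)
from fstscan.simulate import SimConfig, simulate_cohort
from fstscan.types import MISSING

from conftest import make_matrix


def hwe_exact_oracle(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Brute-force enumeration with exact rational arithmetic.

    P(het = h | allele counts) = 2^h n! na! nb! / (hom_a! h! hom_b! (2n)!),
    summed over every h with the observed parity; p-value sums the
    configurations no more probable than the observed one.
    """
    n = n_hom_a + n_het + n_hom_b
    na = 2 * n_hom_a + n_het
    nb = 2 * n - na
    f = math.factorial

    def prob(h):
        ha, hb = (na - h) // 2, (nb - h) // 2
        return Fraction(2**h * f(n) * f(na) * f(nb), f(ha) * f(h) * f(hb) * f(2 * n))

    hets = range(min(na, nb) % 2, min(na, nb) + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(3, 5, 2), (0, 10, 0), (7, 1, 1), (2, 2, 2)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_oracle(*counts), abs=1e-12
        )

    def test_oracle_agreement_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(1, 101))
            counts = rng.multinomial(n, [0.4, 0.35, 0.25])
            assert hwe_exact_test(*counts) == pytest.approx(
                hwe_exact_oracle(*counts), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pvalue_in_unit_interval(self, a, h, b):
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert 0 < p <= 1


class TestPerSampleAndPerSnp:
    def test_sample_call_rate_fractions(self):
        d = np.zeros((3, 100), dtype=np.int8)
        d[1, :11] = MISSING
        d[2, :] = MISSING
        g = make_matrix(d)
        cr = sample_call_rate(g)
        assert cr.tolist() == [1.0, 0.89, 0.0]
        assert (cr < 0.90).tolist() == [False, True, True]

    def test_snp_stats_formula(self):
        # columns: (5,0,5) -> maf 0.5; (9,1,0) -> p 0.05; (10,0,0) -> maf 0
        d = np.zeros((10, 3), dtype=np.int8)
        d[5:, 0] = 2
        d[9, 1] = 1
        g = make_matrix(d)
        s = snp_stats(g)
        assert s["maf"].tolist() == pytest.approx([0.5, 0.05, 0.0])
        assert s["maf"][1] >= 0.05  # boundary value is retained

    def test_all_missing_snp_maf_is_nan(self):
        d = np.full((4, 1), MISSING, dtype=np.int8)
        s = snp_stats(make_matrix(d))
        assert np.isnan(s["maf"][0])
        assert s["call_rate"][0] == 0.0


class TestPairwiseR2:
    def test_identity_and_sign_invariance(self):
        x = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=np.int8)
        assert pairwise_r2(x, x) == pytest.approx(1.0)
        assert pairwise_r2(x, 2 - x) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.4, 10_000)
        y = rng.binomial(2, 0.4, 10_000)
        assert pairwise_r2(x, y) < 0.01

    def test_zero_variance_returns_zero(self):
        x = np.ones(10, dtype=np.int8)
        y = np.arange(10, dtype=np.int8) % 3
        assert pairwise_r2(x, y) == 0.0


class TestLdPrune:
    def test_duplicate_snps_keep_one(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.4, 40).astype(np.int8)
        g = make_matrix(np.column_stack([col, col]))
        kept = ld_prune(g)
        assert len(kept) == 1

    def test_single_snp_chromosome_untouched(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, (30, 2)).astype(np.int8)
        g = make_matrix(d, chrom=["1", "2"], pos=[100, 100])
        assert ld_prune(g).tolist() == [0, 1]

    def test_block_structure_pruned_to_representatives(self):
        # 100 SNPs in perfect blocks of 4 -> one representative per block,
        # and no retained pair within a window above the r^2 ceiling
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.5, (60, 25)).astype(np.int8)
        d = np.repeat(base, 4, axis=1)
        g = make_matrix(d)
        t = QCThresholds()
        kept = ld_prune(g, t)
        assert len(kept) == 25
        dosage = g.dosage.astype(float)
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if abs(kept[a] - kept[b]) < t.ld_window_snps:
                    assert pairwise_r2(dosage[:, kept[a]], dosage[:, kept[b]]) <= 0.5

    def test_stable_under_rerun(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, (50, 120)).astype(np.int8)
        d[:, 1::2] = d[:, ::2]  # heavy LD
        g = make_matrix(d)
        kept = ld_prune(g)
        g2 = g.take(snp_indices=kept)
        assert ld_prune(g2).tolist() == list(range(len(kept)))


class TestApplyQc:
    def test_disabled_thresholds_identity(self, cohort):
        g, _, _ = cohort
        out, report = apply_qc(g, QCThresholds.disabled())
        assert out.n_samples == g.n_samples
        assert out.n_snps == g.n_snps
        assert all(v == 0 for v in report.removed_by_stage.values())

    def test_planted_low_call_samples_removed(self):
        cfg = SimConfig(n_samples=40, n_snps=300, seed=11)
        g, _, _ = simulate_cohort(cfg)
        d = g.dosage.copy()
        bad = [3, 7, 19, 22, 31]
        rng = np.random.default_rng(0)
        for i in bad:
            mask = rng.random(300) < 0.2  # call rate ~0.8 < 0.9
            d[i, mask] = MISSING
        g = make_matrix(d)
        out, report = apply_qc(
            g, QCThresholds(min_snp_call_rate=0.0, min_maf=0.0,
                            hwe_p_floor=0.0, ld_r2_max=1.0, require_rs_id=False)
        )
        assert report.removed_by_stage["sample_call_rate"] == 5
        kept_ids = set(out.samples["sample_id"])
        assert kept_ids == {f"S{i:03d}" for i in range(40) if i not in bad}

    def test_hwe_boundary_strictly_below_removed(self):
        # all-het SNP: exact p well below 1e-6 at n=40 -> removed at hwe;
        # companion SNP drawn in HWE proportions -> retained
        rng = np.random.default_rng(8)
        d = np.ones((40, 2), dtype=np.int8)
        d[:, 1] = rng.binomial(2, 0.5, 40)
        g = make_matrix(d)
        out, report = apply_qc(
            g, QCThresholds(min_sample_call_rate=0.0, min_snp_call_rate=0.0,
                            min_maf=0.0, ld_r2_max=1.0, require_rs_id=False)
        )
        assert report.removed_by_stage["hwe"] == 1
        assert list(out.variants["snp_id"]) == ["rs101"]

    def test_idempotent(self, cohort):
        g, _, _ = cohort
        t = QCThresholds()
        once, _ = apply_qc(g, t)
        twice, report = apply_qc(once, t)
        assert np.array_equal(once.dosage, twice.dosage)
        snp_stages = ("snp_call_rate", "maf", "hwe", "ld_prune")
        assert all(report.removed_by_stage[s] == 0 for s in snp_stages)

    def test_survivors_satisfy_thresholds(self, cohort):
        g, _, _ = cohort
        t = QCThresholds()
        out, _ = apply_qc(g, t)
        s = snp_stats(out)
        assert (s["call_rate"] >= t.min_snp_call_rate).all()
        assert (s["maf"] >= t.min_maf).all()

    def test_everything_removed_raises_with_report(self):
        d = np.zeros((4, 3), dtype=np.int8)  # all SNPs monomorphic
        g = make_matrix(d)
        with pytest.raises(ValueError) as err:
            apply_qc(g, QCThresholds())
        assert err.value.report.n_snps_out == 0
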