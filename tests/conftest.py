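import numpy as np
import pandas as pd
import pytest

from fstscan.simulate import SimConfig, simulate_cohort, simulate_divergent_groups
from fstscan.types import GenotypeMatrix


def make_matrix(dosage, chrom=None, pos=None, sex=None, rs=True):
    """Small GenotypeMatrix literal for targeted unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else list(range(1000, 1000 + 1000 * m, 1000))
    ids = [f"rs{100 + j}" if rs else f"chip_{j}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "snp_id": ids,
            "rs_id": [i if rs else pd.NA for i in ids],
            "chrom": chrom,
            "pos": pos,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n)],
            "sex": sex if sex is not None else (["male", "female"] * (n // 2 + 1))[:n],
            "birth_weight": np.nan,
            "weaning_weight": np.nan,
        }
    )
    return GenotypeMatrix(dosage, variants, samples)


@pytest.fixture(scope="session")
def cohort():
    """Phenotyped cohort with one strong QTL; reused read-only by tests."""
    cfg = SimConfig(
        n_samples=80,
        n_snps=1200,
        heritability=0.3,
        missing_rate=0.01,
        qtl=[(100, 0.8)],
        seed=42,
    )
    g, samples, truth = simulate_cohort(cfg)
    return g, samples, truth


@pytest.fixture(scope="session")
def null_divergent():
    """Two 30-sample groups drawn from identical frequencies (pure null)."""
    cfg = SimConfig(
        n_samples=60,
        n_snps=800,
        divergent_snps=[(0, 0.0)],
        group_sizes=(30, 30),
        seed=7,
    )
    return simulate_divergent_groups(cfg)
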