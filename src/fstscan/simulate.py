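"""Synthetic SNP-chip cohorts with known, recoverable structure.

Two generation modes cover the two halves of the analysis:

* :func:`simulate_cohort` draws a single population in Hardy-Weinberg
  proportions (optionally with local LD blocks) and builds phenotypes from
  a mean, a sex effect, additive QTL effects, a polygenic term with a
  target heritability, and a residual that fills the remaining variance.
  Extreme-phenotype grouping of such a cohort induces allele-frequency
  divergence at the trait loci, which is exactly the signal the scan
  looks for.
* :func:`simulate_divergent_groups` plants allele-frequency differences
  delta directly between two fixed groups, giving a clean calibration
  target for the F_ST machinery without a phenotype model.

Defaults mirror the study system: 140 lambs (55 male / 85 female), ~50k
SNPs on 26 autosomes, MAF drawn uniformly on [0.05, 0.5], birth weight
3.7 +/- 0.5 kg with heritability 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grouping import HIGH, LOW, GroupAssignment
from .types import MISSING, GenotypeMatrix


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    QTL ``effect`` values are in trait-SD units per allele copy;
    ``sex_effect`` is the male - female mean difference in trait-SD units;
    ``divergent_snps`` plants (snp index, allele-frequency difference
    delta) pairs for the direct-divergence mode.
    """

    n_samples: int = 140
    n_snps: int = 50_000
    n_chromosomes: int = 26
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    ld_block_size: int = 0  # 0 = independent SNPs
    ld_rho: float = 0.0
    divergent_snps: list[tuple[int, float]] = field(default_factory=list)
    qtl: list[tuple[int, float]] = field(default_factory=list)
    sex_effect: float = 0.3
    heritability: float = 0.2
    trait_mean: float = 3.7
    trait_sd: float = 0.5
    trait: str = "birth_weight"
    male_fraction: float = 55 / 140
    group_sizes: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.heritability < 1:
            raise ValueError("heritability must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        v_qtl = sum(e**2 for _, e in self.qtl)  # upper bound (2pq <= 0.5)
        if self.heritability + 0.5 * v_qtl >= 1:
            raise ValueError(
                "infeasible variance budget: heritability + QTL variance >= 1"
            )


def _variant_frame(cfg: SimConfig) -> pd.DataFrame:
    """Evenly spread SNPs over the autosomes, 50 kb apart, chip-style rs ids."""
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, cfg.n_chromosomes + 1), per_chrom)
    pos = np.concatenate([50_000 * (np.arange(k) + 1) for k in per_chrom])
    ids = [f"rs{9_000_000 + i}" for i in range(cfg.n_snps)]
    return pd.DataFrame(
        {
            "snp_id": ids,
            "rs_id": ids,
            "chrom": chroms.astype(str),
            "pos": pos.astype(np.int64),
            "allele_a": "A",
            "allele_b": "B",
        }
    )


def _sample_frame(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_male = int(round(cfg.male_fraction * cfg.n_samples))
    sex = np.array(["male"] * n_male + ["female"] * (cfg.n_samples - n_male))
    rng.shuffle(sex)
    return pd.DataFrame(
        {
            "sample_id": [f"L{i + 1:04d}" for i in range(cfg.n_samples)],
            "sex": sex,
            "birth_weight": np.nan,
            "weaning_weight": np.nan,
        }
    )


def _draw_genotypes(cfg: SimConfig, p: np.ndarray, n: int, rng) -> np.ndarray:
    """HWE genotypes, optionally with latent-gamete LD blocks (AR(1) copula)."""
    if cfg.ld_block_size <= 1 or cfg.ld_rho == 0.0:
        return rng.binomial(2, p[None, :], size=(n, len(p))).astype(np.int8)
    m = len(p)
    thresh = _norm_ppf(p)
    dosage = np.empty((n, m), dtype=np.int8)
    rho = cfg.ld_rho
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        size = stop - start
        z = np.empty((n, 2, size))
        z[:, :, 0] = rng.standard_normal((n, 2))
        for j in range(1, size):
            z[:, :, j] = rho * z[:, :, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal((n, 2))
        alleles = (z < thresh[None, None, start:stop]).astype(np.int8)
        dosage[:, start:stop] = alleles.sum(axis=1)
    return dosage


def _norm_ppf(p: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(p)


def _mask_missing(dosage: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate > 0:
        mask = rng.random(dosage.shape) < rate
        dosage = dosage.copy()
        dosage[mask] = MISSING
    return dosage


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """One-population cohort with a fully specified phenotype model.

    Returns the genotype matrix (phenotypes attached to its samples
    frame), the sample frame itself, and a truth record holding every
    planted parameter.  Bit-reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    variants = _variant_frame(cfg)
    samples = _sample_frame(cfg, rng)
    p = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    dosage_clean = _draw_genotypes(cfg, p, cfg.n_samples, rng)

    male = (samples["sex"] == "male").to_numpy(float)
    y = np.full(cfg.n_samples, cfg.trait_mean)
    y += cfg.sex_effect * cfg.trait_sd * male

    qtl_idx = np.array([j for j, _ in cfg.qtl], dtype=int)
    effects = np.array([e for _, e in cfg.qtl], dtype=float)
    v_qtl = float(np.sum(effects**2 * 2 * p[qtl_idx] * (1 - p[qtl_idx]))) if len(qtl_idx) else 0.0
    if cfg.heritability + v_qtl >= 1:
        raise ValueError("infeasible variance budget with realised QTL variance")
    for j, e in zip(qtl_idx, effects):
        y += e * cfg.trait_sd * (dosage_clean[:, j] - 2 * p[j])

    poly_scale = 0.0
    if cfg.heritability > 0:
        bg = np.setdiff1d(np.arange(cfg.n_snps), qtl_idx)
        u = rng.standard_normal(len(bg))
        g_raw = (dosage_clean[:, bg] - 2 * p[bg]) @ u
        sd = g_raw.std()
        poly_scale = np.sqrt(cfg.heritability) * cfg.trait_sd / sd if sd > 0 else 0.0
        y += poly_scale * g_raw

    resid_sd = cfg.trait_sd * np.sqrt(1 - cfg.heritability - v_qtl)
    y += resid_sd * rng.standard_normal(cfg.n_samples)

    samples = samples.copy()
    samples[cfg.trait] = y
    dosage = _mask_missing(dosage_clean, cfg.missing_rate, rng)
    g = GenotypeMatrix(dosage, variants, samples)
    truth = {
        "config": _config_record(cfg),
        "allele_freq": p.tolist(),
        "qtl": [(int(j), float(e)) for j, e in cfg.qtl],
        "qtl_variance_fraction": v_qtl,
        "polygenic_scale": float(poly_scale),
        "residual_sd": float(resid_sd),
    }
    return g, samples, truth


def simulate_divergent_groups(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, GroupAssignment, dict]:
    """Two fixed groups with planted allele-frequency differences.

    Planted SNP j with difference delta draws the LOW group at p_j -
    delta/2 and the HIGH group at p_j + delta/2; all other SNPs share
    p_j.  Group labels are fixed by construction (no phenotype model).
    """
    if not cfg.divergent_snps:
        raise ValueError("divergent_snps must be non-empty in divergence mode")
    if cfg.group_sizes is None:
        n_low = cfg.n_samples // 2
        sizes = (n_low, cfg.n_samples - n_low)
    else:
        sizes = cfg.group_sizes
    n_low, n_high = sizes
    rng = np.random.default_rng(cfg.seed)
    n = n_low + n_high
    cfg_n = SimConfig(**{**_config_record(cfg), "n_samples": n})
    variants = _variant_frame(cfg_n)
    samples = _sample_frame(cfg_n, rng)

    p = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    p_low = p.copy()
    p_high = p.copy()
    for j, delta in cfg.divergent_snps:
        # planted base frequency must keep p +/- delta/2 inside [0.01, 0.99];
        # draw it from the feasible part of maf_range
        lo_f = max(cfg.maf_range[0], 0.01 + delta / 2)
        hi_f = min(cfg.maf_range[1], 0.99 - delta / 2)
        if lo_f > hi_f:
            raise ValueError(
                f"delta {delta} at SNP {j} pushes group frequencies outside "
                f"[0.01, 0.99] for every base frequency in maf_range"
            )
        p[j] = rng.uniform(lo_f, hi_f)
        p_low[j], p_high[j] = p[j] - delta / 2, p[j] + delta / 2

    d_low = rng.binomial(2, p_low[None, :], size=(n_low, cfg.n_snps))
    d_high = rng.binomial(2, p_high[None, :], size=(n_high, cfg.n_snps))
    dosage = np.vstack([d_low, d_high]).astype(np.int8)
    dosage = _mask_missing(dosage, cfg.missing_rate, rng)

    labels = pd.Series([LOW] * n_low + [HIGH] * n_high, name="group")
    groups = GroupAssignment(
        trait=cfg.trait,
        labels=labels,
        low_threshold=np.nan,
        high_threshold=np.nan,
        t_statistic=np.nan,
        t_p_value=np.nan,
    )
    g = GenotypeMatrix(dosage, variants, samples)
    truth = {
        "config": _config_record(cfg),
        "group_sizes": [n_low, n_high],
        "allele_freq": p.tolist(),
        "planted": [(int(j), float(d)) for j, d in cfg.divergent_snps],
    }
    return g, groups, truth


def simulate_parent_offspring(
    n_pairs: int,
    n_snps: int = 5_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Parent-offspring pairs sharing one gamete, for relatedness checks.

    Samples are ordered parent_1, child_1, parent_2, child_2, ...; each
    child inherits one allele drawn from its parent's genotype and one
    from the population.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf_range, size=n_snps)
    cfg = SimConfig(n_samples=2 * n_pairs, n_snps=n_snps, seed=seed)
    variants = _variant_frame(cfg)
    samples = _sample_frame(cfg, rng)
    dosage = np.empty((2 * n_pairs, n_snps), dtype=np.int8)
    for k in range(n_pairs):
        parent = rng.binomial(2, p)
        transmitted = rng.binomial(1, parent / 2)  # one allele from the parent
        other = rng.binomial(1, p)
        dosage[2 * k] = parent
        dosage[2 * k + 1] = transmitted + other
    return GenotypeMatrix(dosage, variants, samples)


def _config_record(cfg: SimConfig) -> dict:
    rec = asdict(cfg)
    rec["maf_range"] = tuple(rec["maf_range"])
    if rec["group_sizes"] is not None:
        rec["group_sizes"] = tuple(rec["group_sizes"])
    rec["divergent_snps"] = [tuple(x) for x in rec["divergent_snps"]]
    rec["qtl"] = [tuple(x) for x in rec["qtl"]]
    return rec
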