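"""SNP-array quality control.

The cascade mirrors standard chip QC practice: drop non-autosomal and
unnamed SNPs, then samples by call rate, then SNPs by call rate, minor
allele frequency, an exact Hardy-Weinberg test, and finally sliding-window
LD pruning.  Removal conditions are strict inequalities (a SNP sitting
exactly on a threshold is retained) and per-SNP statistics are recomputed
on the surviving samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import AUTOSOMES, MISSING, GenotypeMatrix, QCReport

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds of the QC cascade; a stage is disabled by zeroing it out.

    Defaults: samples need >=90% call rate; SNPs need >=98% call rate,
    MAF >= 0.05, HWE exact p >= 1e-6; LD pruning removes one of each pair
    with r^2 > 0.5 inside 50-SNP windows advanced by 5 SNPs.
    """

    min_sample_call_rate: float = 0.90
    min_snp_call_rate: float = 0.98
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-6
    ld_r2_max: float = 0.5
    ld_window_snps: int = 50
    ld_window_step: int = 5
    require_rs_id: bool = True

    def __post_init__(self) -> None:
        for name in ("min_sample_call_rate", "min_snp_call_rate", "min_maf",
                     "ld_r2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.ld_window_step > self.ld_window_snps:
            raise ValueError("ld_window_step must be <= ld_window_snps")

    @classmethod
    def disabled(cls) -> "QCThresholds":
        """Thresholds that pass everything (identity cascade)."""
        return cls(
            min_sample_call_rate=0.0,
            min_snp_call_rate=0.0,
            min_maf=0.0,
            hwe_p_floor=0.0,
            ld_r2_max=1.0,
            require_rs_id=False,
        )


def sample_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing genotypes per sample."""
    if g.n_snps == 0:
        raise ValueError("call rate undefined with zero SNPs")
    return (g.dosage != MISSING).mean(axis=1)


def snp_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, allele-b frequency, MAF and genotype counts.

    MAF is NaN for SNPs with no called genotypes (they fail call rate
    regardless).
    """
    if g.n_samples == 0:
        raise ValueError("SNP statistics undefined with zero samples")
    d = g.dosage
    n0 = (d == 0).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n2 = (d == 2).sum(axis=0)
    called = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2 * n2) / (2 * called)
    p = np.where(called > 0, p, np.nan)
    return pd.DataFrame(
        {
            "call_rate": called / g.n_samples,
            "p_allele_b": p,
            "maf": np.minimum(p, 1 - p),
            "n0": n0,
            "n1": n1,
            "n2": n2,
        }
    )


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Enumerates every heterozygote count compatible with the observed
    allele totals (same parity), computes the conditional probability of
    each configuration given the allele counts, and sums the probabilities
    not exceeding that of the observed table.  Returns a p-value in (0, 1].
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom_a + n_het  # rarity is irrelevant: test is symmetric
    log_probs, hets = _hwe_log_probs(n, n_a)
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_log_probs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities over attainable het counts.

    P(het | allele counts) ∝ 2^het * n! / (hom_a! het! hom_b!) with
    hom_a = (n_a - het)/2, hom_b = n - hom_a - het.
    """
    n_b = 2 * n - n_a
    max_het = min(n_a, n_b)
    hets = np.arange(max_het % 2, max_het + 1, 2)
    hom_a = (n_a - hets) // 2
    hom_b = (n_b - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_a + 1)
        - gammaln(hets + 1)
        - gammaln(hom_b + 1)
    )
    return logp, hets


def hwe_pvalues(stats: pd.DataFrame) -> np.ndarray:
    """Vector of exact HWE p-values from a :func:`snp_stats` frame."""
    out = np.ones(len(stats))
    for i, (n0, n1, n2) in enumerate(
        zip(stats["n0"].to_numpy(), stats["n1"].to_numpy(), stats["n2"].to_numpy())
    ):
        if n0 + n1 + n2 >= 1:
            out[i] = hwe_exact_test(int(n0), int(n1), int(n2))
    return out


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Missing entries are removed pairwise; with fewer than 2 complete pairs
    the call is invalid; zero variance in either vector yields 0 (logged),
    which never triggers pruning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise ValueError("need >=2 complete pairs for r^2")
    xc = x[ok] - x[ok].mean()
    yc = y[ok] - y[ok].mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0 or vy == 0:
        log.debug("zero dosage variance in pairwise r^2; returning 0")
        return 0.0
    return float((xc @ yc) ** 2 / (vx * vy))


def ld_prune(g: GenotypeMatrix, t: QCThresholds | None = None) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained SNP indices.

    Windows of ``ld_window_snps`` markers per chromosome advance by
    ``ld_window_step``.  Within a window, while any retained pair exceeds
    ``ld_r2_max``, the member with the lower MAF is dropped (tie: the
    later SNP).  The result is stable under re-running.
    """
    t = t or QCThresholds()
    if not g.is_sorted():
        raise ValueError("SNPs must be sorted by (chromosome, position)")
    if t.ld_r2_max >= 1.0:
        return np.arange(g.n_snps)
    maf = snp_stats(g)["maf"].to_numpy()
    dosage = np.where(g.dosage == MISSING, np.nan, g.dosage.astype(float))
    keep = np.ones(g.n_snps, dtype=bool)
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            window = idx[start : start + t.ld_window_snps]
            _prune_window(dosage, maf, keep, window, t.ld_r2_max)
            if start + t.ld_window_snps >= len(idx):
                break
            start += t.ld_window_step
    return np.flatnonzero(keep)


def _prune_window(dosage, maf, keep, window, r2_max) -> None:
    active = [int(i) for i in window if keep[i]]
    while True:
        worst = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                r2 = _r2_nan(dosage[:, i], dosage[:, j])
                if r2 > r2_max:
                    # drop the lower-MAF member; tie -> larger index
                    victim = i if (maf[i], -i) < (maf[j], -j) else j
                    worst = victim
                    break
            if worst is not None:
                break
        if worst is None:
            return
        keep[worst] = False
        active.remove(worst)


def _r2_nan(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xc = x[ok] - x[ok].mean()
    yc = y[ok] - y[ok].mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0 or vy == 0:
        return 0.0
    return float((xc @ yc) ** 2 / (vx * vy))


def apply_qc(
    g: GenotypeMatrix, t: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full QC cascade and return the filtered cohort plus a report.

    Stage order: non_autosomal & no_rs_id -> sample call rate -> SNP call
    rate -> MAF -> HWE -> LD prune.  SNP statistics are recomputed after
    sample removal.  Raises if every sample or every SNP is removed (the
    report is attached to the exception).
    """
    t = t or QCThresholds()
    report = QCReport(
        n_samples_in=g.n_samples,
        n_samples_out=g.n_samples,
        n_snps_in=g.n_snps,
        n_snps_out=g.n_snps,
    )

    autosomal = g.variants["chrom"].isin(AUTOSOMES).to_numpy()
    report.removed_by_stage["non_autosomal"] = int((~autosomal).sum())
    g = g.take(snp_indices=np.flatnonzero(autosomal)) if not autosomal.all() else g

    if t.require_rs_id:
        has_rs = g.variants["rs_id"].notna().to_numpy()
    else:
        has_rs = np.ones(g.n_snps, dtype=bool)
    report.removed_by_stage["no_rs_id"] = int((~has_rs).sum())
    if not has_rs.all():
        g = g.take(snp_indices=np.flatnonzero(has_rs))
    _check_nonempty(g, report)

    scr = sample_call_rate(g)
    keep_samples = scr >= t.min_sample_call_rate  # removal is strict '<'
    report.removed_by_stage["sample_call_rate"] = int((~keep_samples).sum())
    if not keep_samples.all():
        g = g.take(sample_indices=np.flatnonzero(keep_samples))
    _check_nonempty(g, report)

    stats = snp_stats(g)
    keep = stats["call_rate"].to_numpy() >= t.min_snp_call_rate
    report.removed_by_stage["snp_call_rate"] = int((~keep).sum())
    g, stats = _drop(g, stats, keep)
    _check_nonempty(g, report)

    maf = stats["maf"].to_numpy()
    keep = np.where(np.isnan(maf), False, maf >= t.min_maf)
    if t.min_maf == 0.0:
        keep = np.ones(len(stats), dtype=bool)
    report.removed_by_stage["maf"] = int((~keep).sum())
    g, stats = _drop(g, stats, keep)
    _check_nonempty(g, report)

    if t.hwe_p_floor > 0.0:
        hwe_p = hwe_pvalues(stats)
        keep = hwe_p >= t.hwe_p_floor
    else:
        keep = np.ones(len(stats), dtype=bool)
    report.removed_by_stage["hwe"] = int((~keep).sum())
    g, stats = _drop(g, stats, keep)
    _check_nonempty(g, report)

    retained = ld_prune(g, t)
    report.removed_by_stage["ld_prune"] = g.n_snps - len(retained)
    if len(retained) < g.n_snps:
        g = g.take(snp_indices=retained)
    _check_nonempty(g, report)

    report.n_samples_out = g.n_samples
    report.n_snps_out = g.n_snps
    return g, report


def _drop(g, stats, keep):
    if keep.all():
        return g, stats
    idx = np.flatnonzero(keep)
    return g.take(snp_indices=idx), stats.iloc[idx].reset_index(drop=True)


def _check_nonempty(g: GenotypeMatrix, report: QCReport) -> None:
    if g.n_samples == 0 or g.n_snps == 0:
        report.n_samples_out = g.n_samples
        report.n_snps_out = g.n_snps
        err = ValueError(
            f"QC removed everything ({g.n_samples} samples, {g.n_snps} SNPs left)"
        )
        err.report = report
        raise err
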