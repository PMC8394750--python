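"""Permutation null for the F_ST scan, with genomic-control correction.

Group labels are shuffled among the grouped animals (EXCLUDED animals
never enter), theta is recomputed per SNP for every shuffle, and the
one-sided upper-tail permutation p-value uses the (b+1)/(m+1)
finite-sample correction so that no p can be exactly zero.  Systematic
inflation of the resulting p-values is summarised by the genomic
inflation factor lambda (median 1-df chi-square quantile over its null
median) and removed by dividing the quantiles by lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .fst import wc_components_from_counts
from .grouping import GroupAssignment
from .types import GenotypeMatrix

log = logging.getLogger(__name__)

#: Median of the 1-df chi-square distribution.
CHI2_1_MEDIAN = float(chi2.isf(0.5, df=1))

#: Absolute tolerance for calling two permuted theta values tied.
_TIE_TOL = 1e-12


@dataclass
class PermutationResult:
    """Permutation p-values with their genomic-control adjustment."""

    n_iterations: int
    seed: int
    perm_p: np.ndarray
    lambda_gc: float
    gc_adjusted_p: np.ndarray


def permutation_pvalues(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    n_iterations: int = 10_000,
    seed: int = 0,
    pooled: bool = False,
    ties: str = "random",
    batch_size: int = 128,
) -> np.ndarray:
    """One-sided upper-tail permutation p-values for per-SNP theta.

    Each iteration shuffles the LOW/HIGH labels among grouped animals,
    preserving group sizes, and recomputes theta for every SNP.
    perm_p = (1 + #exceedances) / (n_valid + 1); draws with missing
    permuted theta are excluded from that SNP's count and denominator, so
    no p can be 0 and the smallest attainable value is 1/(n_valid+1).

    theta is a coarse function of the label split at cohort-scale group
    sizes, so permuted values tie with the observed one often; ``ties``
    picks how a tie contributes to the exceedance count:

    * ``"random"`` (default): a seeded Uniform(0,1) share of the tied
      draws, making p exactly uniform under the null (recommended for
      calibration-sensitive downstream steps such as lambda);
    * ``"midp"``: half of the tied draws (deterministic mid-p);
    * ``"upper"``: all tied draws (conservative; p stochastically large
      under the null).

    ``pooled=True`` compares each observed theta against the permuted
    thetas of *all* SNPs instead of its own.  Deterministic given
    ``seed``.
    """
    if n_iterations < 100:
        raise ValueError("need at least 100 permutation iterations")
    if ties not in ("random", "midp", "upper"):
        raise ValueError(f"unknown tie policy {ties!r}")
    rng = np.random.default_rng(seed)
    grouped = np.concatenate([groups.low_indices, groups.high_indices])
    n_low = groups.n_low
    dosage = g.dosage[grouped, :]
    m = g.n_snps

    # one-hot genotype indicators; permuted group counts are matmuls
    ind = [np.ascontiguousarray((dosage == k), dtype=np.float32) for k in (0, 1, 2)]
    theta_obs = _theta_from_split(
        dosage, np.arange(len(grouped)) < n_low
    )

    exceed = np.zeros(m, dtype=np.int64)
    tied = np.zeros(m, dtype=np.int64)
    valid = np.zeros(m, dtype=np.int64)
    pooled_exceed = np.zeros(m, dtype=np.int64)
    pooled_valid = 0
    done = 0
    while done < n_iterations:
        b = min(batch_size, n_iterations - done)
        picks = np.empty((b, len(grouped)), dtype=np.float32)
        for i in range(b):
            perm = rng.permutation(len(grouped))
            row = np.zeros(len(grouped), dtype=np.float32)
            row[perm[:n_low]] = 1.0
            picks[i] = row
        counts_low = np.stack([picks @ ik for ik in ind], axis=2)  # (b, m, 3)
        totals = np.stack([ik.sum(axis=0) for ik in ind], axis=1)  # (m, 3)
        counts_high = totals[None, :, :] - counts_low
        _, _, _, theta_perm = wc_components_from_counts(
            counts_low.reshape(-1, 3), counts_high.reshape(-1, 3)
        )
        theta_perm = theta_perm.reshape(b, m)
        ok = ~np.isnan(theta_perm)
        with np.errstate(invalid="ignore"):
            gt = ok & (theta_perm > theta_obs[None, :] + _TIE_TOL)
            eq = ok & (np.abs(theta_perm - theta_obs[None, :]) <= _TIE_TOL)
        exceed += gt.sum(axis=0)
        tied += eq.sum(axis=0)
        valid += ok.sum(axis=0)
        if pooled:
            flat = theta_perm[ok]
            pooled_valid += flat.size
            srt = np.sort(flat)
            pooled_exceed += flat.size - np.searchsorted(
                srt, np.where(np.isnan(theta_obs), np.inf, theta_obs), side="left"
            )
        done += b

    if ties == "random":
        share = np.random.default_rng((seed, 0x7135)).random(m)
    elif ties == "midp":
        share = np.full(m, 0.5)
    else:
        share = np.ones(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        if pooled:
            p = (1 + pooled_exceed) / (pooled_valid + 1)
        else:
            p = (1 + exceed + share * tied) / (valid + 1)
    p = np.asarray(p, dtype=float)
    p[np.isnan(theta_obs)] = np.nan
    p[valid == 0] = np.nan
    return p


def _theta_from_split(dosage: np.ndarray, is_low: np.ndarray) -> np.ndarray:
    from .fst import genotype_counts

    c_low = genotype_counts(dosage[is_low, :])
    c_high = genotype_counts(dosage[~is_low, :])
    return wc_components_from_counts(c_low, c_high)[3]


def genomic_inflation_factor(pvalues: np.ndarray) -> float:
    """Genomic inflation factor lambda from a vector of p-values.

    Each p maps to the 1-df chi-square quantile q = Q(1-p); lambda is
    median(q) divided by the null chi-square median 0.4549.  Returns 0
    (flagged) when every p equals 1.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 10:
        raise ValueError("need >=10 p-values to estimate lambda")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = chi2.isf(p, df=1)
    lam = float(np.median(q) / CHI2_1_MEDIAN)
    if lam == 0:
        log.warning("all p-values equal 1; lambda degenerate at 0")
    return lam


def genomic_control_adjust(pvalues: np.ndarray, lambda_gc: float) -> np.ndarray:
    """Deflate p-values by the genomic inflation factor.

    q = Q_{chi2,1}(1-p) is divided by lambda and mapped back through the
    chi-square survival function; output is clipped into (0, 1].  Rank
    order is preserved; lambda = 1 is the identity.
    """
    if lambda_gc <= 0:
        raise ValueError("lambda must be positive")
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = chi2.isf(p[ok], df=1)
    adj = chi2.sf(q / lambda_gc, df=1)
    out[ok] = np.clip(adj, np.nextafter(0, 1), 1.0)
    return out


def run_permutation_null(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    n_iterations: int = 10_000,
    seed: int = 0,
    pooled: bool = False,
    ties: str = "random",
) -> PermutationResult:
    """Permutation p-values -> lambda -> genomic-control adjustment."""
    perm_p = permutation_pvalues(
        g, groups, n_iterations=n_iterations, seed=seed, pooled=pooled, ties=ties
    )
    lam = genomic_inflation_factor(perm_p)
    adjusted = genomic_control_adjust(perm_p, lam) if lam > 0 else perm_p.copy()
    return PermutationResult(
        n_iterations=n_iterations,
        seed=seed,
        perm_p=perm_p,
        lambda_gc=lam,
        gc_adjusted_p=adjusted,
    )
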