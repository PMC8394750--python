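"""Per-SNP Weir-Cockerham F_ST between two divergent groups.

theta is the ratio a/(a+b+c) of the among-group (a), among-individual-
within-group (b) and within-individual (c) variance components, computed
per SNP from the two groups' genotype counts.  theta may be negative (a
finite-sample property of the estimator) and is missing when the
components sum to zero (both groups monomorphic for the same allele).
Z(F_ST) standardises theta by the scan-wide mean and standard deviation;
the selection rule keeps the top fraction of Z values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grouping import GroupAssignment
from .types import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WcComponents:
    """Variance components of the two-population Weir-Cockerham estimator."""

    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else np.nan


@dataclass
class ScanResult:
    """Per-SNP scan statistics plus the standardisation and selection state."""

    variants: pd.DataFrame
    maf: np.ndarray
    theta: np.ndarray
    z_fst: np.ndarray
    selected: np.ndarray  # bool
    mu_fst: float
    sigma_fst: float
    cutoff_z: float
    top_fraction: float

    def to_frame(self) -> pd.DataFrame:
        out = self.variants[["snp_id", "rs_id", "chrom", "pos"]].copy()
        out = out.rename(columns={"chrom": "chr"})
        out["maf"] = self.maf
        out["theta"] = self.theta
        out["z_fst"] = self.z_fst
        out["selected"] = self.selected
        return out


def genotype_counts(dosage: np.ndarray) -> np.ndarray:
    """(n_samples, m) dosages -> (m, 3) counts of genotypes 0/1/2."""
    return np.stack([(dosage == k).sum(axis=0) for k in (0, 1, 2)], axis=1)


def wc_components_from_counts(c1: np.ndarray, c2: np.ndarray):
    """Vectorised Weir-Cockerham components for two groups of genotype counts.

    ``c1``, ``c2``: (m, 3) arrays of genotype counts (hom-a, het, hom-b).
    Returns (a, b, c, theta) float arrays of length m; entries are NaN for
    SNPs where either group has fewer than 2 called genotypes or where the
    component sum vanishes.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n1 = c1.sum(axis=1)
    n2 = c2.sum(axis=1)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (c1[:, 1] + 2 * c1[:, 2]) / (2 * n1)
        p2 = (c2[:, 1] + 2 * c2[:, 2]) / (2 * n2)
        h1 = c1[:, 1] / n1
        h2 = c2[:, 1] / n2
        r = 2.0
        nbar = (n1 + n2) / r
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    for arr in (a, b, c, theta):
        arr[~valid] = np.nan
    return a, b, c, theta


def wc_theta(group1_counts, group2_counts) -> WcComponents:
    """Weir-Cockerham components for one SNP from two genotype-count triples."""
    c1 = np.asarray(group1_counts, dtype=float)[None, :]
    c2 = np.asarray(group2_counts, dtype=float)[None, :]
    if c1.sum() < 2 or c2.sum() < 2:
        raise ValueError("each group needs >=2 called genotypes")
    a, b, c, _ = wc_components_from_counts(c1, c2)
    return WcComponents(float(a[0]), float(b[0]), float(c[0]))


def scan_fst(g: GenotypeMatrix, groups: GroupAssignment) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham components between the LOW and HIGH groups.

    Missing dosages are dropped per group per SNP; SNPs with fewer than 2
    called genotypes in either group get missing components.
    """
    if g.n_snps == 0:
        raise ValueError("no SNPs to scan")
    low = g.dosage[groups.low_indices, :]
    high = g.dosage[groups.high_indices, :]
    a, b, c, theta = wc_components_from_counts(
        genotype_counts(low), genotype_counts(high)
    )
    return pd.DataFrame({"a": a, "b": b, "c": c, "theta": theta})


def z_transform(thetas: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardise theta by the scan-wide mean and SD (n-1 denominator).

    Missing thetas stay missing and are excluded from mu and sigma.
    """
    thetas = np.asarray(thetas, dtype=float)
    ok = ~np.isnan(thetas)
    if ok.sum() < 2:
        raise ValueError("need >=2 non-missing theta values")
    mu = float(thetas[ok].mean())
    sigma = float(thetas[ok].std(ddof=1))
    if sigma <= 1e-13 * max(1.0, abs(mu)):
        raise ValueError("degenerate scan: zero theta variance")
    return (thetas - mu) / sigma, mu, sigma


def select_top_fraction(
    z: np.ndarray, fraction: float = 0.0005
) -> tuple[np.ndarray, float]:
    """Indices of the top ``fraction`` of Z values and the realised cutoff.

    k = floor(fraction * n_non_missing); every SNP with z >= the k-th
    largest value is selected, so ties at the cutoff are all included
    (logged when they push the count past k).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0,1)")
    z = np.asarray(z, dtype=float)
    ok = ~np.isnan(z)
    k = int(np.floor(fraction * ok.sum()))
    if k == 0:
        raise ValueError(
            f"top fraction {fraction} selects no SNPs at n={int(ok.sum())}; "
            "increase the fraction"
        )
    order = np.argsort(z[ok])[::-1]
    cutoff = float(z[ok][order[k - 1]])
    selected = np.flatnonzero(ok & (z >= cutoff))
    if len(selected) > k:
        log.info("%d SNPs tied at the Z cutoff (%d requested)", len(selected), k)
    return selected, cutoff


def run_scan(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    top_fraction: float = 0.0005,
    maf: np.ndarray | None = None,
) -> ScanResult:
    """Convenience wrapper: components -> Z transform -> top-fraction selection."""
    comps = scan_fst(g, groups)
    theta = comps["theta"].to_numpy()
    z, mu, sigma = z_transform(theta)
    sel_idx, cutoff = select_top_fraction(z, top_fraction)
    selected = np.zeros(g.n_snps, dtype=bool)
    selected[sel_idx] = True
    if maf is None:
        from .qc import snp_stats

        maf = snp_stats(g)["maf"].to_numpy()
    return ScanResult(
        variants=g.variants,
        maf=maf,
        theta=theta,
        z_fst=z,
        selected=selected,
        mu_fst=mu,
        sigma_fst=sigma,
        cutoff_z=cutoff,
        top_fraction=top_fraction,
    )
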