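"""Genomic relatedness and the QK mixed-model marker-trait association.

The genomic relationship matrix (GRM) follows VanRaden's first method:
centred dosages W = M - 2p scaled by 2*sum p_j (1-p_j).  Pairwise
relatedness (PI_HAT) uses the classic method-of-moments identity-by-
descent estimator from identity-by-state counts with unbiased allele-
frequency moment corrections.  The association model is

    y = X beta + u + e,   u ~ (0, K sigma_g^2),  e ~ (0, I sigma_e^2)

with fixed effects intercept + sex + SNP dosage.  Variance components are
estimated once per trait by REML (spectral decomposition of K, 1-D search
over the heritability ratio) without any candidate SNP and re-used for
every marker test (P3D/EMMAX style); each SNP then gets a generalized
least squares Wald t-test on its dosage coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .types import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its scaling denominator."""

    matrix: np.ndarray
    sample_ids: list
    denominator: float


def vanraden_grm(g: GenotypeMatrix, min_snps: int = 10) -> GRM:
    """VanRaden method-1 GRM: W W' / (2 sum p_j(1-p_j)), p from the sample.

    Missing dosages are replaced by twice the allele frequency (zero after
    centring).  Monomorphic SNPs carry no information and are skipped; an
    all-monomorphic input raises.
    """
    if g.n_samples < 2 or g.n_snps < min_snps:
        raise ValueError(f"need >=2 samples and >={min_snps} SNPs for a GRM")
    d = np.where(g.dosage == MISSING, np.nan, g.dosage.astype(float))
    p = np.nanmean(d, axis=0) / 2
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; GRM undefined")
    d = d[:, poly]
    p = p[poly]
    w = np.where(np.isnan(d), 0.0, d - 2 * p)
    denom = float(2 * np.sum(p * (1 - p)))
    k = (w @ w.T) / denom
    return GRM(matrix=k, sample_ids=list(g.samples["sample_id"]), denominator=denom)


def _unbiased_moment(x: np.ndarray, a: int, y: np.ndarray, b: int, t: np.ndarray):
    """Unbiased estimator of p^a q^b from allele counts x (of B) and y (of A).

    Falling-factorial (hypergeometric) correction: ff(x,a) ff(y,b) / ff(t,a+b)
    with t = x + y total alleles.  Removes the finite-sample bias of
    plugging sample frequencies into the IBS expectations.
    """
    num = np.ones_like(t, dtype=float)
    for i in range(a):
        num *= x - i
    for i in range(b):
        num *= y - i
    den = np.ones_like(t, dtype=float)
    for i in range(a + b):
        den *= t - i
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, np.maximum(num, 0.0) / den, np.nan)


def pairwise_ibd(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Method-of-moments IBD sharing (PLINK convention) for all sample pairs.

    Observed identity-by-state counts per pair are compared with their
    expectations under IBD states 0/1/2 given sample allele frequencies;
    the resulting P(IBD=0,1,2) are truncated to [0,1] and renormalised.
    Returns the symmetric PI_HAT = P(IBD=2) + P(IBD=1)/2 matrix (diagonal
    1) and the mean over unordered pairs.
    """
    n, m = g.n_samples, g.n_snps
    if n < 2:
        raise ValueError("need >=2 samples for pairwise IBD")
    d = np.where(g.dosage == MISSING, np.nan, g.dosage.astype(float))
    called = 2 * np.sum(~np.isnan(d), axis=0).astype(float)
    x = np.nansum(d, axis=0)  # allele-b count
    y = called - x
    poly = (x > 0) & (y > 0)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; IBD undefined")
    d = d[:, poly]
    x, y, t = x[poly], y[poly], called[poly]

    # per-SNP expected IBS probabilities conditional on IBD state
    p2q2 = _unbiased_moment(x, 2, y, 2, t)
    p3q = _unbiased_moment(x, 3, y, 1, t)
    pq3 = _unbiased_moment(x, 1, y, 3, t)
    p4 = _unbiased_moment(x, 4, y, 0, t)
    q4 = _unbiased_moment(x, 0, y, 4, t)
    p2q = _unbiased_moment(x, 2, y, 1, t)
    pq2 = _unbiased_moment(x, 1, y, 2, t)
    p3 = _unbiased_moment(x, 3, y, 0, t)
    q3 = _unbiased_moment(x, 0, y, 3, t)
    e_ibs0_ibd0 = 2 * p2q2
    e_ibs1_ibd0 = 4 * p3q + 4 * pq3
    e_ibs2_ibd0 = p4 + q4 + 4 * p2q2
    e_ibs1_ibd1 = 2 * p2q + 2 * pq2
    e_ibs2_ibd1 = p3 + q3 + p2q + pq2

    pi_hat = np.eye(n)
    total = 0.0
    for i, j in combinations(range(n), 2):
        both = ~(np.isnan(d[i, :]) | np.isnan(d[j, :]))
        if both.sum() < 10:
            pi_hat[i, j] = pi_hat[j, i] = np.nan
            continue
        diff = np.abs(d[i, both] - d[j, both])
        n_ibs0 = float((diff == 2).sum())
        n_ibs1 = float((diff == 1).sum())
        n_ibs2 = float((diff == 0).sum())
        s00 = np.nansum(e_ibs0_ibd0[both])
        s10 = np.nansum(e_ibs1_ibd0[both])
        s20 = np.nansum(e_ibs2_ibd0[both])
        s11 = np.nansum(e_ibs1_ibd1[both])
        s21 = np.nansum(e_ibs2_ibd1[both])
        n_used = float(both.sum())
        p0 = n_ibs0 / s00 if s00 > 0 else 0.0
        p1 = (n_ibs1 - p0 * s10) / s11 if s11 > 0 else 0.0
        p2 = (n_ibs2 - p0 * s20 - p1 * s21) / n_used
        z = np.clip([p0, p1, p2], 0.0, 1.0)
        z = z / z.sum() if z.sum() > 0 else np.array([1.0, 0.0, 0.0])
        val = z[2] + z[1] / 2
        pi_hat[i, j] = pi_hat[j, i] = val
        total += val
    n_pairs = n * (n - 1) // 2
    return pi_hat, total / n_pairs


# ---------------------------------------------------------------------------
# REML variance components (EMMA-style spectral method)
# ---------------------------------------------------------------------------

def _reml_negloglik(h: float, s: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    """Negative profiled REML log-likelihood at heritability ratio h.

    V is parameterised as sigma_p^2 (h K + (1-h) I); rotating by the
    eigenvectors of K makes V diagonal with weights d = h s + (1-h), and
    sigma_p^2 profiles out in closed form.
    """
    n, p = xr.shape
    d = h * s + (1 - h)
    if np.any(d <= 0):
        return np.inf
    w = 1.0 / d
    xtwx = xr.T @ (w[:, None] * xr)
    try:
        beta = np.linalg.solve(xtwx, xr.T @ (w * yr))
    except np.linalg.LinAlgError:
        return np.inf
    resid = yr - xr @ beta
    rss = float(np.sum(w * resid**2))
    nf = n - p
    sigma2 = rss / nf
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0 or sigma2 <= 0:
        return np.inf
    return 0.5 * (nf * (np.log(sigma2) + 1) + np.sum(np.log(d)) + logdet_xtwx)


def reml_variance_components(
    y: np.ndarray, X: np.ndarray, K: np.ndarray
) -> tuple[float, float]:
    """REML estimates of (sigma_g^2, sigma_e^2) for y = X beta + u + e.

    One eigendecomposition of K followed by a 1-D search over the
    heritability ratio h = sigma_g^2 / (sigma_g^2 + sigma_e^2) of the
    profiled REML likelihood; both components are returned non-negative.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n or K.shape != (n, n):
        raise ValueError("y, X and K dimensions disagree")
    if n <= p + 1:
        raise ValueError("too few samples for the fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design is rank deficient")
    s, u = eigh(K)
    s = np.maximum(s, 0.0)
    yr = u.T @ y
    xr = u.T @ X

    grid = np.linspace(0.0, 0.999, 41)
    vals = [_reml_negloglik(h, s, yr, xr) for h in grid]
    if not np.isfinite(vals).any():
        raise ValueError("REML likelihood non-finite everywhere; check K and y")
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo < hi:
        res = minimize_scalar(
            _reml_negloglik, args=(s, yr, xr), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        h = float(res.x) if res.fun <= vals[i] else float(grid[i])
    else:
        h = float(grid[i])

    d = h * s + (1 - h)
    w = 1.0 / d
    xtwx = xr.T @ (w[:, None] * xr)
    beta = np.linalg.solve(xtwx, xr.T @ (w * yr))
    resid = yr - xr @ beta
    sigma_p2 = float(np.sum(w * resid**2) / (n - p))
    return h * sigma_p2, (1 - h) * sigma_p2


def _gls_wald(y, X, V, test_col: int) -> tuple[float, float, float]:
    """GLS fit under covariance structure V; Wald t-test on ``test_col``.

    V fixes the correlation structure; the residual scale is re-estimated
    from the generalized residuals (s^2 = r' V^-1 r / (n - p)), so with
    V = I the test reduces exactly to the OLS t-test.  Returns (beta, se,
    two-sided p) with df = n - n_fixed.
    """
    n, p = X.shape
    c, low = cho_factor(V, lower=True)
    vy = cho_solve((c, low), y)
    vx = cho_solve((c, low), X)
    xtvx = X.T @ vx
    xtvy = X.T @ vy
    xtvx_inv = np.linalg.inv(xtvx)
    beta = xtvx_inv @ xtvy
    resid = y - X @ beta
    s2 = float(resid @ cho_solve((c, low), resid)) / (n - p)
    se = float(np.sqrt(max(s2, 0.0) * xtvx_inv[test_col, test_col]))
    if se == 0:
        return float(beta[test_col]), np.finfo(float).tiny, np.finfo(float).tiny
    t = beta[test_col] / se
    pval = float(2 * sps.t.sf(abs(t), df=n - p))
    return float(beta[test_col]), se, max(pval, np.finfo(float).tiny)


def snp_association(
    g: GenotypeMatrix,
    y: np.ndarray,
    sex: pd.Series | np.ndarray,
    K: GRM | np.ndarray,
    snp_ids: list[str],
    variance_components: tuple[float, float] | None = None,
    refit_per_snp: bool = False,
) -> pd.DataFrame:
    """Mixed-model association of each listed SNP with trait y.

    Fixed effects: intercept + sex + additive dosage.  Variance
    components default to one REML fit of the no-SNP model, reused for
    every marker (``refit_per_snp=True`` re-estimates them per SNP).
    Samples with missing trait, sex or dosage are dropped per test.
    Monomorphic SNPs yield a record with missing beta/se/p.
    """
    kmat = K.matrix if isinstance(K, GRM) else np.asarray(K)
    y = np.asarray(y, dtype=float)
    sex_num = pd.Series(sex).map({"male": 1.0, "female": 0.0}).to_numpy()
    base_ok = ~np.isnan(y) & ~np.isnan(sex_num)

    if variance_components is None and not refit_per_snp:
        idx = np.flatnonzero(base_ok)
        x0 = np.column_stack([np.ones(len(idx)), sex_num[idx]])
        variance_components = reml_variance_components(
            y[idx], x0, kmat[np.ix_(idx, idx)]
        )
        log.info(
            "REML variance components: sigma_g2=%.4g sigma_e2=%.4g",
            *variance_components,
        )

    id_to_col = {sid: j for j, sid in enumerate(g.variants["snp_id"])}
    records = []
    for sid in snp_ids:
        if sid not in id_to_col:
            raise KeyError(f"SNP {sid!r} not present in the genotype matrix")
        j = id_to_col[sid]
        dose = g.dosage[:, j].astype(float)
        dose[dose == MISSING] = np.nan
        ok = base_ok & ~np.isnan(dose)
        idx = np.flatnonzero(ok)
        rec = {"snp_id": sid, "n_used": len(idx)}
        if len(idx) < 4 or np.var(dose[idx]) == 0:
            log.info("SNP %s monomorphic or underpowered; no test", sid)
            rec.update(beta=np.nan, se=np.nan, p=np.nan,
                       sigma_g2=np.nan, sigma_e2=np.nan)
            records.append(rec)
            continue
        X = np.column_stack([np.ones(len(idx)), sex_num[idx], dose[idx]])
        ksub = kmat[np.ix_(idx, idx)]
        if refit_per_snp:
            sg2, se2 = reml_variance_components(y[idx], X, ksub)
        else:
            sg2, se2 = variance_components
        V = sg2 * ksub + se2 * np.eye(len(idx))
        if sg2 == 0 and se2 == 0:
            raise ValueError("degenerate variance components (both zero)")
        beta, se_b, pval = _gls_wald(y[idx], X, V, test_col=2)
        rec.update(beta=beta, se=se_b, p=pval, sigma_g2=sg2, sigma_e2=se2)
        records.append(rec)
    return pd.DataFrame.from_records(records)
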