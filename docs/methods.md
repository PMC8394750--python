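# Methods

This note records the models behind each stage, the parameters that
matter, the numerical choices made where conventions differ, and what
the synthetic cohorts do and do not emulate.

## Study design

The scan targets a single population split into LOW and HIGH subsets of
one quantitative trait. Under polygenic inheritance, truncating on the
phenotype shifts allele frequencies at trait loci between the subsets,
so a between-group fixation index behaves like a selection-signature
statistic: most SNPs drift around θ ≈ 0, trait-associated SNPs stand
out. Because the two "populations" are arbitrary halves of one cohort,
an empirical (permutation) null and a relatedness-aware confirmation
model are integral parts of the design rather than optional add-ons.

## Quality control

Stage order: non-autosomal and unnamed SNPs → sample call rate → SNP
call rate → MAF → exact HWE → LD pruning. Per-SNP statistics are
recomputed after sample removal, and the cascade is idempotent.

- Removal conditions are **strict** inequalities (call rate < 0.90 /
  < 0.98, MAF < 0.05, HWE p < 10⁻⁶, r² > 0.5): a marker sitting exactly
  on a threshold is retained.
- The HWE test is the exact conditional test: all heterozygote counts
  compatible with the observed allele counts (same parity) are
  enumerated, their probabilities P(h | n_A, n) ∝ 2ʰ n!/(n_AA! h! n_BB!)
  computed in log space via `gammaln`, and the p-value sums the
  configurations no more probable than the observed one (with a 1e-12
  relative guard on the equality comparison). Verified against an
  exact-rational enumeration to 1e-12 for totals up to 200.
- LD pruning is PLINK-style greedy: 50-SNP windows per chromosome,
  advanced by 5 SNPs (PLINK's common step; the window size is standard,
  the step is our choice and is configurable). Within a window, while
  any retained pair has r² > 0.5 the lower-MAF member is dropped (tie:
  the later SNP). r² is the squared Pearson correlation of dosages
  (composite LD), with pairwise deletion of missing calls; a
  zero-variance vector yields r² = 0 so it never triggers pruning.
- Missing genotypes are handled by per-SNP / pairwise deletion
  throughout; there is no imputation.

## Weir–Cockerham θ and Z(F_ST)

For two groups (r = 2) with sizes n_i, allele-B frequencies p_i and
observed heterozygosities h_i:

    n̄ = Σn_i/r          p̄ = Σn_i p_i/(r n̄)      h̄ = Σn_i h_i/(r n̄)
    s² = Σn_i(p_i−p̄)²/((r−1) n̄)
    n_c = (r n̄ − Σn_i²/(r n̄))/(r−1)
    a  = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b  = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c  = h̄/2
    θ̂  = a/(a+b+c)

This is the per-SNP ratio of components (not a multi-SNP ratio of
sums): the scan ranks individual SNPs. θ̂ may be negative; it is missing
when a + b + c = 0 (both groups monomorphic for the same allele) or a
group has fewer than two called genotypes. Missing-θ SNPs are excluded
from μ_FST, σ_FST and the selection denominator. σ_FST uses the n−1
denominator (immaterial at chip scale).

Selection keeps the k = ⌊fraction · n⌋ largest Z values (default
fraction 5×10⁻⁴, i.e. the 99.95th percentile); ties at the cutoff are
all included and logged. Note that under the null, θ̂ per SNP is
approximately a scaled and shifted χ²₁, so Z(F_ST) is right-skewed:
roughly 2% of null SNPs exceed Z = 3. Cutoffs must therefore come from
the empirical distribution, never from Gaussian tail intuition.

## Permutation null, λ and genomic control

Each iteration shuffles LOW/HIGH labels among the grouped animals only
(excluded animals never enter), preserving group sizes, and recomputes
θ for every SNP; the one-sided upper-tail p-value uses the
never-zero finite-sample form p = (1 + #exceedances)/(m + 1).

**Tie handling.** At cohort-scale group sizes θ is a coarse function of
the label split, and the estimator is invariant under swapping the two
groups, so a fifth to a quarter of permuted draws tie exactly with the
observed value. Counting ties as exceedances makes the null p-values
strongly super-uniform (measured λ ≈ 0.42 at 30+30), which would wreck
the downstream λ estimate. The default policy is therefore seeded
randomized tie-splitting, p = (1 + #{>} + U·#{=})/(m + 1) with one
U ~ Uniform(0,1) per SNP drawn from a dedicated stream: under
exchangeability this p is exactly uniform (measured λ ≈ 0.99,
KS D ≈ 0.01), and the whole table is bit-reproducible given the seed.
Deterministic mid-p (`ties="midp"`) and the conservative tie-inclusive
count (`ties="upper"`) are available.

λ maps each p to a 1-df chi-square quantile and divides the median by
0.4549 (the χ²₁ median); genomic control divides the quantiles by λ and
maps back, which preserves rank order and is the identity at λ = 1.
λ is computed from all scanned SNPs, not only selected ones. The
per-SNP null is the default; a pooled (all-SNP) null is available
behind a flag for comparison.

## Mixed-model association

Model: y = Xβ + u + e with u ~ (0, K σ²_g), e ~ (0, I σ²_e); fixed
effects are intercept, sex (two levels) and the SNP's additive dosage.

- **GRM**: VanRaden method 1, W = M − 2p (missing → 0 after centring),
  K = WW′/(2Σp_j(1−p_j)), p estimated from the sample. Centring with
  sample frequencies makes row sums ≈ 0, so unrelated cohorts show a
  structural mean off-diagonal of −mean(diag)/(n−1) ≈ −1/(n−1); tests
  assert that value rather than zero.
- **REML**: one eigendecomposition K = USU′, then a 1-D search over the
  heritability ratio h = σ²_g/(σ²_g+σ²_e) ∈ [0, 0.999] of the profiled
  REML log-likelihood (coarse grid then bounded Brent), with the total
  variance profiled out in closed form. Both components are returned
  non-negative; with K = I the ratio is unidentified and the total
  equals the OLS residual variance.
- **Per-SNP test**: variance components are estimated once per trait
  from the no-SNP model and reused for every marker (P3D/EMMAX
  practice; `refit_per_snp=True` re-estimates). V = σ²_g K + σ²_e I
  fixes the correlation structure; the residual scale is re-estimated
  from the generalized residuals, so at σ²_g = 0 the Wald t equals the
  OLS t exactly. df = n − p_fixed. Samples missing trait, sex or dosage
  are dropped per test; monomorphic SNPs yield missing records. By
  default all QC-passing phenotyped animals are tested, not only the
  grouped subset (switchable).
- **Identifiability caveat**: the sampling SE of ĥ² is ≈ √(2/Σ_{i≠j}
  K²_ij). For an unrelated chip cohort (K ≈ I + noise) this is ~0.5 at
  n = 200 — the ratio is effectively unidentified, which is expected
  behaviour, not a defect. Calibration tests therefore use
  family-structured kinships where the bound is meaningful; the Wald
  test itself is calibrated regardless (type-I error ≈ 5%).
- **PI_HAT**: method-of-moments IBD from IBS counts, with unbiased
  falling-factorial estimators of the allele-frequency monomials
  (the finite-sample correction of the classic PLINK estimator);
  P(IBD = 0,1,2) are truncated to [0,1] and renormalised.

## Candidate regions

Windows are SNP-centred, [max(1, pos − 1 Mb), pos + 1 Mb] (half-width
configurable); overlapping windows are not merged — one row per
selected SNP, so two nearby hits each keep their own window. Gene
overlap is inclusive interval intersection on 1-based coordinates
(BED's 0-based half-open converted on read); a gene touching the window
edge is included. *Positional* = gene span contains the anchor SNP
(distance 0); *flanking* = elsewhere in the window, distance measured
from the anchor to the nearest gene edge. Functional-vs-other gene
labels are a literature judgment and out of scope: the tool reports
geometry only.

## Synthetic cohorts

Defaults mirror the target system: 140 lambs (55 male / 85 female,
configurable), ~50k SNPs spread evenly over 26 autosomes at 50 kb
spacing, base allele frequencies Uniform(0.05, 0.5), birth weight
3.7 ± 0.5 kg, heritability 0.2 (the literature range for early growth
in this breed), sex effect +0.3 trait-SD for males (a typical lamb
dimorphism).

Phenotype model: y = μ + sex·σ_y + Σ_j β_j(d_j − 2p_j)σ_y + g + e,
where g is a polygenic term built from all non-QTL SNPs rescaled to
exactly h²σ²_y, and the residual fills the remaining variance
σ²_y(1 − h² − v_QTL); an infeasible budget raises. Two generation
modes exist because the analysis needs both: phenotype-driven extremes
for end-to-end tests (grouping induces divergence at trait loci) and
direct frequency divergence (LOW at p − δ/2, HIGH at p + δ/2) for clean
F_ST calibration. Planted base frequencies are drawn from the part of
the MAF range that keeps both group frequencies in [0.01, 0.99]; an
empty feasible range raises. Optional LD uses a latent-gamete Gaussian
AR(1) copula within blocks (adjacent-pair r² increases monotonically
with the block correlation); an optional parent-offspring generator
(one transmitted gamete) supports the relatedness tests.

Not emulated: coalescent-realistic LD decay, genotyping batch effects,
pedigree structure beyond parent-offspring pairs, and ascertainment
bias of chip SNPs. Passing tests therefore demonstrate correctness of
the statistical machinery under its stated assumptions, not robustness
to every artefact of real chip data.

## Problem sizes used in tests and the acceptance script

Calibration runs use 5,000 SNPs with 30+30 animals and 1,000
permutations; planted-signal recovery uses 10 loci at δ = 0.45 among
5,000 null SNPs over 20 replicates; mixed-model calibration uses 1,000
null trials and 200 coverage trials at n = 60 with a 5,000-SNP GRM.
These sizes give stable stochastic bounds (binomial SEs of a few
percent) while keeping the whole suite fast on one CPU.

## Known limitations

- The permutation engine recomputes θ from genotype-count matmuls; at
  10,000 iterations × 40k SNPs it processes in batches of 128 to bound
  memory (~tens of MB per batch).
- The exact HWE test loops per SNP in Python (~µs per SNP at chip
  scale); fine for 50K arrays, not tuned for sequencing-scale input.
- Genomic control assumes a one-parameter (scale) miscalibration of the
  χ² quantiles; structure beyond that (e.g. cryptic family clusters)
  is better handled by the mixed model stage.
- REML uses a single random effect; dominance, maternal or litter
  effects are out of scope.
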