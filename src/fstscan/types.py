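"""Core in-memory containers shared across the pipeline.

Genotypes live in a single :class:`GenotypeMatrix`: a samples x SNPs dosage
matrix (counts of allele_b, ``MISSING`` = -1) plus two aligned metadata
frames.  Variants are kept sorted by (chromosome, position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Dosage code for a missing genotype call.
MISSING: int = -1

#: Columns required in the variant metadata frame.
VARIANT_COLUMNS = ["snp_id", "rs_id", "chrom", "pos", "allele_a", "allele_b"]

#: Columns required in the sample metadata frame.
SAMPLE_COLUMNS = ["sample_id", "sex", "birth_weight", "weaning_weight"]

#: Autosome labels accepted for the ovine genome.
AUTOSOMES = frozenset(str(i) for i in range(1, 27))


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(ValueError):
    """Inconsistent sizes or contents across companion files."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with aligned metadata.

    Parameters
    ----------
    dosage
        ``(n_samples, n_snps)`` int8 array counting copies of ``allele_b``
        per genotype; ``MISSING`` (-1) marks a failed call.
    variants
        One row per SNP with columns :data:`VARIANT_COLUMNS`; ``chrom`` is a
        string autosome label ("1".."26"), ``pos`` a 1-based coordinate.
    samples
        One row per sample with columns :data:`SAMPLE_COLUMNS`; weights are
        kg (NaN = not recorded), ``sex`` is "male"/"female".
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D samples x SNPs array")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise IntegrityError(
                f"{len(self.samples)} sample records for {n} dosage rows"
            )
        if len(self.variants) != m:
            raise IntegrityError(
                f"{len(self.variants)} variant records for {m} dosage columns"
            )
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise IntegrityError(f"variants frame lacks column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise IntegrityError(f"samples frame lacks column {col!r}")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise IntegrityError(
                f"{int(bad.sum())} dosage entries outside {{0,1,2,MISSING}}"
            )
        if self.samples["sample_id"].duplicated().any():
            raise IntegrityError("duplicate sample_id in cohort")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def is_sorted(self) -> bool:
        """True if variants are ordered by (chromosome, position)."""
        key = list(zip(self.variants["chrom"].astype(int), self.variants["pos"]))
        return key == sorted(key)

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with variants ordered by (chromosome, position)."""
        order = np.lexsort(
            (self.variants["pos"].to_numpy(), self.variants["chrom"].astype(int).to_numpy())
        )
        return self.take(snp_indices=order)

    def take(self, sample_indices=None, snp_indices=None) -> "GenotypeMatrix":
        """Subset samples and/or SNPs by positional index, preserving order."""
        d = self.dosage
        v = self.variants
        s = self.samples
        if sample_indices is not None:
            sample_indices = np.asarray(sample_indices)
            d = d[sample_indices, :]
            s = s.iloc[sample_indices]
        if snp_indices is not None:
            snp_indices = np.asarray(snp_indices)
            d = d[:, snp_indices]
            v = v.iloc[snp_indices]
        return GenotypeMatrix(d.copy(), v.reset_index(drop=True), s.reset_index(drop=True))


@dataclass
class QCReport:
    """Audit trail of the quality-control cascade."""

    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    removed_by_stage: dict = field(default_factory=dict)

    #: Fixed execution order of the filtering stages.
    STAGE_ORDER = (
        "non_autosomal",
        "no_rs_id",
        "sample_call_rate",
        "snp_call_rate",
        "maf",
        "hwe",
        "ld_prune",
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s, "removed": self.removed_by_stage.get(s, 0)}
            for s in self.STAGE_ORDER
        ]
        return pd.DataFrame(rows)
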