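"""Readers and writers for the formats the pipeline touches.

PLINK 1 binary (bed/bim/fam, SNP-major), a plain dosage-TSV fallback,
phenotype tables, GFF3/BED gene annotations, and the TSV/BED result files.
All coordinates are held 1-based inclusive in memory; BED's 0-based
half-open convention is converted on read/write.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AUTOSOMES,
    MISSING,
    FormatError,
    GenotypeMatrix,
    IntegrityError,
)

log = logging.getLogger(__name__)

def _ext(prefix: Path, ext: str) -> Path:
    """prefix + extension without mangling dots inside the prefix name."""
    return prefix.with_name(prefix.name + ext)


_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK code -> dosage (count of allele_b / .bim A2):
# 00 hom A1 -> 0, 01 missing, 10 het -> 1, 11 hom A2 -> 2
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}

_RS_PATTERN = re.compile(r"^rs\d+$")


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 fileset ``prefix``.bed/.bim/.fam into a GenotypeMatrix.

    Dosage counts copies of the .bim A2 allele.  SNPs on non-autosomal
    chromosome codes (outside "1".."26") are dropped with a logged count.
    Sample order follows .fam, SNP order follows .bim.
    """
    prefix = Path(prefix)
    bim = _read_bim(_ext(prefix, ".bim"))
    fam = _read_fam(_ext(prefix, ".fam"))
    if len(fam) == 0:
        raise FormatError(f"{prefix}.fam: no samples")
    if len(bim) == 0:
        raise FormatError(f"{prefix}.bim: no variants")

    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    raw = _ext(prefix, ".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if len(raw) < 3 or raw[2] != _SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: not SNP-major (mode byte {raw[2:3]!r})")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise IntegrityError(
            f"{prefix}.bed: {body.size} body bytes, expected {m * bytes_per_snp} "
            f"for {n} samples x {m} SNPs"
        )
    codes = _unpack_codes(body.reshape(m, bytes_per_snp), n)  # (m, n)
    dosage = _CODE_TO_DOSAGE[codes].T  # (n, m)

    autosomal = bim["chrom"].isin(AUTOSOMES).to_numpy()
    n_dropped = int((~autosomal).sum())
    if n_dropped:
        log.info("dropping %d non-autosomal SNPs on read", n_dropped)
        dosage = dosage[:, autosomal]
        bim = bim.loc[autosomal].reset_index(drop=True)
    return GenotypeMatrix(dosage, bim, fam)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK 1 SNP-major bed/bim/fam fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = g.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "snp_id": v["snp_id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["allele_a"],
            "a2": v["allele_b"],
        }
    )
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)

    sex_code = g.samples["sex"].map({"male": 1, "female": 2}).fillna(0).astype(int)
    fam = pd.DataFrame(
        {
            "fid": g.samples["sample_id"],
            "iid": g.samples["sample_id"],
            "father": 0,
            "mother": 0,
            "sex": sex_code,
            "pheno": -9,
        }
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)

    n, m = g.n_samples, g.n_snps
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, n), dtype=np.uint8)
    d = g.dosage.T  # (m, n)
    for dose, code in _DOSAGE_TO_CODE.items():
        codes[d == dose] = code
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())


def _unpack_codes(body: np.ndarray, n_samples: int) -> np.ndarray:
    """(m, bytes_per_snp) packed bytes -> (m, n_samples) 2-bit codes."""
    m = body.shape[0]
    out = np.empty((m, body.shape[1] * 4), dtype=np.uint8)
    out[:, 0::4] = body & 0b11
    out[:, 1::4] = (body >> 2) & 0b11
    out[:, 2::4] = (body >> 4) & 0b11
    out[:, 3::4] = (body >> 6) & 0b11
    return out[:, :n_samples]


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    rs = bim["snp_id"].where(bim["snp_id"].str.match(_RS_PATTERN), other=pd.NA)
    return pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "rs_id": rs,
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "allele_a": bim["a1"],
            "allele_b": bim["a2"],
        }
    )


def _read_fam(path: Path) -> pd.DataFrame:
    try:
        fam = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["fid", "iid", "father", "mother", "sex", "pheno"],
            dtype={"iid": str},
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no samples") from None
    sex = fam["sex"].map({1: "male", 2: "female"})
    return pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "sex": sex,
            "birth_weight": np.nan,
            "weaning_weight": np.nan,
        }
    )


# ---------------------------------------------------------------------------
# ped/map conversion and dosage-TSV fallback
# ---------------------------------------------------------------------------

def convert_ped_to_bed(prefix_in: str | Path, prefix_out: str | Path) -> None:
    """One-shot conversion of a text ped/map fileset to PLINK 1 binary.

    The ped alleles at each SNP are oriented so that dosage counts the
    second allele listed in lexicographic order (A1 = first seen minor
    convention is not reproduced; orientation is irrelevant downstream).
    """
    prefix_in, prefix_out = Path(prefix_in), Path(prefix_out)
    mp = pd.read_csv(
        _ext(prefix_in, ".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    rows = []
    ids, sexes = [], []
    for line in _ext(prefix_in, ".ped").read_text().splitlines():
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * len(mp):
            raise IntegrityError(
                f"ped row for {f[1] if len(f) > 1 else '?'} has {len(f)} fields, "
                f"expected {6 + 2 * len(mp)}"
            )
        ids.append(f[1])
        sexes.append({"1": "male", "2": "female"}.get(f[4]))
        rows.append(f[6:])
    if not rows:
        raise FormatError(f"{prefix_in}.ped: no samples")
    alleles = np.array(rows).reshape(len(rows), len(mp), 2)

    dosage = np.full((len(rows), len(mp)), MISSING, dtype=np.int8)
    a_ref, b_ref = [], []
    for j in range(len(mp)):
        obs = alleles[:, j, :]
        seen = sorted(set(obs.ravel()) - {"0"})
        if len(seen) > 2:
            raise FormatError(f"SNP {mp['snp_id'][j]}: >2 alleles {seen}")
        a = seen[0] if seen else "0"
        b = seen[1] if len(seen) > 1 else "0"
        called = (obs != "0").all(axis=1)
        dosage[called, j] = (obs[called] == b).sum(axis=1)
        a_ref.append(a)
        b_ref.append(b)

    variants = pd.DataFrame(
        {
            "snp_id": mp["snp_id"],
            "rs_id": mp["snp_id"].where(mp["snp_id"].str.match(_RS_PATTERN), pd.NA),
            "chrom": mp["chrom"],
            "pos": mp["pos"].astype(np.int64),
            "allele_a": a_ref,
            "allele_b": b_ref,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "sex": sexes,
            "birth_weight": np.nan,
            "weaning_weight": np.nan,
        }
    )
    write_plink(GenotypeMatrix(dosage, variants, samples), prefix_out)


def read_dosage_tsv(dosage_path: str | Path, variants_path: str | Path) -> GenotypeMatrix:
    """Fallback reader: a wide samples x SNPs dosage table plus a variant table.

    ``dosage_path``: TSV with a ``sample_id`` column then one column per SNP
    holding 0/1/2 or empty for missing.  ``variants_path``: TSV with columns
    snp_id, chrom, pos, allele_a, allele_b and optionally rs_id.
    """
    wide = pd.read_csv(dosage_path, sep="\t", dtype={"sample_id": str})
    var = pd.read_csv(variants_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    snp_cols = [c for c in wide.columns if c != "sample_id"]
    if list(var["snp_id"]) != snp_cols:
        raise IntegrityError("variant table SNP order does not match dosage columns")
    if "rs_id" not in var.columns:
        var = var.assign(
            rs_id=var["snp_id"].where(var["snp_id"].str.match(_RS_PATTERN), pd.NA)
        )
    dosage = wide[snp_cols].to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    variants = var[["snp_id", "rs_id", "chrom", "pos", "allele_a", "allele_b"]].copy()
    variants["pos"] = variants["pos"].astype(np.int64)
    samples = pd.DataFrame(
        {
            "sample_id": wide["sample_id"],
            "sex": pd.NA,
            "birth_weight": np.nan,
            "weaning_weight": np.nan,
        }
    )
    return GenotypeMatrix(dosage, variants, samples)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype TSV (sample_id, sex, birth_weight, weaning_weight).

    Extra columns are ignored; missing weight cells become NaN; duplicate
    sample ids or unparseable weights raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "sex", "birth_weight", "weaning_weight"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    sex = df["sex"].str.strip().str.lower().map(_SEX_ALIASES)
    bad_sex = df.loc[sex.isna() & df["sex"].notna(), "sex"]
    if len(bad_sex):
        raise FormatError(f"{path}: unrecognised sex value {bad_sex.iloc[0]!r}")

    def parse_weight(col: str) -> pd.Series:
        raw = df[col].str.strip() if df[col].dtype == object else df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() & raw.notna() & (raw != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise FormatError(f"{path}: unparseable {col} at line {row}")
        if (out <= 0).any():
            row = int(np.flatnonzero(out <= 0)[0]) + 2
            raise FormatError(f"{path}: non-positive {col} at line {row}")
        return out

    return pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "sex": sex,
            "birth_weight": parse_weight("birth_weight"),
            "weaning_weight": parse_weight("weaning_weight"),
        }
    )


def attach_phenotypes(g: GenotypeMatrix, phen: pd.DataFrame) -> GenotypeMatrix:
    """Merge a phenotype table into the cohort by sample_id.

    The phenotype table's sex overrides the .fam sex on conflict (warned).
    Samples absent from the table keep NaN weights.
    """
    merged = g.samples[["sample_id"]].merge(phen, on="sample_id", how="left")
    fam_sex = g.samples["sex"]
    conflict = merged["sex"].notna() & fam_sex.notna() & (merged["sex"] != fam_sex)
    if conflict.any():
        ids = g.samples.loc[conflict, "sample_id"].tolist()
        log.warning("phenotype sex overrides .fam sex for samples %s", ids)
    merged["sex"] = merged["sex"].where(merged["sex"].notna(), fam_sex)
    return GenotypeMatrix(g.dosage, g.variants, merged)


# ---------------------------------------------------------------------------
# Gene annotation (GFF3 or BED)
# ---------------------------------------------------------------------------

_GFF_NAME_KEYS = ("Name", "gene_name", "gene_id", "ID")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene records from a GFF3 or BED file.

    Returns a frame with columns gene_name, chrom, start_bp, end_bp, strand,
    coordinates 1-based inclusive (BED's 0-based half-open is converted).
    Format is chosen by extension, falling back to content sniffing.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        genes = _read_gff3(path)
    elif suffix == ".bed":
        genes = _read_bed_genes(path)
    else:
        text = path.read_text()
        genes = _read_gff3(path) if "##gff" in text or "\tgene\t" in text else _read_bed_genes(path)
    if len(genes) == 0:
        raise FormatError(f"{path}: no gene records")
    return genes.reset_index(drop=True)


def _read_gff3(path: Path) -> pd.DataFrame:
    rows = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        name = next((attrs[k] for k in _GFF_NAME_KEYS if k in attrs), None)
        if name is None:
            continue
        rows.append(
            {
                "gene_name": name,
                "chrom": f[0],
                "start_bp": int(f[3]),
                "end_bp": int(f[4]),
                "strand": f[6] if f[6] in "+-" else "unknown",
            }
        )
    return pd.DataFrame(rows, columns=["gene_name", "chrom", "start_bp", "end_bp", "strand"])


def _read_bed_genes(path: Path) -> pd.DataFrame:
    rows = []
    for line in path.read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise FormatError(f"{path}: BED gene records need >=4 columns")
        rows.append(
            {
                "gene_name": f[3],
                "chrom": f[0],
                "start_bp": int(f[1]) + 1,  # 0-based half-open -> 1-based incl.
                "end_bp": int(f[2]),
                "strand": f[5] if len(f) > 5 and f[5] in "+-" else "unknown",
            }
        )
    return pd.DataFrame(rows, columns=["gene_name", "chrom", "start_bp", "end_bp", "strand"])


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

SCAN_TABLE_COLUMNS = [
    "snp_id",
    "rs_id",
    "chr",
    "pos",
    "maf",
    "theta",
    "z_fst",
    "selected",
    "perm_p",
    "gc_adjusted_p",
    "assoc_p",
]


def write_scan_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-SNP scan table TSV with the canonical column set."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty scan table")
    out = table.copy()
    for col in SCAN_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out[SCAN_TABLE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def write_regions_bed(regions, path: str | Path) -> None:
    """Write candidate regions as BED (0-based half-open).

    Name = anchor rs id (snp id if no rs id); score = anchor Z(F_ST) scaled
    to [0, 1000] and clipped.  An empty region list yields an empty file.
    """
    lines = []
    for r in regions:
        score = int(np.clip(round(r.z_fst * 100), 0, 1000))
        name = r.rs_id if r.rs_id else r.snp_id
        lines.append(
            f"{r.chrom}\t{r.window_start_bp - 1}\t{r.window_end_bp}\t{name}\t{score}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))
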