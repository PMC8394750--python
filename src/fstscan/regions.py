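"""Candidate regions around selected SNPs and gene classification.

Each selected SNP anchors a window of +/- 1 Mb (configurable half-width),
left-clipped at position 1.  Genes from the annotation that intersect the
window (1-based inclusive intervals) are attached and classified as
positional (the gene span contains the anchor SNP) or flanking (anywhere
else in the window, with the bp distance from the anchor to the nearest
gene edge).  Overlapping windows are deliberately not merged: one region
per selected SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

POSITIONAL, FLANKING = "positional", "flanking"

DEFAULT_HALF_WIDTH = 1_000_000


@dataclass
class CandidateRegion:
    """A selected SNP's window and the genes overlapping it."""

    snp_id: str
    rs_id: str | None
    chrom: str
    pos: int
    z_fst: float
    window_start_bp: int
    window_end_bp: int
    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_name", "class", "distance_bp"]
        )
    )


def build_windows(
    selected: pd.DataFrame, half_width: int = DEFAULT_HALF_WIDTH
) -> list[CandidateRegion]:
    """One window per selected SNP: [max(1, pos - half_width), pos + half_width].

    ``selected`` needs columns snp_id, rs_id, chrom, pos, z_fst.
    """
    if len(selected) == 0:
        raise ValueError("no selected SNPs to build windows around")
    regions = []
    for row in selected.itertuples(index=False):
        pos = int(row.pos)
        regions.append(
            CandidateRegion(
                snp_id=row.snp_id,
                rs_id=None if pd.isna(row.rs_id) else row.rs_id,
                chrom=str(row.chrom),
                pos=pos,
                z_fst=float(row.z_fst),
                window_start_bp=max(1, pos - half_width),
                window_end_bp=pos + half_width,
            )
        )
    return regions


def classify_genes(
    regions: list[CandidateRegion], annotation: pd.DataFrame
) -> list[CandidateRegion]:
    """Attach window-overlapping genes to each region, positional first.

    Overlap is inclusive interval intersection; a gene touching the window
    edge is included.  Genes are sorted by distance then name, so output
    is independent of annotation record order.
    """
    ann = annotation.copy()
    ann["chrom"] = ann["chrom"].astype(str)
    for region in regions:
        on_chrom = ann[ann["chrom"] == region.chrom]
        if len(on_chrom) == 0:
            log.warning(
                "no annotation on chromosome %s for region at %d",
                region.chrom,
                region.pos,
            )
            continue
        hit = on_chrom[
            (on_chrom["end_bp"] >= region.window_start_bp)
            & (on_chrom["start_bp"] <= region.window_end_bp)
        ]
        rows = []
        for gene in hit.itertuples(index=False):
            if gene.start_bp <= region.pos <= gene.end_bp:
                rows.append((gene.gene_name, POSITIONAL, 0))
            else:
                dist = (
                    gene.start_bp - region.pos
                    if gene.start_bp > region.pos
                    else region.pos - gene.end_bp
                )
                rows.append((gene.gene_name, FLANKING, int(dist)))
        genes = pd.DataFrame(rows, columns=["gene_name", "class", "distance_bp"])
        region.genes = genes.sort_values(
            ["distance_bp", "gene_name"], kind="stable"
        ).reset_index(drop=True)
    return regions


def regions_table(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Flatten regions to one row per (region, gene); gene-less regions kept."""
    rows = []
    for r in regions:
        base = {
            "snp_id": r.snp_id,
            "rs_id": r.rs_id,
            "chr": r.chrom,
            "pos": r.pos,
            "z_fst": r.z_fst,
            "window_start": r.window_start_bp,
            "window_end": r.window_end_bp,
        }
        if len(r.genes) == 0:
            rows.append({**base, "gene_name": None, "class": None, "distance_bp": None})
        else:
            for gene in r.genes.to_dict("records"):
                rows.append({**base, **gene})
    return pd.DataFrame(rows)
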