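"""End-to-end orchestration of the divergent-group selection scan.

``run_full_scan`` wires the stages together: read genotypes and
phenotypes -> QC -> extreme-group assignment (gated on the group t-test)
-> per-SNP Weir-Cockerham theta -> Z(F_ST) and top-fraction selection ->
permutation null, inflation factor lambda and genomic control ->
mixed-model association of the selected SNPs -> 2 Mb candidate regions.
Every table is written to the output directory and a JSON manifest
records the configuration, seed, lambda and cutoff so a run can be
replayed exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as gio
from .association import snp_association, vanraden_grm
from .fst import ScanResult, run_scan
from .grouping import assign_extreme_groups
from .permutation import run_permutation_null
from .qc import QCThresholds, apply_qc
from .regions import build_windows, classify_genes, regions_table
from .types import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Structured configuration of a full scan (YAML-loadable)."""

    genotypes: str = ""
    phenotypes: str = ""
    annotation: str = ""
    output_dir: str = "fstscan_out"
    trait: str = "birth_weight"
    low_threshold: float | None = None
    high_threshold: float | None = None
    low_quantile: float | None = None
    high_quantile: float | None = None
    group_t_gate_p: float = 0.05
    top_fraction: float = 0.0005
    n_iterations: int = 10_000
    region_half_width: int = 1_000_000
    seed: int = 0
    welch: bool = False
    pooled_null: bool = False
    perm_ties: str = "random"
    refit_per_snp: bool = False
    associate_grouped_only: bool = False
    qc: QCThresholds = field(default_factory=QCThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_raw = raw.pop("qc", {})
        return cls(**raw, qc=QCThresholds(**qc_raw))


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # surface the failing stage by name
        raise StageError(name, exc) from exc


def run_full_scan(cfg: RunConfig, cohort: GenotypeMatrix | None = None) -> dict:
    """Execute the whole pipeline and return the run manifest.

    ``cohort`` may be passed directly (e.g. a simulated GenotypeMatrix
    with phenotypes attached) to skip file input.  If a stage fails, the
    tables already written are renamed with a ``.partial`` suffix and a
    :class:`StageError` naming the stage is raised.
    """
    written: list[Path] = []
    try:
        return _run_full_scan(cfg, cohort, written)
    except StageError:
        for path in written:
            if path.exists():
                path.rename(path.with_name(path.name + ".partial"))
        raise


def _run_full_scan(
    cfg: RunConfig, cohort: GenotypeMatrix | None, written: list[Path]
) -> dict:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "fstscan_version": __version__,
        "config": _jsonable(asdict(cfg)),
        "stages": [],
    }

    if cohort is None:
        g = _stage("read_genotypes", gio.read_plink, cfg.genotypes)
        if cfg.phenotypes:
            phen = _stage("read_phenotypes", gio.read_phenotypes, cfg.phenotypes)
            g = gio.attach_phenotypes(g, phen)
    else:
        g = cohort
    manifest["stages"].append("read")
    manifest["n_samples_raw"], manifest["n_snps_raw"] = g.n_samples, g.n_snps

    g, report = _stage("qc", apply_qc, g, cfg.qc)
    report_frame = report.to_frame()
    report_frame.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    written.append(outdir / "qc_report.tsv")
    written.append(outdir / "qc_report.json")
    (outdir / "qc_report.json").write_text(
        json.dumps(
            {
                "n_samples_in": report.n_samples_in,
                "n_samples_out": report.n_samples_out,
                "n_snps_in": report.n_snps_in,
                "n_snps_out": report.n_snps_out,
                "removed_by_stage": report.removed_by_stage,
            },
            indent=2,
        )
    )
    manifest["stages"].append("qc")
    manifest["n_samples_qc"], manifest["n_snps_qc"] = g.n_samples, g.n_snps

    groups = _stage(
        "grouping",
        assign_extreme_groups,
        g.samples,
        cfg.trait,
        low_threshold=cfg.low_threshold,
        high_threshold=cfg.high_threshold,
        low_quantile=cfg.low_quantile,
        high_quantile=cfg.high_quantile,
        welch=cfg.welch,
    )
    if groups.t_p_value > cfg.group_t_gate_p:
        raise StageError(
            "grouping",
            ValueError(
                f"groups not separated: t-test p={groups.t_p_value:.3g} > "
                f"{cfg.group_t_gate_p}"
            ),
        )
    manifest["stages"].append("grouping")
    manifest["groups"] = {
        "trait": cfg.trait,
        "n_low": groups.n_low,
        "n_high": groups.n_high,
        "t_statistic": groups.t_statistic,
        "t_p_value": groups.t_p_value,
    }

    scan = _stage("fst_scan", run_scan, g, groups, cfg.top_fraction)
    manifest["stages"].append("fst_scan")
    manifest["cutoff_z"] = round(scan.cutoff_z, 2)
    manifest["n_selected"] = int(scan.selected.sum())

    perm = _stage(
        "permutation",
        run_permutation_null,
        g,
        groups,
        n_iterations=cfg.n_iterations,
        seed=cfg.seed,
        pooled=cfg.pooled_null,
        ties=cfg.perm_ties,
    )
    manifest["stages"].append("permutation")
    manifest["lambda_gc"] = perm.lambda_gc
    manifest["permutation_seed"] = cfg.seed
    perm_table = pd.DataFrame(
        {
            "snp_id": g.variants["snp_id"],
            "theta": scan.theta,
            "perm_p": perm.perm_p,
            "gc_adjusted_p": perm.gc_adjusted_p,
        }
    )
    perm_table.to_csv(outdir / "permutation.tsv", sep="\t", index=False, na_rep="NA")
    written.append(outdir / "permutation.tsv")

    selected_ids = g.variants.loc[scan.selected, "snp_id"].tolist()
    if cfg.associate_grouped_only:
        keep = (groups.labels != "EXCLUDED").to_numpy()
        g_assoc = g.take(sample_indices=np.flatnonzero(keep))
    else:
        g_assoc = g
    grm = _stage("grm", vanraden_grm, g_assoc)
    y = g_assoc.samples[cfg.trait].to_numpy(dtype=float)
    assoc = _stage(
        "association",
        snp_association,
        g_assoc,
        y,
        g_assoc.samples["sex"],
        grm,
        selected_ids,
        refit_per_snp=cfg.refit_per_snp,
    )
    assoc.to_csv(outdir / "association.tsv", sep="\t", index=False, na_rep="NA")
    written.append(outdir / "association.tsv")
    manifest["stages"].append("association")
    if len(assoc) and assoc["sigma_g2"].notna().any():
        first = assoc.loc[assoc["sigma_g2"].notna()].iloc[0]
        manifest["sigma_g2"] = float(first["sigma_g2"])
        manifest["sigma_e2"] = float(first["sigma_e2"])

    scan_table = scan.to_frame()
    scan_table["perm_p"] = perm.perm_p
    scan_table["gc_adjusted_p"] = perm.gc_adjusted_p
    scan_table = scan_table.merge(
        assoc[["snp_id", "p"]].rename(columns={"p": "assoc_p"}), on="snp_id", how="left"
    )
    gio.write_scan_table(scan_table, outdir / "scan.tsv")
    written.append(outdir / "scan.tsv")

    selected_frame = (
        scan_table.loc[scan_table["selected"]]
        .rename(columns={"chr": "chrom"})
        .reset_index(drop=True)
    )
    regions = _stage("regions", build_windows, selected_frame, cfg.region_half_width)
    if cfg.annotation:
        annotation = _stage("read_annotation", gio.read_gene_annotation, cfg.annotation)
        regions = _stage("regions", classify_genes, regions, annotation)
    regions_table(regions).to_csv(
        outdir / "regions.tsv", sep="\t", index=False, na_rep="NA"
    )
    written.append(outdir / "regions.tsv")
    gio.write_regions_bed(regions, outdir / "regions.bed")
    written.append(outdir / "regions.bed")
    manifest["stages"].append("regions")

    manhattan = manhattan_table(scan)
    manhattan.to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
    manifest["stages"].append("manhattan")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def manhattan_table(scan: ScanResult) -> pd.DataFrame:
    """Per-SNP plotting table with genome-wide cumulative positions.

    Chromosomes are laid end to end: each chromosome's positions are
    offset by the summed maximum positions of all preceding chromosomes.
    """
    if len(scan.variants) == 0:
        raise ValueError("empty scan")
    chrom = scan.variants["chrom"].astype(int).to_numpy()
    pos = scan.variants["pos"].to_numpy()
    offset = {}
    running = 0
    for c in sorted(set(chrom)):
        offset[c] = running
        running += int(pos[chrom == c].max())
    cumulative = pos + np.array([offset[c] for c in chrom])
    return pd.DataFrame(
        {
            "chr": chrom,
            "pos": pos,
            "cumulative_pos": cumulative,
            "z_fst": scan.z_fst,
            "selected": scan.selected,
        }
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
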