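"""End-to-end composition: assign -> catalog -> ORFs -> classify -> quantify
-> project, with a machine-readable run log."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .assign import apply_assignments, assign_transcripts, assignment_table
from .catalog import CatalogParams, catalog_gene, promoter_count, summarize_cohort
from .classify import (
    build_architecture,
    classify_gene,
    classify_isoform,
    flags_table,
    start_residue_in_reference,
    summarize_flags,
)
from .expression import (
    ExpressionMatrix,
    aggregate_by_tissue,
    transcript_fractions,
)
from .io import (
    read_abundance,
    read_bed,
    read_domains,
    read_fasta,
    read_gtf,
    read_metadata,
    read_variants,
    write_fasta,
)
from .model import GeneModel, IsocatError, group_into_genes
from .orf import call_orfs, select_reference_isoform
from .variants import (
    affected_transcript_set,
    capture_gaps,
    project_variant,
    projection_table,
)


class PipelineError(IsocatError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Input paths and thresholds for one pipeline run."""

    merged_gtf: Path
    annotation_gtf: Path
    genome_fasta: Path
    abundance_tsv: Path
    metadata_tsv: Path
    outdir: Path
    domains_tsv: Optional[Path] = None
    variants_path: Optional[Path] = None
    capture_bed: Optional[Path] = None
    tss_tolerance_bp: int = 50
    tes_tolerance_bp: int = 50
    expressed_tpm: float = 0.5
    novel_prefix: str = "NSTRG"
    chimeric_min_bases: int = 1
    strand_aware: bool = True
    correlation_method: str = "pearson"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        paths = {
            k: Path(v)
            for k, v in raw.items()
            if k.endswith(("_gtf", "_fasta", "_tsv", "_bed", "_path"))
            or k == "outdir"
        }
        rest = {k: v for k, v in raw.items() if k not in paths}
        return cls(**paths, **rest)


def load_and_assign(
    merged_gtf,
    annotation_gtf,
    novel_prefix: str = "NSTRG",
    strand_aware: bool = True,
    chimeric_min_bases: int = 1,
):
    """Read both GTFs and attach novel transcripts to annotated genes.

    Returns (merged transcripts with gene names applied, gene models,
    assignment results).
    """
    try:
        merged = read_gtf(merged_gtf, novel_prefix=novel_prefix)
        annotation = read_gtf(annotation_gtf, novel_prefix=novel_prefix)
    except IsocatError as exc:
        raise PipelineError("load", str(exc)) from exc
    if not merged:
        raise PipelineError("load", "no transcripts in merged GTF")
    ann_genes = group_into_genes(annotation)
    if not ann_genes:
        raise PipelineError("load", "annotation carries no gene names")
    results = assign_transcripts(
        [t for t in merged if t.is_novel],
        ann_genes,
        strand_aware=strand_aware,
        chimeric_min_bases=chimeric_min_bases,
    )
    merged = apply_assignments(merged, results)
    return merged, group_into_genes(merged), results


def classify_stage(genes, orfs, domains, results) -> Tuple[pd.DataFrame, list]:
    """Per-isoform classifications and per-gene variability flags."""
    chimeric_by_gene: Dict[str, set] = {}
    for r in results:
        if r.chimeric and r.assigned_gene:
            chimeric_by_gene.setdefault(r.assigned_gene, set()).update(
                r.chimeric_partners - {r.assigned_gene}
            )
    class_rows = []
    gene_flags = []
    for gene in genes:
        ref_tid = select_reference_isoform(gene, orfs)
        if ref_tid is None:
            continue
        ref_orf = orfs[ref_tid]
        ref_arch = build_architecture(ref_tid, ref_orf.protein_length, domains)
        members = []
        for t in gene.transcripts:
            rec = orfs.get(t.transcript_id)
            if rec is None:
                continue
            arch = build_architecture(t.transcript_id, rec.protein_length, domains)
            cls = classify_isoform(
                arch,
                ref_arch,
                start_residue_in_ref=start_residue_in_reference(rec, ref_orf),
                protein=rec.protein,
                reference_protein=ref_orf.protein,
            )
            members.append((cls, arch, rec.protein))
            class_rows.append(
                {
                    "gene": gene.gene_name,
                    "transcript_id": t.transcript_id,
                    "category": cls.category,
                    "full_length_7tm": int(cls.full_length_7tm),
                    "soluble_n_terminus": int(cls.soluble_n_terminus),
                    "membrane_anchored_n_terminus": int(
                        cls.membrane_anchored_n_terminus
                    ),
                    "ctf_like": int(cls.ctf_like),
                    "c_term_variant_only": int(cls.c_term_variant_only),
                }
            )
        if members:
            gene_flags.append(
                classify_gene(
                    gene.gene_name,
                    members,
                    chimeric_by_gene.get(gene.gene_name, ()),
                )
            )
    return pd.DataFrame(class_rows), gene_flags


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Execute all stages and write the report bundle.

    Returns the mapping of report name to written path; raises
    :class:`PipelineError` naming the failing stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        written[name] = path

    # --- load & assign ----------------------------------------------------
    merged, genes, results = load_and_assign(
        config.merged_gtf,
        config.annotation_gtf,
        novel_prefix=config.novel_prefix,
        strand_aware=config.strand_aware,
        chimeric_min_bases=config.chimeric_min_bases,
    )
    try:
        genome = read_fasta(config.genome_fasta)
    except IsocatError as exc:
        raise PipelineError("load", str(exc)) from exc
    emit("assignment", assignment_table(results))

    # --- catalog ----------------------------------------------------------
    params = CatalogParams(config.tss_tolerance_bp, config.tes_tolerance_bp)
    catalogs = [catalog_gene(g, params) for g in genes]
    emit("exon_catalog", summarize_cohort(catalogs), index=True)

    # --- ORFs -------------------------------------------------------------
    try:
        orfs = call_orfs(merged, genome)
    except IsocatError as exc:
        raise PipelineError("orf", str(exc)) from exc
    write_fasta(
        {tid: rec.protein for tid, rec in sorted(orfs.items()) if rec.protein},
        out / "proteins.fa",
    )
    written["proteins"] = out / "proteins.fa"
    cds_rows = [
        {
            "transcript_id": tid,
            "orf_start": rec.orf_start,
            "orf_end": rec.orf_end,
            "has_stop": int(rec.has_stop),
            "protein_length": rec.protein_length,
            "cds_genomic": ";".join(
                f"{iv.chrom}:{iv.start}-{iv.end}" for iv in rec.cds_genomic
            ),
        }
        for tid, rec in sorted(orfs.items())
    ]
    emit("orfs", pd.DataFrame(cds_rows))

    # --- classify ---------------------------------------------------------
    if config.domains_tsv is not None:
        domains = read_domains(config.domains_tsv)
        class_df, gene_flags = classify_stage(genes, orfs, domains, results)
        emit("isoform_classes", class_df)
        emit("gene_flags", flags_table(gene_flags))
        emit(
            "flag_percentages",
            summarize_flags(gene_flags).rename("percent").round(1).to_frame(),
            index=True,
        )

    # --- quantify ---------------------------------------------------------
    records = read_abundance(config.abundance_tsv)
    metadata = read_metadata(config.metadata_tsv)
    gene_of = {
        t.transcript_id: t.gene_name for t in merged if t.gene_name is not None
    }
    matrix = ExpressionMatrix.from_records(records, metadata, gene_of)
    tissue_means = aggregate_by_tissue(matrix)
    emit("expression_long", transcript_fractions(tissue_means, gene_of))

    # --- project variants -------------------------------------------------
    if config.variants_path is not None:
        variants = read_variants(config.variants_path)
        projections = []
        affected_rows = []
        for v in variants:
            for gene in genes:
                if gene.transcripts[0].chrom != v.chrom:
                    continue
                res = project_variant(v, gene, orfs)
                classes = {p.location_class for p in res.projections}
                if classes == {"outside"}:
                    continue
                projections.append(res)
                affected_rows.append(
                    {
                        "variant": v.label,
                        "gene": gene.gene_name,
                        "affected_cds": ",".join(
                            sorted(affected_transcript_set(res, "cds"))
                        ),
                    }
                )
        if projections:
            emit("variant_projection", projection_table(projections), index=True)
            emit("variant_affected", pd.DataFrame(affected_rows))

    # --- capture gaps -----------------------------------------------------
    if config.capture_bed is not None:
        capture = read_bed(config.capture_bed)
        exons_by_gene = {
            g.gene_name: [e for t in g.transcripts for e in t.exons]
            for g in genes
        }
        report = capture_gaps(exons_by_gene, capture)
        gap_rows = [
            {
                "gene": ec.gene,
                "chrom": ec.exon.chrom,
                "exon_start": ec.exon.start,
                "exon_end": ec.exon.end,
                "covered_bp": ec.covered_bases,
                "uncovered_bp": ec.uncovered_bases,
                "uncovered": ";".join(f"{s}-{e}" for s, e in ec.uncovered),
            }
            for ec in report.exons
        ]
        emit("capture_gaps", pd.DataFrame(gap_rows))

    # --- run log ----------------------------------------------------------
    log = {
        "isocat_version": __version__,
        "python_version": platform.python_version(),
        "parameters": {
            "tss_tolerance_bp": config.tss_tolerance_bp,
            "tes_tolerance_bp": config.tes_tolerance_bp,
            "expressed_tpm": config.expressed_tpm,
            "novel_prefix": config.novel_prefix,
            "chimeric_min_bases": config.chimeric_min_bases,
            "strand_aware": config.strand_aware,
            "correlation_method": config.correlation_method,
        },
        "outputs": {name: path.name for name, path in written.items()},
    }
    with open(out / "run_log.json", "wt") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["run_log"] = out / "run_log.json"
    return written
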