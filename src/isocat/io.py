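"""Readers and writers for the external formats at the package boundary.

Coordinate bases are converted exactly once, here: GTF and VCF positions are
1-based inclusive on disk and 0-based half-open in memory; BED is already
0-based half-open.  All readers are gzip-transparent.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .model import (
    NOVEL_PREFIX,
    AbundanceRecord,
    DomainAnnotation,
    GenomicInterval,
    IsocatError,
    SampleMetadata,
    TranscriptModel,
    Variant,
)

PathLike = Union[str, Path]


class ParseError(IsocatError, ValueError):
    """An input file violates its format contract."""


def _open_text(path: PathLike) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(
    path: PathLike, novel_prefix: str = NOVEL_PREFIX
) -> List[TranscriptModel]:
    """Read transcript models from a GTF file (StringTie-merge dialect).

    Only ``exon`` features are used.  Each exon must carry a
    ``transcript_id`` attribute; ``gene_name`` (or ``ref_gene_name``) is kept
    when present.  Transcripts whose identifier starts with ``novel_prefix``
    are marked ``source="novel"``.

    Returns transcripts sorted by transcript_id, each with exons in
    ascending genomic order.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    gene_names: Dict[str, str] = {}
    order: List[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF "
                    f"columns, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                end = int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_attributes(fields[8])
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(
                    f"{path}: line {lineno}: exon feature lacks transcript_id"
                )
            try:
                interval = GenomicInterval(fields[0], start, end, fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append(interval)
            name = attrs.get("gene_name") or attrs.get("ref_gene_name")
            if name:
                gene_names.setdefault(tid, name)
    transcripts = [
        TranscriptModel(
            transcript_id=tid,
            exons=tuple(exons[tid]),
            source="novel" if tid.startswith(novel_prefix) else "annotated",
            gene_name=gene_names.get(tid),
        )
        for tid in sorted(order)
    ]
    return transcripts


def write_gtf(
    transcripts: Iterable[TranscriptModel], path: PathLike, source: str = "isocat"
) -> None:
    """Write exon features; the inverse of :func:`read_gtf` on the model."""
    with open(path, "wt") as fh:
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            for e in t.exons:
                attrs = f'transcript_id "{t.transcript_id}";'
                if t.gene_name:
                    attrs += f' gene_name "{t.gene_name}";'
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a FASTA file into a chrom -> uppercase sequence mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Dict[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read BED3+ records (already 0-based half-open)."""
    intervals: List[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >=3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(
    intervals: Iterable[Tuple[GenomicInterval, str]], path: PathLike
) -> None:
    """Write (interval, name) pairs as BED6."""
    with open(path, "wt") as fh:
        for iv, name in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Variants (VCF-lite or 3-column TSV)
# ---------------------------------------------------------------------------


def read_variants(path: PathLike) -> List[Variant]:
    """Read a variant list from VCF (positions, ref/alt; INFO ignored) or TSV.

    VCF positions are 1-based and converted; the TSV dialect has a header
    ``chrom  pos  label`` with 1-based positions to match common variant
    tables.
    """
    path = Path(path)
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    if name.endswith(".vcf"):
        return _read_vcf_lite(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "label": str})
    for col in ("chrom", "pos", "label"):
        if col not in df.columns:
            raise ParseError(f"{path}: variant TSV needs a {col!r} column")
    return [
        Variant(row.chrom, int(row.pos) - 1, row.label)
        for row in df.itertuples(index=False)
    ]


def _read_vcf_lite(path: PathLike) -> List[Variant]:
    variants: List[Variant] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(
                    f"{path}: line {lineno}: VCF record needs >=5 columns"
                )
            chrom, pos, vid, ref, alt = fields[:5]
            try:
                pos0 = int(pos) - 1
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad POS") from exc
            label = vid if vid not in (".", "") else f"{chrom}:{pos}{ref}>{alt}"
            variants.append(Variant(chrom, pos0, label, ref, alt))
    return variants


# ---------------------------------------------------------------------------
# Abundance and metadata tables
# ---------------------------------------------------------------------------


def read_abundance(
    path: PathLike, sample_id: Optional[str] = None
) -> List[AbundanceRecord]:
    """Read a TPM table with columns ``transcript_id``, ``tpm`` and
    optionally ``sample_id``.

    When the table lacks a sample column, ``sample_id`` (or the file stem)
    names the sample.  Negative TPM values are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "transcript_id" not in df.columns or "tpm" not in df.columns:
        raise ParseError(f"{path}: abundance TSV needs transcript_id and tpm columns")
    if "sample_id" not in df.columns:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        df["sample_id"] = sample_id or Path(stem).stem
    records = []
    for row in df.itertuples(index=False):
        tpm = float(row.tpm)
        if tpm < 0:
            raise ParseError(
                f"{path}: negative TPM {tpm} for {row.transcript_id}/{row.sample_id}"
            )
        records.append(AbundanceRecord(str(row.transcript_id), str(row.sample_id), tpm))
    return records


def read_metadata(path: PathLike) -> List[SampleMetadata]:
    """Read sample metadata (``sample_id``, ``tissue``); sample ids unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if "sample_id" not in df.columns or "tissue" not in df.columns:
        raise ParseError(f"{path}: metadata TSV needs sample_id and tissue columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    return [
        SampleMetadata(row.sample_id, row.tissue) for row in df.itertuples(index=False)
    ]


def read_domains(path: PathLike) -> List[DomainAnnotation]:
    """Read consumed protein-domain calls.

    Columns: ``transcript_id``, ``domain``, ``residue_start``,
    ``residue_end`` (1-based inclusive protein coordinates).
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    needed = ("transcript_id", "domain", "residue_start", "residue_end")
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"{path}: domain TSV needs a {col!r} column")
    return [
        DomainAnnotation(
            str(row.transcript_id),
            str(row.domain),
            int(row.residue_start),
            int(row.residue_end),
        )
        for row in df.itertuples(index=False)
    ]
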