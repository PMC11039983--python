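"""Projection of genomic variants onto transcript structures, and
exome-capture coverage gaps.

A point variant is located on every transcript of a gene: outside the
transcript span, intronic, or exonic — with exonic positions subdivided by
the transcript's ORF into 5' UTR, CDS and 3' UTR (strand-aware).  Within
the CDS the splice-aware coordinate map yields the nucleotide offset and
the 1-based codon (residue) index, so a nonsense variant can be placed on
each isoform it touches.  Transcripts whose exon sets skip the variant's
exon are unaffected, which is how identical genomic lesions can spare
specific isoforms.

Capture gaps compare assembled exons against an exome capture design:
capture intervals are merged and each exon is partitioned into covered and
uncovered sub-intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .assign import merge_intervals
from .model import GeneModel, GenomicInterval, TranscriptModel, Variant
from .orf import OrfRecord, genome_to_transcript

LOCATION_CLASSES = (
    "exonic_cds",
    "exonic_utr5",
    "exonic_utr3",
    "exonic_noncoding",
    "intronic",
    "outside",
)


@dataclass(frozen=True)
class TranscriptProjection:
    transcript_id: str
    location_class: str
    cds_offset: Optional[int] = None
    codon_index: Optional[int] = None


@dataclass(frozen=True)
class ProjectionResult:
    variant: Variant
    projections: Tuple[TranscriptProjection, ...]

    def by_transcript(self) -> Dict[str, TranscriptProjection]:
        return {p.transcript_id: p for p in self.projections}


def project_variant(
    variant: Variant,
    gene: GeneModel,
    orfs: Mapping[str, OrfRecord],
) -> ProjectionResult:
    """Locate one variant on every transcript of a gene.

    Each transcript receives exactly one location class.  Transcripts
    without an ORF (or unstranded) report exonic positions as
    ``exonic_noncoding``.
    """
    projections: List[TranscriptProjection] = []
    for t in gene.transcripts:
        projections.append(_project_one(variant, t, orfs.get(t.transcript_id)))
    return ProjectionResult(variant, tuple(projections))


def _project_one(
    variant: Variant, t: TranscriptModel, orf: Optional[OrfRecord]
) -> TranscriptProjection:
    tid = t.transcript_id
    if variant.chrom != t.chrom or not t.span.contains(variant.pos):
        return TranscriptProjection(tid, "outside")
    if not any(e.contains(variant.pos) for e in t.exons):
        return TranscriptProjection(tid, "intronic")
    if orf is None or not t.is_stranded:
        return TranscriptProjection(tid, "exonic_noncoding")
    tpos = genome_to_transcript(t, variant.pos)
    assert tpos is not None  # exonic by the check above
    if tpos < orf.orf_start:
        return TranscriptProjection(tid, "exonic_utr5")
    if tpos >= orf.orf_end:
        return TranscriptProjection(tid, "exonic_utr3")
    offset = tpos - orf.orf_start
    return TranscriptProjection(tid, "exonic_cds", offset, offset // 3 + 1)


def affected_transcript_set(
    result: ProjectionResult, rule: str = "cds"
) -> Set[str]:
    """Transcripts a variant affects under a rule.

    ``"cds"`` (default) selects transcripts where the variant falls in the
    coding sequence; ``"any-exonic"`` selects every exonic hit and is a
    superset of the default.
    """
    if rule == "cds":
        wanted = {"exonic_cds"}
    elif rule == "any-exonic":
        wanted = {"exonic_cds", "exonic_utr5", "exonic_utr3", "exonic_noncoding"}
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return {
        p.transcript_id for p in result.projections if p.location_class in wanted
    }


def projection_table(
    results: Sequence[ProjectionResult],
) -> pd.DataFrame:
    """Wide variant x transcript matrix of location classes."""
    rows = []
    for r in results:
        row: Dict[str, object] = {"variant": r.variant.label}
        for p in r.projections:
            row[p.transcript_id] = p.location_class
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant").sort_index(axis=1)


# ---------------------------------------------------------------------------
# exome-capture coverage gaps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonCoverage:
    gene: str
    exon: GenomicInterval
    covered: Tuple[Tuple[int, int], ...]
    uncovered: Tuple[Tuple[int, int], ...]

    @property
    def has_gap(self) -> bool:
        return len(self.uncovered) > 0

    @property
    def covered_bases(self) -> int:
        return sum(e - s for s, e in self.covered)

    @property
    def uncovered_bases(self) -> int:
        return sum(e - s for s, e in self.uncovered)


@dataclass(frozen=True)
class CaptureGapReport:
    exons: Tuple[ExonCoverage, ...]

    def gap_exon_counts(self) -> Dict[str, int]:
        """Per gene: number of exons with at least one uncovered base."""
        counts: Dict[str, int] = {}
        for ec in self.exons:
            counts.setdefault(ec.gene, 0)
            if ec.has_gap:
                counts[ec.gene] += 1
        return counts

    def gap_intervals(self) -> List[Tuple[str, GenomicInterval]]:
        out = []
        for ec in self.exons:
            for s, e in ec.uncovered:
                out.append((ec.gene, GenomicInterval(ec.exon.chrom, s, e, ec.exon.strand)))
        return out


def capture_gaps(
    exons_by_gene: Mapping[str, Iterable[GenomicInterval]],
    capture: Iterable[GenomicInterval],
) -> CaptureGapReport:
    """Partition each exon into capture-covered and uncovered sub-intervals.

    Capture intervals are merged per chromosome first, so overlapping BED
    records are tolerated.  For every exon, covered and uncovered intervals
    are disjoint and their lengths sum to the exon length.
    """
    merged: Dict[str, List[Tuple[int, int]]] = {}
    for iv in capture:
        merged.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {chrom: merge_intervals(ivs) for chrom, ivs in merged.items()}

    coverages: List[ExonCoverage] = []
    for gene in sorted(exons_by_gene):
        for exon in sorted(set(exons_by_gene[gene])):
            covered: List[Tuple[int, int]] = []
            for s, e in merged.get(exon.chrom, []):
                lo, hi = max(s, exon.start), min(e, exon.end)
                if lo < hi:
                    covered.append((lo, hi))
            uncovered: List[Tuple[int, int]] = []
            cursor = exon.start
            for s, e in covered:
                if cursor < s:
                    uncovered.append((cursor, s))
                cursor = e
            if cursor < exon.end:
                uncovered.append((cursor, exon.end))
            coverages.append(
                ExonCoverage(gene, exon, tuple(covered), tuple(uncovered))
            )
    return CaptureGapReport(tuple(coverages))
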