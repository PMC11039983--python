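"""Core domain types and coordinate conventions.

All in-memory coordinates are 0-based half-open intervals on a named
chromosome. External formats that use 1-based inclusive coordinates (GTF,
VCF) are converted exactly once, at the I/O boundary (:mod:`isocat.io`).

Exons of a transcript are kept in ascending genomic order regardless of
strand; 5'/3' semantics (TSS, donor/acceptor, first/last exon) are derived
from the strand at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

STRANDS = ("+", "-", ".")

#: identifier prefix marking transcripts absent from the reference annotation
NOVEL_PREFIX = "NSTRG"


class IsocatError(Exception):
    """Base class for all package errors."""


class CoordinateError(IsocatError, ValueError):
    """A genomic coordinate violates the interval conventions."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware ordered exon chain with provenance.

    ``source`` is ``"novel"`` for assembled transcripts whose identifier
    carries the novelty prefix (NSTRG by default) and ``"annotated"``
    otherwise.  Exons must share one chromosome and strand, be sorted by
    genomic position and be separated by introns of at least 1 bp.
    """

    transcript_id: str
    exons: Tuple[GenomicInterval, ...]
    source: str = "annotated"
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        if self.source not in ("annotated", "novel"):
            raise ValueError(f"invalid source {self.source!r}")
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise CoordinateError(
                f"{self.transcript_id}: exons must share one chromosome and strand"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise CoordinateError(
                    f"{self.transcript_id}: exons [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) overlap or abut (intron must be >=1 bp)"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def is_stranded(self) -> bool:
        return self.strand in ("+", "-")

    @property
    def is_novel(self) -> bool:
        return self.source == "novel"

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def first_exon(self) -> GenomicInterval:
        """5'-most exon (strand-aware); requires a stranded transcript."""
        self._require_strand()
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def last_exon(self) -> GenomicInterval:
        """3'-most exon (strand-aware)."""
        self._require_strand()
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def tss(self) -> int:
        """Transcription start position (0-based, strand-aware)."""
        e = self.first_exon()
        return e.start if self.strand == "+" else e.end - 1

    @property
    def tes(self) -> int:
        """Transcription end position (0-based, strand-aware)."""
        e = self.last_exon()
        return e.end - 1 if self.strand == "+" else e.start

    def _require_strand(self) -> None:
        if not self.is_stranded:
            raise CoordinateError(
                f"{self.transcript_id}: unstranded transcript has no 5'/3' semantics"
            )


@dataclass(frozen=True)
class GeneModel:
    """A named gene with its member transcripts."""

    gene_name: str
    transcripts: Tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.gene_name:
            raise ValueError("gene_name must be non-empty")
        if not self.transcripts:
            raise ValueError(f"{self.gene_name}: gene needs >=1 transcript")
        object.__setattr__(
            self,
            "transcripts",
            tuple(sorted(self.transcripts, key=lambda t: t.transcript_id)),
        )

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class AbundanceRecord:
    """One transcript's abundance in one sample, in transcripts per million."""

    transcript_id: str
    sample_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(
                f"{self.transcript_id}/{self.sample_id}: negative TPM {self.tpm}"
            )


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    tissue: str


@dataclass(frozen=True)
class Variant:
    """A point variant: 0-based genomic position plus a display label."""

    chrom: str
    pos: int
    label: str
    ref: Optional[str] = None
    alt: Optional[str] = None


@dataclass(frozen=True)
class DomainAnnotation:
    """A consumed protein-domain call in 1-based inclusive residue coordinates.

    Domain labels follow the conventions of upstream predictors: ``SP``
    (signal peptide), ``GAIN``, ``GPS``, ``PTX``, ``TM1`` .. ``TM7`` for the
    canonical seven-transmembrane bundle and ``extraTM`` for an additional
    N-terminal helix.
    """

    transcript_id: str
    domain_label: str
    residue_start: int
    residue_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.residue_start <= self.residue_end):
            raise ValueError(
                f"{self.transcript_id}/{self.domain_label}: invalid residue "
                f"interval {self.residue_start}-{self.residue_end}"
            )


def group_into_genes(
    transcripts: Sequence[TranscriptModel],
) -> Tuple[GeneModel, ...]:
    """Group transcripts carrying a gene_name into :class:`GeneModel` objects.

    Transcripts without a gene name are skipped (they are novel loci until
    assignment attaches them to a gene).
    """
    by_gene: dict = {}
    for t in transcripts:
        if t.gene_name:
            by_gene.setdefault(t.gene_name, []).append(t)
    return tuple(
        GeneModel(name, tuple(members)) for name, members in sorted(by_gene.items())
    )
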