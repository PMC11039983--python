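"""Spliced transcript sequences, longest-ORF calling and coordinate maps.

The longest open reading frame of each transcript is the longest span that
begins at an ATG and ends at the first in-frame stop codon; when no in-frame
stop occurs before the sequence end the open-ended span qualifies and is
flagged (``has_stop=False``), which keeps 3'-incomplete assemblies from
being dropped.  Length ties resolve to the 5'-most start.  Codons containing
N translate to X and never terminate the frame.

Coordinate maps run protein residue -> transcript nucleotide -> genomic
interval(s), splitting at splice junctions, so domains annotated in residue
space can be drawn on the genome and genomic variants located in codons.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .model import CoordinateError, GeneModel, GenomicInterval, TranscriptModel

_CODON_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; N-containing codons -> X.

    Trailing partial codons are ignored; stop codons are not represented.
    """
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            break
        protein.append(_CODON_TABLE.get(codon, "X"))
    return "".join(protein)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Exon sequences concatenated in genomic order; reverse-complemented as
    a whole on the minus strand.  Uppercase; N allowed."""
    if t.strand not in ("+", "-"):
        raise CoordinateError(
            f"{t.transcript_id}: cannot build a spliced sequence without strand"
        )
    if t.chrom not in genome:
        raise CoordinateError(f"{t.transcript_id}: unknown chromosome {t.chrom}")
    chrom_seq = genome[t.chrom]
    if t.exons[-1].end > len(chrom_seq):
        raise CoordinateError(
            f"{t.transcript_id}: exon end {t.exons[-1].end} beyond "
            f"{t.chrom} length {len(chrom_seq)}"
        )
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons).upper()
    return reverse_complement(seq) if t.strand == "-" else seq


@dataclass(frozen=True)
class OrfCall:
    """Result of the longest-ORF scan on a spliced sequence.

    ``orf_end`` includes the stop codon when ``has_stop``; the protein never
    includes a stop symbol.
    """

    orf_start: int
    orf_end: int
    has_stop: bool
    protein: str


def longest_orf(seq: str, require_stop: bool = False) -> Optional[OrfCall]:
    """Find the longest ATG-initiated reading frame in a transcript sequence.

    Returns ``None`` when the sequence contains no ATG (or, with
    ``require_stop``, no ORF with an in-frame stop).  Ties in protein length
    go to the 5'-most start codon.
    """
    seq = seq.upper()
    n = len(seq)
    starts = []
    stops_by_frame: List[List[int]] = [[], [], []]
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon == "ATG":
            starts.append(i)
        if codon in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    best: Optional[Tuple[int, int, int, bool]] = None  # (aa_len, -start, end, stop)
    for start in starts:
        frame_stops = stops_by_frame[start % 3]
        k = bisect_left(frame_stops, start)
        if k < len(frame_stops):
            stop = frame_stops[k]
            end, has_stop = stop + 3, True
            aa_len = (stop - start) // 3
        else:
            if require_stop:
                continue
            end, has_stop = start + 3 * ((n - start) // 3), False
            aa_len = (end - start) // 3
        key = (aa_len, -start)
        if best is None or key > best[:2]:
            best = (aa_len, -start, end, has_stop)
    if best is None:
        return None
    aa_len, neg_start, end, has_stop = best
    start = -neg_start
    coding = seq[start:end]
    return OrfCall(start, end, has_stop, translate(coding))


# ---------------------------------------------------------------------------
# transcript <-> genome coordinate maps (strand-aware)
# ---------------------------------------------------------------------------


def transcript_to_genome(
    t: TranscriptModel, tstart: int, tend: int
) -> List[GenomicInterval]:
    """Map a transcript-relative [tstart, tend) window to genomic intervals.

    Intervals are returned in transcript (5'->3') order; on the minus strand
    that is descending genomic order.
    """
    if not (0 <= tstart < tend <= t.exonic_length):
        raise CoordinateError(
            f"{t.transcript_id}: transcript window [{tstart},{tend}) out of "
            f"range 0..{t.exonic_length}"
        )
    exons = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    out: List[GenomicInterval] = []
    offset = 0
    for e in exons:
        lo = max(tstart - offset, 0)
        hi = min(tend - offset, len(e))
        if lo < hi:
            if t.strand == "+":
                out.append(GenomicInterval(e.chrom, e.start + lo, e.start + hi, "+"))
            else:
                out.append(GenomicInterval(e.chrom, e.end - hi, e.end - lo, "-"))
        offset += len(e)
        if offset >= tend:
            break
    return out


def genome_to_transcript(t: TranscriptModel, pos: int) -> Optional[int]:
    """Transcript-relative coordinate of a genomic position; None if intronic
    or outside."""
    exons = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    offset = 0
    for e in exons:
        if e.contains(pos):
            return offset + (pos - e.start if t.strand == "+" else e.end - 1 - pos)
        offset += len(e)
    return None


@dataclass(frozen=True)
class OrfRecord:
    """Longest ORF of one transcript with its genomic CDS map."""

    transcript_id: str
    orf_start: int
    orf_end: int
    has_stop: bool
    protein: str
    cds_genomic: Tuple[GenomicInterval, ...]

    @property
    def protein_length(self) -> int:
        return len(self.protein)


def call_orf(
    t: TranscriptModel, genome: Mapping[str, str], require_stop: bool = False
) -> Optional[OrfRecord]:
    """Longest ORF of a transcript, with the CDS projected onto the genome."""
    call = longest_orf(spliced_sequence(t, genome), require_stop=require_stop)
    if call is None:
        return None
    cds = transcript_to_genome(t, call.orf_start, call.orf_end)
    return OrfRecord(
        t.transcript_id,
        call.orf_start,
        call.orf_end,
        call.has_stop,
        call.protein,
        tuple(cds),
    )


def call_orfs(
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    require_stop: bool = False,
) -> Dict[str, OrfRecord]:
    """ORF records for all stranded transcripts, keyed by transcript_id."""
    orfs: Dict[str, OrfRecord] = {}
    for t in transcripts:
        if not t.is_stranded:
            continue
        rec = call_orf(t, genome, require_stop=require_stop)
        if rec is not None:
            orfs[t.transcript_id] = rec
    return orfs


def select_reference_isoform(
    gene: GeneModel, orfs: Mapping[str, OrfRecord]
) -> Optional[str]:
    """Transcript with the longest predicted protein; ties take the
    lexicographically smallest transcript_id."""
    candidates = [
        (orfs[t.transcript_id].protein_length, t.transcript_id)
        for t in gene.transcripts
        if t.transcript_id in orfs
    ]
    if not candidates:
        return None
    best = max(length for length, _ in candidates)
    return min(tid for length, tid in candidates if length == best)


def protein_to_genome(
    orf: OrfRecord, residue_start: int, residue_end: int
) -> List[GenomicInterval]:
    """Genomic intervals coding residues [residue_start, residue_end]
    (1-based inclusive), split at splice junctions.

    Total genomic length is exactly 3 x the residue count.
    """
    if not (1 <= residue_start <= residue_end <= orf.protein_length):
        raise CoordinateError(
            f"{orf.transcript_id}: residues {residue_start}-{residue_end} out "
            f"of range 1..{orf.protein_length}"
        )
    nt_lo = 3 * (residue_start - 1)
    nt_hi = 3 * residue_end
    out: List[GenomicInterval] = []
    offset = 0
    for piece in orf.cds_genomic:
        lo = max(nt_lo - offset, 0)
        hi = min(nt_hi - offset, len(piece))
        if lo < hi:
            if piece.strand == "-":
                out.append(
                    GenomicInterval(piece.chrom, piece.end - hi, piece.end - lo, "-")
                )
            else:
                out.append(
                    GenomicInterval(piece.chrom, piece.start + lo, piece.start + hi, "+")
                )
        offset += len(piece)
        if offset >= nt_hi:
            break
    return out


def cds_offset_of(orf: OrfRecord, pos: int) -> Optional[int]:
    """0-based nucleotide offset of a genomic position within the ORF, or
    None when the position does not fall in the coding intervals."""
    offset = 0
    for piece in orf.cds_genomic:
        if piece.contains(pos):
            within = pos - piece.start if piece.strand == "+" else piece.end - 1 - pos
            return offset + within
        offset += len(piece)
    return None
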