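"""Per-gene exon taxonomy: merged 5' start exons, internal exons, 3' end exons.

Exons are grouped by the splice sites that define them: a 5' start exon by
its donor site, a 3' end exon by its acceptor site, and an internal exon by
both.  Start exons sharing an identical donor whose transcription start
sites lie within a tolerance (default +/-50 bp) are merged into one class by
single-linkage clustering, so a chain of starts each within tolerance of the
next forms a single class; the number of start-exon classes estimates the
number of distinct promoters of the gene.  End exons are merged
symmetrically on (acceptor, transcription end site).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .model import GeneModel, GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class CatalogParams:
    """Merging tolerances for terminal-exon classes.

    ``single_exon_classes`` controls whether single-exon transcripts (which
    have neither donor nor acceptor) contribute TSS-only start classes and
    TES-only end classes, merged under the same tolerances.
    """

    tss_tolerance_bp: int = 50
    tes_tolerance_bp: int = 50
    single_exon_classes: bool = True

    def __post_init__(self) -> None:
        if self.tss_tolerance_bp < 0 or self.tes_tolerance_bp < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass(frozen=True)
class TerminalExonClass:
    """A merged class of first (or last) exons.

    ``anchor`` is the shared splice site defining the class: the donor for
    start exons, the acceptor for end exons; ``None`` for classes formed by
    single-exon transcripts.  ``positions`` are the member TSS (or TES)
    coordinates and ``span`` covers all member exons.
    """

    anchor: Optional[int]
    positions: Tuple[int, ...]
    members: Tuple[str, ...]
    span: GenomicInterval


@dataclass
class ExonCatalog:
    """The exon taxonomy of one gene."""

    gene_name: str
    start_classes: List[TerminalExonClass]
    end_classes: List[TerminalExonClass]
    internal_exons: Set[Tuple[int, int]]
    n_transcripts: int
    exons_per_transcript: List[int]
    n_all_exons: int
    excluded_unstranded: List[str] = field(default_factory=list)

    @property
    def n_start_exon_classes(self) -> int:
        return len(self.start_classes)

    @property
    def n_end_exon_classes(self) -> int:
        return len(self.end_classes)


def single_linkage_1d(positions: Sequence[int], tolerance: int) -> List[List[int]]:
    """Cluster sorted 1-D positions; split where adjacent gap exceeds tolerance.

    Equivalent to the transitive closure of the pairwise |a-b| <= tolerance
    relation (chained merges allowed).
    """
    clusters: List[List[int]] = []
    for idx in sorted(range(len(positions)), key=lambda i: positions[i]):
        if clusters and positions[idx] - positions[clusters[-1][-1]] <= tolerance:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    return clusters


def _merge_terminal(
    candidates: List[Tuple[Optional[int], int, str, GenomicInterval]],
    tolerance: int,
) -> List[TerminalExonClass]:
    """Merge (anchor, position, transcript_id, exon) candidates into classes."""
    by_anchor: Dict[Optional[int], List[Tuple[int, str, GenomicInterval]]] = {}
    for anchor, pos, tid, exon in candidates:
        by_anchor.setdefault(anchor, []).append((pos, tid, exon))
    classes: List[TerminalExonClass] = []
    for anchor in sorted(by_anchor, key=lambda a: (a is None, a)):
        group = by_anchor[anchor]
        positions = [g[0] for g in group]
        for cluster in single_linkage_1d(positions, tolerance):
            members = [group[i] for i in cluster]
            exons = [m[2] for m in members]
            span = GenomicInterval(
                exons[0].chrom,
                min(e.start for e in exons),
                max(e.end for e in exons),
                exons[0].strand,
            )
            classes.append(
                TerminalExonClass(
                    anchor=anchor,
                    positions=tuple(sorted(m[0] for m in members)),
                    members=tuple(sorted(m[1] for m in members)),
                    span=span,
                )
            )
    return classes


def catalog_gene(
    gene: GeneModel, params: CatalogParams = CatalogParams()
) -> ExonCatalog:
    """Build the exon taxonomy of one gene.

    Unstranded transcripts have no 5'/3' semantics and are excluded with a
    warning.  The distinct-exon count ``n_all_exons`` uses exact coordinates
    for internal exons and counts each merged start/end class once; an exon
    of a single-exon transcript (both first and last) is counted once.
    """
    start_candidates: List[Tuple[Optional[int], int, str, GenomicInterval]] = []
    end_candidates: List[Tuple[Optional[int], int, str, GenomicInterval]] = []
    internal: Set[Tuple[int, int]] = set()
    terminal_coords: Set[Tuple[int, int]] = set()
    exons_per_transcript: List[int] = []
    excluded: List[str] = []
    n_used = 0

    for t in gene.transcripts:
        if not t.is_stranded:
            warnings.warn(
                f"{gene.gene_name}: excluding unstranded transcript "
                f"{t.transcript_id} from the exon catalog"
            )
            excluded.append(t.transcript_id)
            continue
        n_used += 1
        exons_per_transcript.append(len(t.exons))
        first, last = t.first_exon(), t.last_exon()
        if len(t.exons) == 1:
            if params.single_exon_classes:
                start_candidates.append((None, t.tss, t.transcript_id, first))
                end_candidates.append((None, t.tes, t.transcript_id, last))
            continue
        # donor = 3' splice site of the first exon; acceptor = 5' splice site
        # of the last exon (both strand-aware, recorded as 0-based boundaries)
        donor = first.end if t.strand == "+" else first.start
        acceptor = last.start if t.strand == "+" else last.end
        start_candidates.append((donor, t.tss, t.transcript_id, first))
        end_candidates.append((acceptor, t.tes, t.transcript_id, last))
        for e in t.exons:
            if e not in (first, last):
                internal.add((e.start, e.end))
        terminal_coords.update({(first.start, first.end), (last.start, last.end)})

    start_classes = _merge_terminal(start_candidates, params.tss_tolerance_bp)
    end_classes = _merge_terminal(end_candidates, params.tes_tolerance_bp)

    # single-exon transcripts contribute one exon overall even though they
    # appear in both a start and an end class
    n_single_classes = sum(1 for c in end_classes if c.anchor is None)
    internal_only = internal - terminal_coords
    n_all = (
        len(internal_only)
        + len(start_classes)
        + len(end_classes)
        - n_single_classes
    )

    return ExonCatalog(
        gene_name=gene.gene_name,
        start_classes=start_classes,
        end_classes=end_classes,
        internal_exons=internal,
        n_transcripts=n_used,
        exons_per_transcript=exons_per_transcript,
        n_all_exons=n_all,
        excluded_unstranded=excluded,
    )


def promoter_count(catalog: ExonCatalog) -> int:
    """Number of start-exon classes, i.e. potential promoters of the gene."""
    return catalog.n_start_exon_classes


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


_SUMMARY_COLUMNS = [
    "n_transcripts",
    "n_start_exon_classes",
    "n_end_exon_classes",
    "mean_exons_per_transcript",
    "n_all_exons",
    "median_exons_per_transcript",
]


def catalog_row(catalog: ExonCatalog) -> Dict[str, Union[str, float]]:
    epr = catalog.exons_per_transcript
    return {
        "gene": catalog.gene_name,
        "n_transcripts": catalog.n_transcripts,
        "n_start_exon_classes": catalog.n_start_exon_classes,
        "n_end_exon_classes": catalog.n_end_exon_classes,
        "mean_exons_per_transcript": float(np.mean(epr)) if epr else 0.0,
        "n_all_exons": catalog.n_all_exons,
        "median_exons_per_transcript": float(np.median(epr)) if epr else 0.0,
    }


def summarize_cohort(
    catalogs: Union[Sequence[ExonCatalog], pd.DataFrame]
) -> pd.DataFrame:
    """Cohort summary: one row per gene plus mean, rounded mean and median.

    Accepts either built :class:`ExonCatalog` objects or a pre-tabulated
    per-gene DataFrame with the same numeric columns (e.g. a published
    cohort table).  The median of an even-length column is the mean of the
    two middle order statistics; rounded means use round-half-up.
    """
    if isinstance(catalogs, pd.DataFrame):
        df = catalogs.copy()
        if "gene" in df.columns:
            df = df.set_index("gene")
    else:
        if len(catalogs) == 0:
            raise ValueError("summarize_cohort needs at least one catalog")
        df = pd.DataFrame([catalog_row(c) for c in catalogs]).set_index("gene")
    cols = [c for c in _SUMMARY_COLUMNS if c in df.columns]
    if not cols or len(df) == 0:
        raise ValueError("summarize_cohort needs at least one gene row")
    body = df[cols].astype(float)
    summary = pd.DataFrame(
        {
            "mean": body.mean(),
            "mean_rounded": body.mean().map(_round_half_up),
            "median": body.median(),
        }
    ).T
    summary.index.name = "gene"
    return pd.concat([body, summary])
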