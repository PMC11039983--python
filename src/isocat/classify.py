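"""Structural classification of predicted receptor isoforms.

Adhesion GPCRs are built from a long multi-domain N terminus, a GAIN domain
carrying the GPS autoproteolysis site, the seven-transmembrane bundle
(7TMD) and a C terminus.  Alternative transcription starts and splicing
produce proteins that keep or lose these parts; each isoform is classified
against the gene's reference (longest-protein) isoform:

* ``full_length_7tm`` — at least 7 TM helices with the ORF starting at the
  reference N terminus;
* ``soluble_n_terminus`` — no TM helix at all (premature stops upstream of
  the 7TMD);
* ``membrane_anchored_n_terminus`` — 1 to 6 TM helices (truncation within
  the 7TMD);
* ``ctf_like`` — at least 7 TM helices but an ORF starting at or downstream
  of the reference GPS, resembling the autoproteolytic C-terminal fragment;
* ``c_term_variant_only`` — full-length architecture whose sequence differs
  from the reference only C-terminal of TM7.

Domain calls (TM spans, GPS, signal peptide) are consumed from an upstream
annotation, never predicted here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import DomainAnnotation, IsocatError
from .orf import OrfRecord, cds_offset_of

_TM_LABEL = re.compile(r"^TM(\d+)$")


class ClassificationError(IsocatError, ValueError):
    pass


@dataclass(frozen=True)
class ReceptorArchitecture:
    """Domain architecture of one predicted protein.

    ``tm_spans`` are the canonical TM1..TM7 helices in 1-based residue
    coordinates, ordered N- to C-terminal; an additional N-terminal helix
    annotated ``extraTM`` is kept separately and does not count toward the
    seven-TM bundle.
    """

    transcript_id: str
    protein_length: int
    tm_spans: Tuple[Tuple[int, int], ...]
    extra_tm_spans: Tuple[Tuple[int, int], ...] = ()
    gps_residue: Optional[int] = None
    has_signal_peptide: bool = False

    @property
    def n_tm(self) -> int:
        return len(self.tm_spans)

    @property
    def tm1_start(self) -> Optional[int]:
        return self.tm_spans[0][0] if self.tm_spans else None

    @property
    def last_tm_end(self) -> Optional[int]:
        return self.tm_spans[-1][1] if self.tm_spans else None


def build_architecture(
    transcript_id: str,
    protein_length: int,
    domains: Iterable[DomainAnnotation],
) -> ReceptorArchitecture:
    """Assemble an architecture from consumed domain calls for one transcript."""
    tm: List[Tuple[int, Tuple[int, int]]] = []
    extra: List[Tuple[int, int]] = []
    gps: Optional[int] = None
    sp = False
    for d in domains:
        if d.transcript_id != transcript_id:
            continue
        if d.residue_end > protein_length:
            raise ClassificationError(
                f"{transcript_id}: domain {d.domain_label} ends at residue "
                f"{d.residue_end} beyond protein length {protein_length}"
            )
        m = _TM_LABEL.match(d.domain_label)
        if m:
            tm.append((int(m.group(1)), (d.residue_start, d.residue_end)))
        elif d.domain_label == "extraTM":
            extra.append((d.residue_start, d.residue_end))
        elif d.domain_label == "GPS":
            gps = d.residue_start
        elif d.domain_label == "SP":
            sp = True
    spans = tuple(span for _, span in sorted(tm))
    for a, b in zip(spans, spans[1:]):
        if b[0] <= a[1]:
            raise ClassificationError(
                f"{transcript_id}: TM spans overlap or are out of order"
            )
    return ReceptorArchitecture(
        transcript_id=transcript_id,
        protein_length=protein_length,
        tm_spans=spans,
        extra_tm_spans=tuple(sorted(extra)),
        gps_residue=gps,
        has_signal_peptide=sp,
    )


@dataclass(frozen=True)
class IsoformClassification:
    transcript_id: str
    full_length_7tm: bool = False
    soluble_n_terminus: bool = False
    membrane_anchored_n_terminus: bool = False
    ctf_like: bool = False
    c_term_variant_only: bool = False

    @property
    def category(self) -> str:
        for name in (
            "ctf_like",
            "full_length_7tm",
            "soluble_n_terminus",
            "membrane_anchored_n_terminus",
        ):
            if getattr(self, name):
                return name
        return "other"


def start_residue_in_reference(
    orf: OrfRecord, reference_orf: OrfRecord
) -> Optional[int]:
    """Residue of the reference protein where this isoform's ORF begins.

    Returns 1 when the start maps to (or genomically 5' of) the reference
    start codon, a larger residue number when it falls inside the reference
    CDS, and None when the two coding regions do not correspond (the start
    lies in a reference intron or beyond its CDS).
    """
    first = orf.cds_genomic[0]
    start_pos = first.start if first.strand == "+" else first.end - 1
    offset = cds_offset_of(reference_orf, start_pos)
    if offset is not None:
        return offset // 3 + 1
    ref_first = reference_orf.cds_genomic[0]
    if ref_first.strand == "+" and start_pos < ref_first.start:
        return 1
    if ref_first.strand == "-" and start_pos >= ref_first.end:
        return 1
    return None


def classify_isoform(
    arch: ReceptorArchitecture,
    reference: ReceptorArchitecture,
    start_residue_in_ref: Optional[int] = None,
    protein: Optional[str] = None,
    reference_protein: Optional[str] = None,
    ctf_upstream_window: int = 50,
) -> IsoformClassification:
    """Classify one isoform against the gene's reference architecture.

    ``start_residue_in_ref`` locates this isoform's translation start on the
    reference protein (see :func:`start_residue_in_reference`); when omitted
    the start is assumed aligned with the reference N terminus.  When the
    reference GPS is not annotated, the CTF boundary falls back to
    ``ctf_upstream_window`` residues upstream of the reference TM1.
    """
    if reference.n_tm == 0:
        raise ClassificationError(
            f"{reference.transcript_id}: reference isoform carries no TM "
            "annotation; cannot classify against it"
        )
    n_tm = arch.n_tm
    soluble = n_tm == 0
    anchored = 1 <= n_tm <= 6
    if reference.gps_residue is not None:
        ctf_boundary = reference.gps_residue
    else:
        ctf_boundary = max(1, (reference.tm1_start or 1) - ctf_upstream_window)
    ctf = (
        n_tm >= 7
        and start_residue_in_ref is not None
        and start_residue_in_ref >= ctf_boundary
    )
    full = n_tm >= 7 and not ctf and (
        start_residue_in_ref is None or start_residue_in_ref <= 1
    )
    cterm_only = False
    if (
        full
        and protein is not None
        and reference_protein is not None
        and reference.last_tm_end is not None
    ):
        cut = reference.last_tm_end
        cterm_only = (
            protein != reference_protein
            and protein[:cut] == reference_protein[:cut]
        )
    return IsoformClassification(
        transcript_id=arch.transcript_id,
        full_length_7tm=full,
        soluble_n_terminus=soluble,
        membrane_anchored_n_terminus=anchored,
        ctf_like=ctf,
        c_term_variant_only=cterm_only,
    )


@dataclass(frozen=True)
class GeneVariabilityFlags:
    gene_name: str
    ntf_variability: bool
    cterm_variability: bool
    tmd_variability: bool
    any_soluble_nt: bool
    any_anchored_nt: bool
    any_ctf: bool
    n_signal_peptides: int
    chimeric_partner_genes: Tuple[str, ...] = ()


#: Table 2-style category columns, in reporting order
FLAG_COLUMNS = [
    "ntf_variability",
    "cterm_variability",
    "tmd_variability",
    "any_soluble_nt",
    "any_anchored_nt",
    "any_ctf",
]


def _regions(arch: ReceptorArchitecture, protein: str) -> Dict[str, Optional[str]]:
    """N-terminal, TM-block and C-terminal residue stretches of one isoform.

    Regions are delimited by the isoform's own TM annotation; an isoform
    without TM helices is all N terminus.
    """
    if arch.n_tm == 0:
        return {"n": protein, "tm": None, "c": None}
    t1 = arch.tm1_start
    tl = arch.last_tm_end
    return {"n": protein[: t1 - 1], "tm": protein[t1 - 1 : tl], "c": protein[tl:]}


def classify_gene(
    gene_name: str,
    members: Sequence[Tuple[IsoformClassification, ReceptorArchitecture, str]],
    chimeric_partners: Iterable[str] = (),
) -> GeneVariabilityFlags:
    """Aggregate per-isoform classifications into per-gene variability flags.

    ``members`` are (classification, architecture, protein) triples.  A
    region (N terminus, TM block, C terminus) is variable when at least two
    isoforms that possess the region differ in its residue sequence.  The
    existential flags record whether any member falls into the respective
    structural category; ``n_signal_peptides`` counts members whose consumed
    annotation includes a signal peptide.
    """
    if not members:
        raise ValueError(f"{gene_name}: classify_gene needs >=1 member")
    region_sets: Dict[str, Set[str]] = {"n": set(), "tm": set(), "c": set()}
    for _, arch, protein in members:
        for key, value in _regions(arch, protein).items():
            if value is not None:
                region_sets[key].add(value)
    return GeneVariabilityFlags(
        gene_name=gene_name,
        ntf_variability=len(region_sets["n"]) >= 2,
        cterm_variability=len(region_sets["c"]) >= 2,
        tmd_variability=len(region_sets["tm"]) >= 2,
        any_soluble_nt=any(c.soluble_n_terminus for c, _, _ in members),
        any_anchored_nt=any(c.membrane_anchored_n_terminus for c, _, _ in members),
        any_ctf=any(c.ctf_like for c, _, _ in members),
        n_signal_peptides=sum(1 for _, a, _ in members if a.has_signal_peptide),
        chimeric_partner_genes=tuple(sorted(set(chimeric_partners))),
    )


def flags_table(flags: Sequence[GeneVariabilityFlags]) -> pd.DataFrame:
    rows = []
    for f in flags:
        row = {"gene": f.gene_name}
        row.update({col: int(getattr(f, col)) for col in FLAG_COLUMNS})
        row["n_signal_peptides"] = f.n_signal_peptides
        row["chimeric_partners"] = ",".join(f.chimeric_partner_genes)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_flags(
    flags: "Sequence[GeneVariabilityFlags] | pd.DataFrame",
) -> pd.Series:
    """Percentage of genes with each category flag set.

    Accepts flag objects or a 0/1 indicator DataFrame with the category
    columns.  Percentages are exact (callers format to one decimal for
    display).
    """
    if isinstance(flags, pd.DataFrame):
        df = flags
    else:
        if len(flags) == 0:
            raise ValueError("summarize_flags needs >=1 gene")
        df = flags_table(flags)
    cols = [c for c in FLAG_COLUMNS if c in df.columns]
    if len(df) == 0 or not cols:
        raise ValueError("summarize_flags needs >=1 gene with category columns")
    return 100.0 * df[cols].astype(float).mean()
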