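"""Self-contained synthetic transcriptome fixtures with known ground truth.

The generator emits a complete toy input bundle — genome FASTA, reference
annotation GTF, merged assembly GTF with NSTRG-prefixed novel transcripts,
per-sample abundance and metadata TSVs, a protein-domain TSV, a variant
list, a capture BED — plus a machine-readable truth manifest, so every
pipeline stage can be tested without downloads.

Each gene follows one designed receptor architecture (signal peptide, GAIN
domain with a GPS methionine, seven TM helices, C terminus; 290 residues)
and a fixed repertoire of transcript variants exercising the phenomena the
pipeline must recover: a near promoter within the TSS merge tolerance, far
promoters beyond it, an internal-TSS transcript whose ORF starts at the GPS
(a CTF-like product), a premature-stop soluble variant, an open-ended
truncation inside the TM bundle (membrane-anchored), an alternative
C-terminal exon, and optionally a two-gene chimera.

Coding sequence is deterministic (seed-independent) and built from a codon
map in which the trinucleotide ATG cannot occur except at designed start
codons — neither inside a codon nor across codon junctions — and all
rng-generated UTR/intron sequence is scrubbed of ATG, so the designed ORF
is provably the longest for every seed.  The seed controls only
untranslated sequence content and the expression noise.

Expression designs: ``independent`` draws each transcript's tissue profile
independently; ``proportional`` gives two designed transcripts the same
profile shape (co-expression r near 1); ``switch`` makes different
transcripts dominant in different tissues.  Per-sample TPM is the designed
tissue mean times multiplicative lognormal noise with coefficient of
variation ``noise_cv`` (CV=0 reproduces the means exactly).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as iio
from .model import GenomicInterval, TranscriptModel

CHROM = "chrT"
_BASES = np.array(list("ACGT"))

# one codon per amino acid, chosen so that no codon contains "TG" (except
# ATG itself, used only for designed Met) and none ends in A or T -- hence
# ATG cannot arise across any codon junction
_CODON = {
    "A": "GCC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC", "H": "CAC",
    "I": "ATC", "K": "AAG", "L": "CTC", "M": "ATG", "N": "AAC", "P": "CCC",
    "Q": "CAG", "R": "CGC", "S": "TCC", "T": "ACC", "V": "GTC", "Y": "TAC",
}
_ALPHABET = "ADEFGHIKLNPQRSTVY"  # no M (reserved for starts), no C/W
_HYDRO = "LIVFA"

# residue layout of the designed reference protein (1-based)
PROT_LEN = 290
SP_SPAN = (2, 21)
GAIN_SPAN = (51, 80)
GPS_RES = 81          # the GPS methionine; GPS domain 81-90
TM_LEN, LOOP_LEN = 20, 5
TM1_START = 91        # TM_i spans 91+25(i-1) .. +19; block ends at 260
CTERM_START = 261
ANCHORED_LAST_RES = 165   # truncation point after TM3 loop
ALT_CTERM_LEN = 25        # alternative C-terminal exon product


def tm_span(i: int, offset: int = 0) -> Tuple[int, int]:
    start = TM1_START + (TM_LEN + LOOP_LEN) * (i - 1) - offset
    return start, start + TM_LEN - 1


def encode(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def scrub_atg(seq: str) -> str:
    """Remove every ATG occurrence from non-coding sequence."""
    while "ATG" in seq:
        seq = seq.replace("ATG", "ACG")
    return seq


def _noncoding(rng: np.random.Generator, n: int) -> str:
    """Random sequence guaranteed free of ATG, ending in CC so that ATG
    cannot form across the junction with whatever follows."""
    seq = scrub_atg("".join(_BASES[rng.integers(0, 4, n)]))
    return seq[:-2] + "CC"


def _seg(gene_idx: int, salt: int, length: int, alphabet: str = _ALPHABET) -> str:
    return "".join(
        alphabet[(gene_idx * 7 + salt * 3 + k) % len(alphabet)]
        for k in range(length)
    )


def reference_protein(gene_idx: int) -> str:
    """The designed 290-residue full-length receptor of one gene.

    Methionines occur only at residue 1 and at the GPS (residue 81).
    """
    parts = [
        "M",
        _seg(gene_idx, 1, 20, _HYDRO),       # 2-21   signal-peptide helix
        _seg(gene_idx, 2, 29),               # 22-50  N-terminal domain
        _seg(gene_idx, 3, 30),               # 51-80  GAIN
        "M" + _seg(gene_idx, 4, 9),          # 81-90  GPS
    ]
    for i in range(1, 8):                    # 91-260 TM bundle with loops
        parts.append(_seg(gene_idx, 10 + i, TM_LEN, _HYDRO))
        if i < 7:
            parts.append(_seg(gene_idx, 20 + i, LOOP_LEN, "GSPTE"))
    parts.append(_seg(gene_idx, 5, 30))      # 261-290 C terminus
    protein = "".join(parts)
    assert len(protein) == PROT_LEN and protein.count("M") == 2
    return protein


def alt_cterm(gene_idx: int) -> str:
    return _seg(gene_idx, 6, ALT_CTERM_LEN)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study; the seed fixes all randomness."""

    seed: int = 1
    n_genes: int = 3
    n_promoters: int = 2              # external promoter classes per gene
    include_internal_tss: bool = True
    include_ctf_like: bool = True
    include_chimeric: bool = True
    tissues: Tuple[str, ...] = (
        "brain", "liver", "heart", "kidney", "lung",
        "colon", "skin", "muscle", "testis", "spleen",
    )
    n_samples_per_tissue: int = 3
    design: str = "independent"       # independent | proportional | switch
    noise_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_promoters < 1 or self.n_samples_per_tissue < 1:
            raise ValueError("counts must be >= 1")
        if self.design not in ("independent", "proportional", "switch"):
            raise ValueError(f"unknown expression design {self.design!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.tissues:
            raise ValueError("need >=1 tissue")

    @property
    def include_internal(self) -> bool:
        # the internal-TSS transcript is the CTF-like product; either toggle
        # materializes it
        return self.include_internal_tss or self.include_ctf_like


@dataclass
class TruthManifest:
    """Ground truth for everything the generator emitted."""

    spec: Dict
    genes: Dict[str, Dict]
    transcripts: Dict[str, Dict]
    dominant: Dict[str, Dict[str, str]]
    proportional_pairs: Dict[str, List[str]]
    variants: Dict[str, List[str]]
    capture_gaps: Dict[str, Dict]

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


class _GeneBuild:
    """Piece-wise genomic layout of one designed gene."""

    # transcript-forward piece order
    def __init__(self, gene_idx: int, strand: str, spec: FixtureSpec,
                 rng: np.random.Generator):
        self.gene_idx = gene_idx
        self.strand = strand
        self.gene_name = f"GENE{gene_idx + 1}"
        protein = reference_protein(gene_idx)
        cds = encode(protein)  # 870 nt, no stop
        far_len = 80 * (spec.n_promoters - 1)
        self.pieces: List[Tuple[str, str]] = []  # (name, transcript-forward seq)
        if far_len:
            self.pieces.append(("u5far", _noncoding(rng, far_len)))
        self.pieces += [
            ("u5", _noncoding(rng, 60)),
            ("partA", cds[: 3 * 60]),                   # aa 1-60
            ("intron1", _noncoding(rng, 150)),
            ("partB", cds[3 * 60 : 3 * 90]),            # aa 61-90 (GPS Met)
            ("intron2", scrub_atg("TAA" + _noncoding(rng, 117))),
            ("partC", cds[3 * 90 : 3 * 260]),           # aa 91-260 (TM bundle)
            ("intron3", _noncoding(rng, 100)),
            ("partD", cds[3 * 260 :] + scrub_atg("TAA" + _noncoding(rng, 80))),
            ("gap3b", _noncoding(rng, 80)),
            ("e4b", encode(alt_cterm(gene_idx)) + scrub_atg("TAA" + _noncoding(rng, 70))),
        ]
        self.protein = protein
        self.lengths = {name: len(seq) for name, seq in self.pieces}
        self.intervals: Dict[str, Tuple[int, int]] = {}

    def place(self, cursor: int) -> Tuple[str, int]:
        """Lay the pieces onto the genome from ``cursor``; returns the
        genomic sequence contribution and the new cursor."""
        from .orf import reverse_complement

        ordered = self.pieces if self.strand == "+" else list(reversed(self.pieces))
        chunks = []
        for name, seq in ordered:
            gseq = seq if self.strand == "+" else reverse_complement(seq)
            self.intervals[name] = (cursor, cursor + len(seq))
            chunks.append(gseq)
            cursor += len(seq)
        return "".join(chunks), cursor

    def sub(self, name: str, t_lo: int, t_hi: int) -> Tuple[int, int]:
        """Genomic interval of a transcript-forward window of one piece."""
        start, end = self.intervals[name]
        if self.strand == "+":
            return start + t_lo, start + t_hi
        return end - t_hi, end - t_lo

    def exon(self, parts: Sequence[Tuple[str, Optional[int], Optional[int]]]
             ) -> GenomicInterval:
        """One exon spanning contiguous (piece, t_lo, t_hi) windows."""
        ivs = []
        total = 0
        for name, t_lo, t_hi in parts:
            lo = 0 if t_lo is None else t_lo
            hi = self.lengths[name] if t_hi is None else t_hi
            ivs.append(self.sub(name, lo, hi))
            total += hi - lo
        start = min(s for s, _ in ivs)
        end = max(e for _, e in ivs)
        assert end - start == total, "exon pieces must be contiguous"
        return GenomicInterval(CHROM, start, end, self.strand)


def _build_transcripts(
    builds: List[_GeneBuild], spec: FixtureSpec
) -> Tuple[List[TranscriptModel], Dict[str, Dict]]:
    """All transcript models plus their per-transcript truth records."""
    transcripts: List[TranscriptModel] = []
    truth: Dict[str, Dict] = {}

    def add(tid, gene, exons, source, category, promoter_class,
            protein_len, has_stop=True, partners=()):
        gene_name = gene.gene_name if source == "annotated" else None
        transcripts.append(
            TranscriptModel(tid, tuple(exons), source, gene_name)
        )
        truth[tid] = {
            "gene": gene.gene_name,
            "source": source,
            "category": category,
            "promoter_class": promoter_class,
            "protein_length": protein_len,
            "has_stop": has_stop,
            "chimeric_partners": sorted(partners),
        }

    for g in builds:
        i = g.gene_idx + 1
        e1 = g.exon([("u5", None, None), ("partA", None, None)])
        e2 = g.exon([("partB", None, None)])
        e3 = g.exon([("partC", None, None)])
        e4 = g.exon([("partD", None, None)])
        ref_id = f"NM_{100000 + g.gene_idx}.1"
        add(ref_id, g, [e1, e2, e3, e4], "annotated", "full_length_7tm", 0,
            PROT_LEN)
        k = 1
        # near promoter: TSS 30 bp downstream, same donor -> merges with ref
        e1_near = g.exon([("u5", 30, None), ("partA", None, None)])
        add(f"NSTRG.{i}.{k}", g, [e1_near, e2, e3, e4], "novel",
            "full_length_7tm", 0, PROT_LEN)
        k += 1
        # far promoters: TSS 80*j bp upstream, same donor -> own classes
        for j in range(1, spec.n_promoters):
            far_len = g.lengths.get("u5far", 0)
            e1_far = g.exon([
                ("u5far", far_len - 80 * j, None),
                ("u5", None, None),
                ("partA", None, None),
            ])
            add(f"NSTRG.{i}.{k}", g, [e1_far, e2, e3, e4], "novel",
                "full_length_7tm", j, PROT_LEN)
            k += 1
        if spec.include_internal:
            # internal TSS inside intron1; ORF starts at the GPS Met
            e_int = g.exon([("intron1", 100, None), ("partB", None, None)])
            add(f"NSTRG.{i}.{k}", g, [e_int, e3, e4], "novel", "ctf_like",
                spec.n_promoters, PROT_LEN - GPS_RES + 1)
        k += 1
        # soluble: last exon runs into intron2 and hits the planted stop
        e2ext = g.exon([("partB", None, None), ("intron2", 0, 63)])
        add(f"NSTRG.{i}.{k}", g, [e1, e2ext], "novel", "soluble_n_terminus",
            0, GPS_RES + 9)  # aa 1-90
        k += 1
        # anchored: transcript ends inside the TM bundle (open-ended ORF)
        e3a = g.exon([("partC", 0, 3 * (ANCHORED_LAST_RES - TM1_START + 1))])
        add(f"NSTRG.{i}.{k}", g, [e1, e2, e3a], "novel",
            "membrane_anchored_n_terminus", 0, ANCHORED_LAST_RES,
            has_stop=False)
        k += 1
        # alternative C-terminal exon
        e4b = g.exon([("e4b", None, None)])
        add(f"NSTRG.{i}.{k}", g, [e1, e2, e3, e4b], "novel",
            "full_length_7tm", 0, CTERM_START - 1 + ALT_CTERM_LEN)
        k += 1

    if spec.include_chimeric and len(builds) >= 2:
        a, b = builds[0], builds[1]
        e1 = a.exon([("u5", None, None), ("partA", None, None)])
        e2 = a.exon([("partB", None, None)])
        e3 = a.exon([("partC", None, None)])
        be4 = b.exon([("partD", None, None)])
        tid = f"NSTRG.{a.gene_idx + 1}.90"
        add(tid, a, [e1, e2, e3, be4], "novel", "full_length_7tm", 0,
            PROT_LEN, partners=[a.gene_name, b.gene_name])
    return transcripts, truth


def _domain_rows(truth: Dict[str, Dict]) -> List[Tuple[str, str, int, int]]:
    """Consumed-domain annotation consistent with the designed proteins."""
    rows: List[Tuple[str, str, int, int]] = []
    for tid, rec in sorted(truth.items()):
        cat = rec["category"]
        if cat == "ctf_like":
            offset = GPS_RES - 1          # protein starts at the GPS Met
            rows.append((tid, "GPS", 1, 10))
            for i in range(1, 8):
                s, e = tm_span(i, offset)
                rows.append((tid, f"TM{i}", s, e))
            continue
        rows.append((tid, "SP", SP_SPAN[0], SP_SPAN[1]))
        rows.append((tid, "GAIN", GAIN_SPAN[0], GAIN_SPAN[1]))
        rows.append((tid, "GPS", GPS_RES, GPS_RES + 9))
        if cat == "soluble_n_terminus":
            continue
        n_tm = 3 if cat == "membrane_anchored_n_terminus" else 7
        for i in range(1, n_tm + 1):
            s, e = tm_span(i)
            rows.append((tid, f"TM{i}", s, e))
    return rows


def _tissue_profile(rng: np.random.Generator, n: int) -> np.ndarray:
    """A tissue-mean profile with realistic dynamic range: a shuffled
    geometric series spanning roughly 1.5 orders of magnitude, as
    tissue-specific transcripts show in expression heatmaps."""
    return rng.permutation(3.0 * 1.45 ** np.arange(n))


def _design_means(
    builds: List[_GeneBuild],
    truth: Dict[str, Dict],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> Dict[str, Dict[str, float]]:
    """Designed tissue-mean TPM per transcript."""
    means: Dict[str, Dict[str, float]] = {}
    for g in builds:
        tids = sorted(t for t, r in truth.items() if r["gene"] == g.gene_name)
        if spec.design == "proportional":
            pair = tids[:2]
            profile = _tissue_profile(rng, len(spec.tissues))
            for tid in tids:
                if tid == pair[0]:
                    vals = profile
                elif tid == pair[1]:
                    vals = 0.6 * profile
                else:
                    vals = _tissue_profile(rng, len(spec.tissues))
                means[tid] = dict(zip(spec.tissues, np.round(vals, 4)))
        elif spec.design == "switch":
            hi_a, hi_b = tids[0], tids[min(2, len(tids) - 1)]
            for tid in tids:
                base = rng.uniform(2.0, 8.0, size=len(spec.tissues))
                means[tid] = dict(zip(spec.tissues, np.round(base, 4)))
            means[hi_a][spec.tissues[0]] = 40.0
            if len(spec.tissues) > 1:
                means[hi_b][spec.tissues[1]] = 40.0
        else:
            for tid in tids:
                vals = _tissue_profile(rng, len(spec.tissues))
                means[tid] = dict(zip(spec.tissues, np.round(vals, 4)))
    return means


def generate(spec: FixtureSpec, outdir) -> TruthManifest:
    """Write the full fixture bundle into ``outdir``; returns the manifest.

    The same spec (same seed) produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    strands = ["+" if (i < 2 or i % 2 == 1) else "-" for i in range(spec.n_genes)]
    builds = [
        _GeneBuild(i, strands[i], spec, rng) for i in range(spec.n_genes)
    ]
    chrom_parts = ["".join(_BASES[rng.integers(0, 4, 100)])]
    cursor = 100
    for g in builds:
        seq, cursor = g.place(cursor)
        chrom_parts.append(seq)
        spacer = _noncoding(rng, 300)
        chrom_parts.append(spacer)
        cursor += len(spacer)
    chrom_parts.append("".join(_BASES[rng.integers(0, 4, 100)]))
    genome = {CHROM: "".join(chrom_parts)}

    transcripts, truth = _build_transcripts(builds, spec)
    annotated = [t for t in transcripts if t.source == "annotated"]
    iio.write_fasta(genome, outdir / "genome.fa")
    iio.write_gtf(annotated, outdir / "annotation.gtf", source="fixture")
    iio.write_gtf(transcripts, outdir / "merged.gtf", source="fixture")

    # expression
    means = _design_means(builds, truth, spec, rng)
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    samples = [
        (f"{tissue}_{j + 1}", tissue)
        for tissue in spec.tissues
        for j in range(spec.n_samples_per_tissue)
    ]
    with open(outdir / "metadata.tsv", "wt") as fh:
        fh.write("sample_id\ttissue\n")
        for sid, tissue in samples:
            fh.write(f"{sid}\t{tissue}\n")
    with open(outdir / "abundance.tsv", "wt") as fh:
        fh.write("transcript_id\tsample_id\ttpm\n")
        for tid in sorted(means):
            for sid, tissue in samples:
                mean = means[tid][tissue]
                if spec.noise_cv > 0:
                    factor = rng.lognormal(-sigma**2 / 2, sigma)
                else:
                    factor = 1.0
                fh.write(f"{tid}\t{sid}\t{mean * factor:.6f}\n")

    with open(outdir / "domains.tsv", "wt") as fh:
        fh.write("transcript_id\tdomain\tresidue_start\tresidue_end\n")
        for tid, label, s, e in _domain_rows(truth):
            fh.write(f"{tid}\t{label}\t{s}\t{e}\n")

    # variants: one in the first coding exon (codon 30), one in the TM exon
    # (codon 120); positions written 1-based
    variant_truth: Dict[str, List[str]] = {}
    with open(outdir / "variants.tsv", "wt") as fh:
        fh.write("chrom\tpos\tlabel\n")
        for g in builds:
            up_pos = g.sub("partA", 3 * 29, 3 * 29 + 1)[0]
            sh_pos = g.sub("partC", 3 * (120 - 91), 3 * (120 - 91) + 1)[0]
            for label, pos in (
                (f"{g.gene_name}_upstream_stop", up_pos),
                (f"{g.gene_name}_shared_tm_stop", sh_pos),
            ):
                fh.write(f"{CHROM}\t{pos + 1}\t{label}\n")
            members = {
                tid: rec for tid, rec in truth.items()
                if rec["gene"] == g.gene_name
            }
            up_affected, sh_affected = [], []
            for tid, rec in members.items():
                cat = rec["category"]
                chimera = bool(rec["chimeric_partners"])
                has_e1 = cat != "ctf_like"
                has_e3 = cat not in ("soluble_n_terminus",)
                if has_e1:
                    up_affected.append(tid)
                if has_e3 and cat != "membrane_anchored_n_terminus":
                    sh_affected.append(tid)
                elif cat == "membrane_anchored_n_terminus":
                    # codon 120 lies inside the retained TM1-TM3 exon part
                    sh_affected.append(tid)
            variant_truth[f"{g.gene_name}_upstream_stop"] = sorted(up_affected)
            variant_truth[f"{g.gene_name}_shared_tm_stop"] = sorted(sh_affected)

    # capture design: the whole gene locus is targeted except the middle of
    # the alternative C-terminal exon e4b -- the designed "new exon" gap
    capture_rows: List[Tuple[GenomicInterval, str]] = []
    capture_truth: Dict[str, Dict] = {}
    for g in builds:
        span_lo = min(s for s, _ in g.intervals.values())
        span_hi = max(e for _, e in g.intervals.values())
        s, e = g.intervals["e4b"]
        gap_lo, gap_hi = s + 30, e - 30
        capture_rows.append(
            (GenomicInterval(CHROM, span_lo, gap_lo, "."), f"{g.gene_name}_a")
        )
        capture_rows.append(
            (GenomicInterval(CHROM, gap_hi, span_hi, "."), f"{g.gene_name}_b")
        )
        capture_truth[g.gene_name] = {
            "exon": [s, e],
            "uncovered": [[gap_lo, gap_hi]],
            "n_gap_exons": 1,
        }
    iio.write_bed(sorted(capture_rows, key=lambda r: r[0]), outdir / "capture.bed")

    gene_truth: Dict[str, Dict] = {}
    n_prom_truth = spec.n_promoters + (1 if spec.include_internal else 0)
    for g in builds:
        chim_here = spec.include_chimeric and spec.n_genes >= 2 and g.gene_idx == 0
        gene_truth[g.gene_name] = {
            "chrom": CHROM,
            "strand": g.strand,
            "reference_isoform": f"NM_{100000 + g.gene_idx}.1",
            "n_promoters": n_prom_truth,
            # end classes: main stop exon, soluble, anchored, alt C-term
            # (+ the chimera's borrowed end exon on gene A)
            "n_end_exon_classes": 4 + (1 if chim_here else 0),
            "reference_protein": g.protein,
        }

    dominant = {
        g.gene_name: {
            tissue: min(
                tid for tid in means
                if truth[tid]["gene"] == g.gene_name
                and means[tid][tissue] == max(
                    means[t2][tissue] for t2 in means
                    if truth[t2]["gene"] == g.gene_name
                )
            )
            for tissue in spec.tissues
        }
        for g in builds
    }
    proportional_pairs = {}
    if spec.design == "proportional":
        for g in builds:
            tids = sorted(t for t, r in truth.items() if r["gene"] == g.gene_name)
            proportional_pairs[g.gene_name] = tids[:2]

    manifest = TruthManifest(
        spec={**asdict(spec), "tissues": list(spec.tissues)},
        genes=gene_truth,
        transcripts=truth,
        dominant=dominant,
        proportional_pairs=proportional_pairs,
        variants=variant_truth,
        capture_gaps=capture_truth,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
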