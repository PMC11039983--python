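# Methods

This note documents the models, conventions and design choices behind
`isocat`, in the order the pipeline applies them.

## Coordinates and data model

All in-memory coordinates are 0-based half-open on a named chromosome.
GTF and VCF use 1-based inclusive coordinates on disk; the conversion
happens exactly once, in `isocat.io`, so no other code ever reasons about
bases. Exons are stored in ascending genomic order for both strands;
5′/3′ semantics (TSS, TES, donor/acceptor, first/last exon) are computed
from the strand at the point of use. Transcripts must have ≥1 exon, all
exons on one chromosome and strand, pairwise disjoint with introns of at
least 1 bp. Novelty is keyed on the transcript-identifier prefix
(`NSTRG` by default, configurable), matching StringTie-merge output.

Transcripts with strand "`.`" are accepted by the readers but excluded
from every operation that needs 5′/3′ semantics (exon cataloguing, ORF
calling); they are reported with a warning. Stranded assemblies are the
intended input; silently guessing a strand would corrupt promoter counts.

## Gene assignment

A novel transcript is assigned to the annotated gene with which it shares
the most exonic bases. Overlap is computed against the *base-level union*
of all annotated transcripts of a gene, so exons shared between annotated
isoforms are not double counted. Counting is strand-aware by default
(antisense overlap counts zero) because antisense mis-assignment is the
more damaging error for downstream per-gene statistics; a flag relaxes
this. Ties are broken by lexicographically smaller gene name and recorded
in the result, making assignment invariant under input permutation. A
transcript with zero overlap everywhere is labelled a novel locus. A
transcript sharing at least `min_bases` (default 1) exonic bases with two
or more genes is flagged chimeric, with the partner set recorded; the
threshold is exposed because no principled universal value exists.

Interval bookkeeping uses an interval tree per (chromosome, strand); the
result equals per-base set intersection (tested against that oracle).

## Exon taxonomy and promoter counts

Exons are classified by the splice sites that define them:

* a **5′ start exon** by its donor site,
* a **3′ end exon** by its acceptor site,
* an **internal exon** by both (exact coordinates).

Start exons sharing an identical donor whose TSS differ by at most
`tss_tolerance_bp` (default 50) merge into one class; end exons merge
symmetrically on (acceptor, TES). Merging is single-linkage: the
tolerance is a pairwise relation and single linkage is its deterministic
transitive closure, so a chain of starts 0/40/80 bp apart forms one
class. The alternative (fixed 50-bp bins) would make class boundaries
depend on an arbitrary origin. Class counts are therefore monotonically
non-increasing in the tolerance, and re-cataloguing one representative
per class is idempotent (both properties are tested).

The number of start-exon classes is reported as the gene's potential
promoter count; internal TSS (a first exon beginning inside an intron)
naturally form their own class because their donor differs.

Single-exon transcripts have neither donor nor acceptor. By default they
contribute TSS-only start classes and TES-only end classes merged under
the same tolerances and count once (not twice) toward the distinct-exon
total; the behaviour sits behind `CatalogParams.single_exon_classes`.
The distinct-exon count (`n_all_exons`) uses exact coordinates for
internal exons plus one count per merged terminal class; whether a
published distinct-exon tally collapses terminal classes or counts raw
coordinates is generally ambiguous, so this choice is documented rather
than asserted as canonical.

Cohort summaries report per-gene rows plus mean, rounded mean
(round-half-up) and median; the median of an even-length column is the
mean of the two middle order statistics.

## ORFs and the predicted proteome

The spliced sequence of a transcript is the concatenation of its exon
sequences in genomic order, reverse-complemented as a whole on the minus
strand. The longest ORF is the longest span starting at an ATG and ending
at the first in-frame stop (TAA/TAG/TGA). Design choices:

* **ATG starts only.** Non-AUG initiation and IRES-driven starts exist
  biologically but are not predictable from sequence alone at this level.
* **Open-ended ORFs allowed.** An ORF with no in-frame stop before the
  sequence end qualifies and is flagged (`has_stop=False`); assembled
  3′-incomplete transcripts are common, and dropping them would bias the
  longest-ORF choice toward complete models. A `require_stop` switch
  restores the strict behaviour.
* **Ties go to the 5′-most ATG** (the longest-UTR-consistent call);
  deterministic.
* **N-containing codons translate to X and never terminate** —
  conservative on gappy assemblies.

The implementation indexes stop positions per frame and binary-searches
the first in-frame stop per ATG; it is tested against a brute-force
oracle that scans every ATG codon by codon.

Each gene's reference isoform is the transcript with the longest
predicted protein (ties: smallest transcript id). Residue intervals map
to genomic intervals through the CDS coordinate map, splitting at splice
junctions; the genomic length of a residue interval is exactly three
times the residue count, and the inverse map recovers codon indices for
variant projection.

## Isoform structural classes

Domain calls (TM1..TM7 helices, an optional extra N-terminal helix, GPS,
signal peptide) are *consumed* from an annotation table produced by
upstream predictors — never predicted here. Classification against the
gene's reference architecture:

* `full_length_7tm`: ≥7 TM helices, ORF start aligned with the reference
  N terminus;
* `soluble_n_terminus`: no TM helix (premature stop upstream of the TM
  bundle);
* `membrane_anchored_n_terminus`: 1–6 TM helices (truncation inside the
  bundle);
* `ctf_like`: ≥7 TM helices with the ORF starting at or downstream of the
  reference GPS — resembling the autoproteolytic C-terminal fragment.
  When the GPS is not annotated, the boundary falls back to 50 residues
  upstream of the reference TM1 (configurable).

The isoform's start is located on the reference protein through the
genomic CDS maps (`start_residue_in_reference`); a start genomically 5′
of the reference start codon counts as aligned.

Per-gene variability flags compare residue regions delimited by each
isoform's own TM annotation: the N terminus (before TM1; the whole
protein for TM-less isoforms), the TM block (TM1 start to last TM end)
and the C terminus (after the last TM). A region is *variable* when at
least two isoforms that possess it differ in its residue sequence. This
is the simplest testable operationalization of category check-marks in
published per-gene tables, which rarely state their exact criterion; a
domain-level (rather than residue-level) definition would be coarser.
`summarize_flags` returns exact percentages; display formatting rounds
half-up to one decimal (published tables vary between rounding and
truncating such rows, which is why the exact values are the API).

Signal-peptide presence is a pass-through count of members whose
annotation includes one.

## Expression

The quantification unit is TPM as supplied; no renormalization is
performed. Samples aggregate to tissues by arithmetic mean. A
transcript's fraction is 100 × its mean TPM over the summed mean TPM of
its gene's transcripts in that tissue (0 when the gene total is 0,
flagged); fractions per gene and tissue sum to 100 whenever the gene is
expressed. A gene counts as expressed in a tissue when its summed
transcript mean TPM strictly exceeds the threshold (default 0.5 TPM; 1
TPM serves as the stricter sensitivity cut). Dominant transcripts are
arg-max by mean TPM with lexicographic tie-break.

Transcript–transcript co-expression treats each tissue as one
observation; Pearson is the default (absolute-expression correlation),
Spearman available. Zero-variance vectors yield a flagged undefined
result rather than an arbitrary number.

Tissue contrasts use Welch's unequal-variance t-test on per-sample TPM
without log transform (a log2(TPM+1) option exists but is off by
default — fidelity to the plain-TPM convention first, robustness as an
option), with Benjamini–Hochberg correction across the transcripts tested
in one call. Groups with fewer than two samples are skipped with a
warning.

## Variant projection and capture gaps

Variants are points (SNVs). For each transcript a variant receives
exactly one class: `outside` (beyond the transcript span), `intronic`,
or exonic subdivided by the ORF into `exonic_utr5` / `exonic_cds` /
`exonic_utr3` (strand-aware); transcripts without an ORF report
`exonic_noncoding`. In the CDS, the splice-aware map yields the
nucleotide offset and 1-based codon index. The default affected-set rule
selects CDS hits; an any-exonic rule is a monotone superset.

Capture-gap reporting merges the capture intervals per chromosome, then
partitions every assembled exon into covered and uncovered sub-intervals
(their lengths always sum to the exon length — tested against a per-base
oracle) and tallies, per gene, the exons with at least one uncovered
base.

## The synthetic fixture generator

The generator emulates the statistical structure the pipeline must
resolve, not raw reads (no FASTQ; the toolchain starts at assembled
transcripts). Each gene follows one designed 290-residue receptor
architecture — signal peptide, GAIN-like region, GPS methionine at
residue 81, seven 20-residue TM helices with 5-residue loops (TM1 at
residue 91, bundle ending at 260), 30-residue C terminus — and a fixed
transcript repertoire: the annotated full-length model, a near promoter
(TSS −30 bp, merging), far promoters (−80 bp each, not merging), an
internal-TSS transcript whose ORF begins at the GPS (the CTF-like
product), a premature-stop soluble variant (last exon running into an
intron with a planted stop), an open-ended truncation after TM3
(membrane-anchored), an alternative C-terminal exon, and optionally a
chimera joining the first three exons of one gene to the last exon of
the next same-strand gene.

Two constructions make ground truth provable rather than probable:

* **Coding sequence is seed-independent** and uses one codon per amino
  acid chosen so the trinucleotide ATG cannot occur inside a codon or
  across any codon junction; designed proteins contain methionine only at
  the start and the GPS.
* **All rng-generated UTR/intron sequence is scrubbed of ATG** and ends
  in CC so no ATG can form across piece junctions.

Hence the designed ORF is the longest ORF for *every* seed, and the seed
only controls untranslated sequence content and expression noise. Genome
length stays under ~10 kb for the default three genes, so the full test
suite runs in seconds.

Expression designs: tissue-mean profiles are shuffled geometric series
spanning about 1.5 orders of magnitude — the dynamic range
tissue-specific transcripts show in expression heatmaps; a uniform draw
was rejected because it can produce profiles too flat for the designed
co-expression contrast to be detectable at the default noise level.
`proportional` gives two designed transcripts the same profile shape
(scaled 0.6×), `independent` draws every profile separately, `switch`
plants different dominant transcripts in two designated tissues.
Per-sample TPM is the designed mean times multiplicative lognormal noise
with unit mean and coefficient of variation `noise_cv` (default 0.2;
CV=0 reproduces the means exactly, which is what the exact-recovery
tests use). The same spec and seed produce byte-identical files.

What the fixtures do **not** emulate: read-level sampling noise,
assembly artifacts (mis-joined exons, fragmented models), TPM
compositional coupling between genes, multi-chromosome genomes, and
unstranded transcripts. Passing the recovery tests therefore shows the
analytical logic is correct on well-formed inputs, not that upstream
assembly errors are tolerated.

## Problem sizes and numerical checks

The acceptance script and test suite use: 1000 random 300-nt sequences
against the brute-force ORF oracle; per-base set oracles for overlap and
capture-gap arithmetic on randomized interval sets; a 1000-replicate
simulated null (two groups of 5, same normal distribution) for the Welch
type-I error, expected within three binomial standard deviations of
α = 0.05; and the default three-gene fixture bundles at CV 0 (exact
recovery) and CV 0.2 (statistical recovery). Fraction sums are asserted
to 1e-9; correlation contracts at r > 0.9 (proportional pair) and a mean
pairwise r within ±0.3 of zero (independent design, ~70 partially
dependent pairs).

## Known limitations

* The chimera model is read-through-like (shared splice structure); no
  genomic breakpoint reasoning.
* Variability flags compare residue strings; biologically silent
  differences (e.g. alternate codons) upstream of the protein level are
  invisible, and alignment-free region comparison can over-call
  variability when an isoform's own TM annotation is shifted.
* Variant projection classifies position only — no missense/NMD effect
  prediction.
* `select_reference_isoform` prefers the longest protein, which on
  3′-incomplete assemblies with open-ended ORFs may pick an incomplete
  model; `require_stop` avoids this at the cost of dropping such
  transcripts.
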