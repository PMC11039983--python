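"""Variant projection onto transcript structures and capture gaps."""

import numpy as np
import pytest

from isocat.model import GeneModel, GenomicInterval, TranscriptModel, Variant
from isocat.orf import call_orfs
from isocat.variants import (
    affected_transcript_set,
    capture_gaps,
    project_variant,
)

# two-transcript toy gene on a tiny genome: T2 skips the middle exon
GENOME = {"chr1": "A" * 50 + "ATG" + "A" * 27 + "C" * 20 + "AAATAA" + "G" * 200}
# layout: exon1 [50,80) holds ATG..., exon2 [80,100), exon3 [100,106)
T1 = TranscriptModel(
    "T1",
    (
        GenomicInterval("chr1", 50, 80, "+"),
        GenomicInterval("chr1", 90, 100, "+"),
        GenomicInterval("chr1", 150, 200, "+"),
    ),
)
T2 = TranscriptModel(
    "T2",
    (
        GenomicInterval("chr1", 50, 80, "+"),
        GenomicInterval("chr1", 150, 200, "+"),
    ),
)
GENE = GeneModel("G", (T1, T2))
ORFS = call_orfs([T1, T2], GENOME)


class TestProjectVariant:
    def test_intron_of_one_exon_of_another(self):
        v = Variant("chr1", 95, "m1")
        res = project_variant(v, GENE, ORFS).by_transcript()
        assert res["T1"].location_class.startswith("exonic")
        assert res["T2"].location_class == "intronic"

    def test_each_transcript_gets_exactly_one_class(self):
        for pos in (10, 55, 85, 95, 160, 250):
            res = project_variant(Variant("chr1", pos, "m"), GENE, ORFS)
            assert len(res.projections) == len(GENE.transcripts)

    def test_first_base_of_start_codon_is_codon_one(self):
        v = Variant("chr1", 50, "m")  # ATG starts at 50
        res = project_variant(v, GENE, ORFS).by_transcript()
        assert res["T1"].location_class == "exonic_cds"
        assert res["T1"].cds_offset == 0
        assert res["T1"].codon_index == 1

    def test_codon_index_follows_splice_aware_offset(self):
        v = Variant("chr1", 92, "m")  # exon2 of T1 only
        res = project_variant(v, GENE, ORFS).by_transcript()
        assert res["T1"].codon_index == res["T1"].cds_offset // 3 + 1

    def test_position_outside_span_is_outside(self):
        res = project_variant(Variant("chr1", 10, "m"), GENE, ORFS).by_transcript()
        assert {p.location_class for p in res.values()} == {"outside"}

    def test_fixture_upstream_variant_spares_internal_tss_transcript(
        self, fixture_bundle
    ):
        from isocat.io import read_fasta, read_gtf, read_variants
        from isocat.assign import apply_assignments, assign_transcripts
        from isocat.model import group_into_genes

        outdir, manifest = fixture_bundle
        merged = read_gtf(outdir / "merged.gtf")
        ann = group_into_genes(read_gtf(outdir / "annotation.gtf"))
        merged = apply_assignments(
            merged, assign_transcripts([t for t in merged if t.is_novel], ann)
        )
        genes = {g.gene_name: g for g in group_into_genes(merged)}
        orfs = call_orfs(merged, read_fasta(outdir / "genome.fa"))
        for v in read_variants(outdir / "variants.tsv"):
            gene_name = v.label.split("_")[0]
            res = project_variant(v, genes[gene_name], orfs)
            affected = affected_transcript_set(res)
            assert sorted(affected) == manifest.variants[v.label]
            if v.label.endswith("upstream_stop"):
                by_tid = res.by_transcript()
                ctf = next(
                    t for t, r in manifest.transcripts.items()
                    if r["gene"] == gene_name and r["category"] == "ctf_like"
                )
                assert by_tid[ctf].location_class == "outside"


class TestAffectedTranscriptSet:
    def test_all_intronic_is_empty(self):
        res = project_variant(Variant("chr1", 120, "m"), GENE, ORFS)
        assert affected_transcript_set(res) == set()

    def test_any_exonic_rule_is_a_superset_of_default(self):
        for pos in range(40, 220, 7):
            res = project_variant(Variant("chr1", pos, "m"), GENE, ORFS)
            assert affected_transcript_set(res) <= affected_transcript_set(
                res, "any-exonic"
            )


def _per_base_gap_oracle(exon, capture):
    capture_bases = {
        b
        for iv in capture
        if iv.chrom == exon.chrom
        for b in range(iv.start, iv.end)
    }
    exon_bases = set(range(exon.start, exon.end))
    return len(exon_bases & capture_bases), len(exon_bases - capture_bases)


class TestCaptureGaps:
    def test_interval_difference_example(self):
        exon = GenomicInterval("chr1", 100, 200)
        report = capture_gaps({"G": [exon]}, [GenomicInterval("chr1", 150, 250)])
        (ec,) = report.exons
        assert ec.uncovered == ((100, 150),)
        assert report.gap_exon_counts() == {"G": 1}

    def test_fully_covered_exon_has_no_gap(self):
        exon = GenomicInterval("chr1", 100, 200)
        report = capture_gaps({"G": [exon]}, [GenomicInterval("chr1", 50, 300)])
        assert not report.exons[0].has_gap
        assert report.gap_exon_counts() == {"G": 0}

    def test_overlapping_capture_records_are_merged(self):
        exon = GenomicInterval("chr1", 100, 200)
        capture = [
            GenomicInterval("chr1", 90, 150),
            GenomicInterval("chr1", 140, 210),
        ]
        report = capture_gaps({"G": [exon]}, capture)
        assert report.exons[0].covered == ((100, 200),)

    def test_matches_per_base_oracle_on_random_sets(self):
        rng = np.random.default_rng(23)
        for _ in range(40)   :
            exons = [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(5, 40)))
                for s in rng.choice(np.arange(0, 900, 50), 4, replace=False)
            ]
            capture = [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(5, 80)))
                for s in rng.integers(0, 900, 6)
            ]
            report = capture_gaps({"G": exons}, capture)
            for ec in report.exons:
                cov, uncov = _per_base_gap_oracle(ec.exon, capture)
                assert (ec.covered_bases, ec.uncovered_bases) == (cov, uncov)
                # covered and uncovered partition the exon
                assert ec.covered_bases + ec.uncovered_bases == len(ec.exon)

    def test_fixture_designed_gap_is_found(self, fixture_bundle):
        from isocat.io import read_bed, read_gtf
        from isocat.assign import apply_assignments, assign_transcripts
        from isocat.model import group_into_genes

        outdir, manifest = fixture_bundle
        merged = read_gtf(outdir / "merged.gtf")
        ann = group_into_genes(read_gtf(outdir / "annotation.gtf"))
        merged = apply_assignments(
            merged, assign_transcripts([t for t in merged if t.is_novel], ann)
        )
        exons_by_gene = {
            g.gene_name: {e for t in g.transcripts for e in t.exons}
            for g in group_into_genes(merged)
        }
        report = capture_gaps(exons_by_gene, read_bed(outdir / "capture.bed"))
        counts = report.gap_exon_counts()
        for gene, truth in manifest.capture_gaps.items():
            assert counts[gene] == truth["n_gap_exons"]
            gaps = [
                [s, e]
                for g, iv in report.gap_intervals()
                if g == gene
                for s, e in [(iv.start, iv.end)]
            ]
            assert gaps == truth["uncovered"]
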