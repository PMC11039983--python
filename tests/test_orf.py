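"""Spliced sequences, longest-ORF calling and protein/genome maps."""

import numpy as np
import pytest

from isocat.model import CoordinateError, GeneModel, GenomicInterval, TranscriptModel
from isocat.orf import (
    OrfRecord,
    call_orf,
    call_orfs,
    cds_offset_of,
    longest_orf,
    protein_to_genome,
    select_reference_isoform,
    spliced_sequence,
    transcript_to_genome,
    translate,
)

GENCODE = {"TTT": "F", "ATG": "M"}  # spot checks only; oracle below is free


def brute_force_longest_orf(seq):
    """Independent oracle: enumerate every ATG, scan codon by codon."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        has_stop = False
        while j + 3 <= len(seq):
            if seq[j : j + 3] in stops:
                has_stop = True
                break
            j += 3
        end = j + 3 if has_stop else j
        aa_len = (j - i) // 3
        key = (aa_len, -i)
        if best is None or key > best[0]:
            best = (key, i, end if has_stop else i + 3 * aa_len, has_stop)
    if best is None:
        return None
    _, start, end, has_stop = best
    return start, end + (0 if not has_stop else 0), has_stop


def _tx(exons, strand="+", tid="t1"):
    return TranscriptModel(
        tid, tuple(GenomicInterval("chr1", s, e, strand) for s, e in exons)
    )


class TestSplicedSequence:
    def test_plus_strand_concatenation(self):
        genome = {"chr1": "ATGCCCAAA"}
        assert spliced_sequence(_tx([(0, 3), (6, 9)]), genome) == "ATGAAA"

    def test_minus_strand_reverse_complement(self):
        genome = {"chr1": "ATGCCC"}
        assert spliced_sequence(_tx([(0, 6)], strand="-"), genome) == "GGGCAT"

    def test_matches_manual_slice_oracle(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=500))}
        exons = [(10, 60), (100, 130), (200, 290)]
        manual = "".join(genome["chr1"][s:e] for s, e in exons)
        assert spliced_sequence(_tx(exons), genome) == manual

    def test_exon_beyond_chromosome_is_an_error(self):
        with pytest.raises(CoordinateError):
            spliced_sequence(_tx([(0, 100)]), {"chr1": "ACGT"})


class TestLongestOrf:
    def test_direct_translation(self):
        call = longest_orf("ATGAAATAG")
        assert call.protein == "MK" and call.has_stop
        assert (call.orf_start, call.orf_end) == (0, 9)

    def test_no_start_codon_means_no_orf(self):
        assert longest_orf("CCCGGG") is None

    def test_open_ended_orf_is_flagged(self):
        call = longest_orf("ATGAAAAA")
        assert not call.has_stop
        assert call.protein == "MK"
        assert (call.orf_end - call.orf_start) % 3 == 0

    def test_n_codons_translate_to_x_and_do_not_terminate(self):
        call = longest_orf("ATGANATAG")  # ANA could fake a stop if mishandled
        assert call.protein == "MX"
        assert call.has_stop

    def test_tie_goes_to_five_prime_most_start(self):
        # two ORFs of equal length in different frames
        seq = "ATGAAATAGCATGAAATAGC"
        call = longest_orf(seq)
        assert call.orf_start == 0

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            call = longest_orf(seq)
            expected = brute_force_longest_orf(seq)
            if expected is None:
                assert call is None
            else:
                start, end, has_stop = expected
                assert (call.orf_start, call.orf_end, call.has_stop) == (
                    start,
                    end,
                    has_stop,
                )
                aa_len = (end - start) // 3 - (1 if has_stop else 0)
                assert len(call.protein) == aa_len


class TestSelectReferenceIsoform:
    def _gene_with_proteins(self, proteins):
        orfs = {
            tid: OrfRecord(tid, 0, 3 * len(p), True, p,
                           (GenomicInterval("chr1", 0, 3 * len(p), "+"),))
            for tid, p in proteins.items()
        }
        transcripts = tuple(
            _tx([(0, 3 * len(p))], tid=tid) for tid, p in proteins.items()
        )
        return GeneModel("G", transcripts), orfs

    def test_longest_protein_wins(self):
        gene, orfs = self._gene_with_proteins({"a": "M" * 300, "b": "M" * 295})
        assert select_reference_isoform(gene, orfs) == "a"

    def test_tie_takes_smallest_id(self):
        gene, orfs = self._gene_with_proteins({"b": "M" * 10, "a": "M" * 10})
        assert select_reference_isoform(gene, orfs) == "a"

    def test_no_orfs_gives_none(self):
        gene, _ = self._gene_with_proteins({"a": "M"})
        assert select_reference_isoform(gene, {}) is None


class TestProteinToGenome:
    def test_intronless_affine_map(self):
        orf = OrfRecord(
            "t", 0, 30, False, "M" * 10,
            (GenomicInterval("chr1", 100, 130, "+"),),
        )
        (iv,) = protein_to_genome(orf, 1, 10)
        assert (iv.start, iv.end) == (100, 130)

    def test_junction_spanning_domain_conserves_length(self):
        orf = OrfRecord(
            "t", 0, 60, True, "M" * 19,
            (
                GenomicInterval("chr1", 100, 130, "+"),
                GenomicInterval("chr1", 200, 230, "+"),
            ),
        )
        ivs = protein_to_genome(orf, 8, 13)
        assert len(ivs) == 2
        assert sum(len(iv) for iv in ivs) == 3 * 6

    def test_out_of_range_residues_error(self):
        orf = OrfRecord(
            "t", 0, 30, True, "M" * 9, (GenomicInterval("chr1", 100, 130, "+"),)
        )
        with pytest.raises(CoordinateError):
            protein_to_genome(orf, 1, 11)

    def test_round_trip_through_cds_offset(self, fixture_bundle):
        from isocat.io import read_fasta, read_gtf

        outdir, _ = fixture_bundle
        genome = read_fasta(outdir / "genome.fa")
        for t in read_gtf(outdir / "merged.gtf"):
            orf = call_orf(t, genome)
            for residue in (1, 2, orf.protein_length // 2, orf.protein_length):
                (iv, *rest) = protein_to_genome(orf, residue, residue)
                pieces = [iv] + rest
                assert sum(len(p) for p in pieces) == 3
                first = pieces[0]
                pos = first.start if first.strand == "+" else first.end - 1
                offset = cds_offset_of(orf, pos)
                assert offset // 3 + 1 == residue
                # disjoint, exon-contained intervals
                for p in pieces:
                    assert any(
                        e.start <= p.start and p.end <= e.end for e in t.exons
                    )


def test_translation_is_self_consistent_on_fixture_orfs(fixture_bundle):
    from isocat.io import read_fasta, read_gtf

    outdir, manifest = fixture_bundle
    genome = read_fasta(outdir / "genome.fa")
    transcripts = read_gtf(outdir / "merged.gtf")
    orfs = call_orfs(transcripts, genome)
    for t in transcripts:
        orf = orfs[t.transcript_id]
        seq = spliced_sequence(t, genome)
        assert translate(seq[orf.orf_start : orf.orf_end]) == orf.protein
        truth = manifest.transcripts[t.transcript_id]
        assert orf.protein_length == truth["protein_length"]
        assert orf.has_stop == truth["has_stop"]
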