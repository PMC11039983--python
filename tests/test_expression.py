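"""Tissue aggregation, transcript fractions, thresholds and statistics."""

import numpy as np
import pandas as pd
import pytest

from isocat.expression import (
    ExpressionMatrix,
    aggregate_by_tissue,
    co_expression,
    dominant_transcript,
    expressed_genes,
    tissue_compare,
    transcript_fractions,
)
from isocat.model import AbundanceRecord, SampleMetadata


def _matrix(values, tissues, gene_of):
    """values: dict tid -> dict sample -> tpm; tissues: dict sample -> tissue."""
    records = [
        AbundanceRecord(tid, sid, tpm)
        for tid, row in values.items()
        for sid, tpm in row.items()
    ]
    metadata = [SampleMetadata(s, t) for s, t in tissues.items()]
    return ExpressionMatrix.from_records(records, metadata, gene_of)


SIMPLE = _matrix(
    {
        "t1": {"s1": 2.0, "s2": 4.0, "s3": 9.0},
        "t2": {"s1": 1.0, "s2": 1.0, "s3": 3.0},
    },
    {"s1": "brain", "s2": "brain", "s3": "liver"},
    {"t1": "G", "t2": "G"},
)


class TestAggregateByTissue:
    def test_single_sample_tissue_is_itself(self):
        means = aggregate_by_tissue(SIMPLE)
        assert means.loc["t1", "liver"] == 9.0

    def test_mean_of_two_samples(self):
        means = aggregate_by_tissue(SIMPLE)
        assert means.loc["t1", "brain"] == 3.0

    def test_matches_independent_group_mean_oracle(self):
        rng = np.random.default_rng(5)
        tissues = {f"s{i}": f"t{i % 4}" for i in range(12)}
        values = {
            f"tx{j}": {s: float(rng.uniform(0, 50)) for s in tissues}
            for j in range(6)
        }
        m = _matrix(values, tissues, {f"tx{j}": "G" for j in range(6)})
        means = aggregate_by_tissue(m)
        for tid, row in values.items():
            for tissue in set(tissues.values()):
                expected = np.mean(
                    [v for s, v in row.items() if tissues[s] == tissue]
                )
                assert means.loc[tid, tissue] == pytest.approx(expected)


class TestTranscriptFractions:
    def test_three_to_one_split(self):
        m = _matrix(
            {"t1": {"s1": 3.0}, "t2": {"s1": 1.0}},
            {"s1": "brain"},
            {"t1": "G", "t2": "G"},
        )
        frac = transcript_fractions(aggregate_by_tissue(m), m.gene_of)
        by_tid = frac.set_index("transcript_id")["fraction_pct"]
        assert by_tid["t1"] == 75.0 and by_tid["t2"] == 25.0

    def test_zero_expression_gives_zero_fractions_flagged(self):
        m = _matrix(
            {"t1": {"s1": 0.0}, "t2": {"s1": 0.0}},
            {"s1": "brain"},
            {"t1": "G", "t2": "G"},
        )
        frac = transcript_fractions(aggregate_by_tissue(m), m.gene_of)
        assert (frac["fraction_pct"] == 0).all()
        assert (~frac["gene_expressed"]).all()

    def test_fractions_sum_to_hundred_per_gene_and_tissue(self, fixture_bundle):
        from isocat.io import read_abundance, read_gtf, read_metadata

        outdir, manifest = fixture_bundle
        records = read_abundance(outdir / "abundance.tsv")
        metadata = read_metadata(outdir / "metadata.tsv")
        gene_of = {t: r["gene"] for t, r in manifest.transcripts.items()}
        m = ExpressionMatrix.from_records(records, metadata, gene_of)
        frac = transcript_fractions(aggregate_by_tissue(m), gene_of)
        sums = frac.groupby(["gene", "tissue"])["fraction_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)


class TestExpressedGenes:
    def _means(self, total):
        m = _matrix(
            {"t1": {"s1": total}}, {"s1": "brain"}, {"t1": "G"}
        )
        return aggregate_by_tissue(m)

    def test_strictly_above_threshold_is_expressed(self):
        assert "G" in expressed_genes(self._means(0.6), {"t1": "G"}, 0.5)["brain"]

    def test_equal_to_threshold_is_not_expressed(self):
        assert "G" not in expressed_genes(self._means(0.5), {"t1": "G"}, 0.5)["brain"]

    def test_one_tpm_sensitivity_threshold(self):
        assert "G" not in expressed_genes(self._means(0.9), {"t1": "G"}, 1.0)["brain"]

    def test_raising_threshold_never_adds_genes(self):
        rng = np.random.default_rng(9)
        tissues = {f"s{i}": f"t{i % 3}" for i in range(9)}
        values = {
            f"tx{j}": {s: float(rng.uniform(0, 2)) for s in tissues}
            for j in range(8)
        }
        gene_of = {f"tx{j}": f"G{j % 3}" for j in range(8)}
        means = aggregate_by_tissue(_matrix(values, tissues, gene_of))
        previous = None
        for threshold in (0.0, 0.5, 1.0, 2.0, 5.0):
            current = expressed_genes(means, gene_of, threshold)
            if previous is not None:
                for tissue in current:
                    assert current[tissue] <= previous[tissue]
            previous = current


class TestDominantTranscript:
    def test_single_transcript_is_dominant(self):
        means = aggregate_by_tissue(
            _matrix({"t1": {"s1": 5.0}}, {"s1": "brain"}, {"t1": "G"})
        )
        assert dominant_transcript(means, {"t1": "G"}, "G", "brain") == "t1"

    def test_tie_takes_smallest_id(self):
        m = _matrix(
            {"t2": {"s1": 5.0}, "t1": {"s1": 5.0}},
            {"s1": "brain"},
            {"t1": "G", "t2": "G"},
        )
        means = aggregate_by_tissue(m)
        assert dominant_transcript(means, m.gene_of, "G", "brain") == "t1"

    def test_switch_design_changes_dominance_between_tissues(self, tmp_path):
        from isocat.simulate import FixtureSpec, generate
        from isocat.io import read_abundance, read_metadata

        manifest = generate(
            FixtureSpec(seed=3, design="switch", noise_cv=0.0), tmp_path
        )
        gene_of = {t: r["gene"] for t, r in manifest.transcripts.items()}
        m = ExpressionMatrix.from_records(
            read_abundance(tmp_path / "abundance.tsv"),
            read_metadata(tmp_path / "metadata.tsv"),
            gene_of,
        )
        means = aggregate_by_tissue(m)
        t_a, t_b = manifest.spec["tissues"][:2]
        for gene, truth in manifest.dominant.items():
            assert dominant_transcript(means, gene_of, gene, t_a) == truth[t_a]
            assert dominant_transcript(means, gene_of, gene, t_b) == truth[t_b]
            assert truth[t_a] != truth[t_b]


class TestCoExpression:
    def test_vector_with_itself_is_one(self):
        v = [1.0, 5.0, 2.0, 8.0]
        assert co_expression(v, v).r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert co_expression([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_zero_variance_is_flagged_undefined(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = co_expression([1, 1, 1], [1, 2, 3])
        assert not res.valid and np.isnan(res.r)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 10, 20), rng.uniform(0, 10, 20)
        res = co_expression(x, y)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert res.r == pytest.approx(manual)

    def test_spearman_is_rank_based(self):
        x = [1, 2, 3, 4, 5.0]
        y = [1, 4, 9, 16, 25.0]  # monotone but nonlinear
        assert co_expression(x, y, method="spearman").r == pytest.approx(1.0)


class TestTissueCompare:
    def _matrix_for_ttest(self, a_vals, b_vals):
        samples = {f"a{i}": "A" for i in range(len(a_vals))}
        samples.update({f"b{i}": "B" for i in range(len(b_vals))})
        values = {
            "t1": {
                **{f"a{i}": v for i, v in enumerate(a_vals)},
                **{f"b{i}": v for i, v in enumerate(b_vals)},
            }
        }
        return _matrix(values, samples, {"t1": "G"})

    def test_identical_groups_give_p_one(self):
        m = self._matrix_for_ttest([1, 2, 3], [1, 2, 3])
        res = tissue_compare(m, ["t1"], "A", "B")
        assert res.loc[0, "statistic"] == pytest.approx(0.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_separated_groups_are_significant(self):
        m = self._matrix_for_ttest([0.0, 0.01, 0.02], [10.0, 10.01, 10.02])
        res = tissue_compare(m, ["t1"], "A", "B")
        assert res.loc[0, "p"] < 1e-6

    def test_single_sample_group_is_skipped_with_warning(self):
        m = self._matrix_for_ttest([1.0], [1.0, 2.0])
        with pytest.warns(UserWarning, match="<2 samples"):
            res = tissue_compare(m, ["t1"], "A", "B")
        assert res.empty

    def test_bh_correction_spans_the_tested_transcripts(self):
        samples = {f"a{i}": "A" for i in range(4)}
        samples.update({f"b{i}": "B" for i in range(4)})
        rng = np.random.default_rng(1)
        values = {
            f"t{j}": {s: float(rng.normal(10, 1)) for s in samples}
            for j in range(5)
        }
        m = _matrix(values, samples, {f"t{j}": "G" for j in range(5)})
        res = tissue_compare(m, [f"t{j}" for j in range(5)], "A", "B")
        assert (res["q"] >= res["p"] - 1e-12).all()
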