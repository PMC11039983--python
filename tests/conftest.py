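import pathlib

import pytest

from isocat.pipeline import RunConfig, run_pipeline
from isocat.simulate import FixtureSpec, generate


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Noise-free synthetic bundle: exact ground-truth recovery expected."""
    outdir = tmp_path_factory.mktemp("fixture_cv0")
    manifest = generate(FixtureSpec(seed=7, noise_cv=0.0), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def pipeline_outputs(fixture_bundle, tmp_path_factory):
    outdir, manifest = fixture_bundle
    report_dir = tmp_path_factory.mktemp("report_cv0")
    config = RunConfig(
        merged_gtf=outdir / "merged.gtf",
        annotation_gtf=outdir / "annotation.gtf",
        genome_fasta=outdir / "genome.fa",
        abundance_tsv=outdir / "abundance.tsv",
        metadata_tsv=outdir / "metadata.tsv",
        outdir=report_dir,
        domains_tsv=outdir / "domains.tsv",
        variants_path=outdir / "variants.tsv",
        capture_bed=outdir / "capture.bed",
    )
    written = run_pipeline(config)
    return written, manifest
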