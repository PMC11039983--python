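"""Bundled example data: a published survey of the 33 human adhesion-GPCR
genes, used as a worked example for the cohort summarization operations.

``agpcr_exon_composition`` carries the per-gene transcript and exon counts
(transcripts per gene, merged 5' start and 3' end exon classes, exons per
transcript, distinct exons) and ``agpcr_isoform_categories`` the per-gene
structural-category indicator matrix (N-terminal/C-terminal/7TMD
variability, soluble and membrane-anchored N termini, CTF-like isoforms,
signal-peptide counts and chimeric partner genes).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("isocat.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def agpcr_exon_composition() -> pd.DataFrame:
    """Per-gene exon-composition survey of the 33 human aGPCR genes."""
    return _load("agpcr_exon_composition.tsv")


def agpcr_isoform_categories() -> pd.DataFrame:
    """Per-gene isoform structural-category indicators (0/1 columns)."""
    df = _load("agpcr_isoform_categories.tsv")
    df["chimeric_partners"] = df["chimeric_partners"].fillna("")
    return df
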