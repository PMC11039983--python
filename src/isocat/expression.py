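"""Tissue-level transcript expression: fractions, thresholds, correlation.

The quantification unit is TPM per transcript per sample.  Samples are
grouped into tissues and averaged (arithmetic mean); a transcript's
*fraction* in a tissue is its share (%) of the summed mean TPM of its
gene's transcripts there, so a gene's fractions sum to 100 in every tissue
where it is expressed.  A gene counts as expressed in a tissue when its
summed transcript mean TPM strictly exceeds the threshold (default 0.5
TPM; 1 TPM is the conventional stricter cut).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import AbundanceRecord, SampleMetadata


@dataclass
class ExpressionMatrix:
    """Transcript x sample TPM matrix with a sample -> tissue grouping."""

    tpm: pd.DataFrame  # index: transcript_id, columns: sample_id
    tissue_of: pd.Series  # index: sample_id
    gene_of: Dict[str, str]  # transcript_id -> gene_name

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.tpm.columns) - set(self.tissue_of.index)
        if missing:
            raise ValueError(f"samples without tissue metadata: {sorted(missing)}")

    @classmethod
    def from_records(
        cls,
        records: Sequence[AbundanceRecord],
        metadata: Sequence[SampleMetadata],
        gene_of: Mapping[str, str],
    ) -> "ExpressionMatrix":
        df = pd.DataFrame(
            [(r.transcript_id, r.sample_id, r.tpm) for r in records],
            columns=["transcript_id", "sample_id", "tpm"],
        )
        wide = (
            df.pivot_table(
                index="transcript_id", columns="sample_id", values="tpm", fill_value=0.0
            )
            .sort_index()
            .sort_index(axis=1)
        )
        tissue = pd.Series(
            {m.sample_id: m.tissue for m in metadata}, name="tissue"
        ).sort_index()
        return cls(wide, tissue, dict(gene_of))

    @property
    def tissues(self) -> List[str]:
        return sorted(self.tissue_of.unique())


def aggregate_by_tissue(m: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean TPM per transcript per tissue (transcript x tissue)."""
    groups = m.tissue_of.reindex(m.tpm.columns)
    return m.tpm.T.groupby(groups).mean().T.sort_index(axis=1)


def transcript_fractions(
    tissue_means: pd.DataFrame, gene_of: Mapping[str, str]
) -> pd.DataFrame:
    """Long-format per-tissue transcript fractions.

    Columns: gene, transcript_id, tissue, mean_tpm, fraction_pct.  The
    fraction is 100 x transcript mean TPM / gene total in that tissue, and 0
    where the gene total is 0 (flagged by ``gene_expressed=False``).
    """
    genes = pd.Series(
        {tid: gene_of.get(tid, "") for tid in tissue_means.index}, name="gene"
    )
    totals = tissue_means.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 100.0 * tissue_means / totals
    frac = frac.where(totals > 0, 0.0)
    long = (
        tissue_means.stack()
        .rename("mean_tpm")
        .to_frame()
        .join(frac.stack().rename("fraction_pct"))
        .join(totals.stack().rename("_total"))
        .reset_index()
        .rename(columns={"level_0": "transcript_id", "level_1": "tissue"})
    )
    long.columns = ["transcript_id", "tissue", "mean_tpm", "fraction_pct", "_total"]
    long["gene"] = long["transcript_id"].map(genes)
    long["gene_expressed"] = long.pop("_total") > 0
    return long[
        ["gene", "transcript_id", "tissue", "mean_tpm", "fraction_pct", "gene_expressed"]
    ].sort_values(["gene", "transcript_id", "tissue"], ignore_index=True)


def expressed_genes(
    tissue_means: pd.DataFrame,
    gene_of: Mapping[str, str],
    threshold_tpm: float = 0.5,
) -> Dict[str, Set[str]]:
    """Per-tissue sets of genes whose summed transcript mean TPM strictly
    exceeds the threshold."""
    if threshold_tpm < 0:
        raise ValueError("threshold_tpm must be >= 0")
    genes = pd.Series({tid: gene_of.get(tid, "") for tid in tissue_means.index})
    totals = tissue_means.groupby(genes).sum()
    return {
        tissue: set(totals.index[totals[tissue] > threshold_tpm])
        for tissue in totals.columns
    }


def dominant_transcript(
    tissue_means: pd.DataFrame,
    gene_of: Mapping[str, str],
    gene: str,
    tissue: str,
) -> Optional[str]:
    """Transcript of ``gene`` with the highest mean TPM in ``tissue``; ties
    take the lexicographically smallest transcript_id."""
    tids = sorted(t for t in tissue_means.index if gene_of.get(t) == gene)
    if not tids or tissue not in tissue_means.columns:
        return None
    col = tissue_means.loc[tids, tissue]
    return min(col.index[col == col.max()])


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    method: str
    valid: bool = True


def co_expression(
    v1: Sequence[float], v2: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Correlation between two transcript tissue-mean vectors.

    Each tissue is one observation.  A zero-variance vector makes the
    coefficient undefined; the result is flagged invalid with NaN values.
    """
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("co_expression needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance vector: correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), method, valid=False)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(res[0]), float(res[1]), method)


def tissue_compare(
    m: ExpressionMatrix,
    transcripts: Sequence[str],
    tissue_a: str,
    tissue_b: str,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Welch t-test of per-sample TPM between two tissues, per transcript.

    Benjamini-Hochberg q-values are computed across the transcripts tested
    in this call.  Transcripts are skipped (with a warning) when either
    tissue has fewer than 2 samples.  ``log_transform`` applies
    log2(TPM + 1) first (off by default).
    """
    samples_a = m.tissue_of.index[m.tissue_of == tissue_a]
    samples_b = m.tissue_of.index[m.tissue_of == tissue_b]
    samples_a = [s for s in samples_a if s in m.tpm.columns]
    samples_b = [s for s in samples_b if s in m.tpm.columns]
    if len(samples_a) < 2 or len(samples_b) < 2:
        warnings.warn(
            f"tissue_compare: <2 samples in {tissue_a!r} or {tissue_b!r}; skipped"
        )
        return pd.DataFrame(columns=["transcript_id", "statistic", "p", "q"])
    rows = []
    for tid in transcripts:
        if tid not in m.tpm.index:
            warnings.warn(f"tissue_compare: unknown transcript {tid!r}; skipped")
            continue
        a = m.tpm.loc[tid, samples_a].to_numpy(dtype=float)
        b = m.tpm.loc[tid, samples_b].to_numpy(dtype=float)
        if log_transform:
            a = np.log2(a + 1.0)
            b = np.log2(b + 1.0)
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append((tid, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["transcript_id", "statistic", "p"])
    if len(df):
        finite = df["p"].notna()
        df["q"] = np.nan
        if finite.any():
            df.loc[finite, "q"] = multipletests(
                df.loc[finite, "p"], method="fdr_bh"
            )[1]
    else:
        df["q"] = []
    return df
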