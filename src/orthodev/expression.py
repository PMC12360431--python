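"""Normalization and abundance statistics.

Implements TPM, median-of-ratios size factors, a log2-based
variance-stabilizing transform, the per-stage quartile abundance table with
its chi-square goodness-of-fit, and the isoform census.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, ExpressionMatrix

LOG2 = np.log(2.0)


def compute_tpm(counts: CountMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million normalization.

    ``lengths`` gives per-gene transcript length in nucleotides.  Per sample,
    count rates per kilobase are rescaled so each column sums to one million.
    """
    missing = counts.genes.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"no length for gene {missing[0]!r}")
    lens = lengths.reindex(counts.genes).astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rates = counts.counts.div(lens / 1e3, axis=0)
    tpm = rates.div(rates.sum(axis=0), axis=1) * 1e6
    return ExpressionMatrix(values=tpm, design=counts.design.copy(), kind="TPM")


def size_factors(counts: CountMatrix) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    The reference per gene is the geometric mean across samples; genes with a
    zero count anywhere drop out of the median.
    """
    arr = counts.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    loggeo = logs.mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError("degenerate count matrix: no gene has all-positive counts")
    ratios = np.exp(logs[usable] - loggeo[usable, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.samples, name="size_factor")


def vst_transform(counts: CountMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Variance-stabilizing transform: log2(normalized count + 1).

    Monotone in the count for a fixed factor and flattens the NB
    mean-variance relationship enough for distance-based clustering.
    """
    f = factors.reindex(counts.samples)
    if (f <= 0).any() or f.isna().any():
        raise ValueError("size factors must be positive and cover every sample")
    vst = np.log2(counts.counts.div(f, axis=1) + 1.0)
    return ExpressionMatrix(values=vst, design=counts.design.copy(), kind="VST")


@dataclass
class QuartileTable:
    """Per-class abundance-bin counts at one stage, with a uniformity test."""

    species: str
    stage: str
    counts: pd.DataFrame  # rows: class (coding/noncoding), cols Q1..Q4
    chi2: pd.Series
    p: pd.Series
    df: int = 3


def chi_square_uniform(bin_counts) -> tuple[float, float]:
    """Chi-square goodness-of-fit of bin counts against uniform expectation."""
    obs = np.asarray(bin_counts, dtype=float)
    stat, p = stats.chisquare(obs)
    return float(stat), float(p)


def quartile_table(
    tpm: ExpressionMatrix, coding: pd.Series, stage: str
) -> QuartileTable:
    """Quartile abundance distribution of coding vs noncoding transcripts.

    Transcripts with positive mean TPM across the stage's replicates are
    ranked on the pooled distribution and split into four near-equal bins
    (Q1 lowest .. Q4 highest); each class's bin counts are tested against
    the uniform expectation with df = 3.
    """
    if tpm.kind != "TPM":
        raise ValueError("quartile_table requires a TPM matrix")
    cols = tpm.samples_for_stage(stage)
    means = tpm.values[cols].mean(axis=1)
    expressed = means[means > 0]
    # ranked on the pooled distribution; ties broken by gene id
    idx = sorted(expressed.index, key=lambda g: (expressed[g], g))
    bins = np.array_split(np.array(idx, dtype=object), 4)
    classes = ("coding", "noncoding")
    flags = coding.reindex(expressed.index)
    table = pd.DataFrame(
        0, index=list(classes), columns=[f"Q{i}" for i in range(1, 5)], dtype=int
    )
    for q, members in enumerate(bins, start=1):
        members = pd.Index(members)
        n_cod = int(flags.loc[members].sum())
        table.loc["coding", f"Q{q}"] = n_cod
        table.loc["noncoding", f"Q{q}"] = len(members) - n_cod
    chi2 = {}
    pvals = {}
    for cls in classes:
        obs = table.loc[cls].to_numpy()
        if obs.sum() == 0:
            chi2[cls], pvals[cls] = 0.0, 1.0
        else:
            chi2[cls], pvals[cls] = chi_square_uniform(obs)
    species = str(tpm.design["species"].iloc[0])
    return QuartileTable(
        species=species,
        stage=stage,
        counts=table,
        chi2=pd.Series(chi2),
        p=pd.Series(pvals),
    )


def isoform_census(transcript_to_gene: pd.Series) -> pd.DataFrame:
    """Distribution of isoform counts per gene.

    ``transcript_to_gene`` maps transcript id -> gene id.  Returns a frame
    indexed by isoform count k with the number of genes having k transcripts
    and, among multi-isoform (alternatively spliced) genes, the fraction at
    each k.
    """
    per_gene = transcript_to_gene.groupby(transcript_to_gene).size()
    dist = per_gene.value_counts().sort_index()
    dist.index.name = "n_isoforms"
    out = dist.to_frame(name="n_genes")
    multi = out.loc[out.index > 1, "n_genes"].sum()
    out["fraction_of_as_genes"] = np.where(
        out.index > 1, out["n_genes"] / multi if multi else 0.0, np.nan
    )
    return out
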