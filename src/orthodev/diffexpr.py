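"""Negative-binomial differential expression between consecutive stages.

The test is a closed-form Wald test on the log2 ratio of group means of
size-factor-normalized counts (with +0.5 pseudocounts), with a
method-of-moments NB dispersion shrunk toward the across-gene median and
Benjamini-Hochberg FDR control.  DEGs require both a fold-change and an
adjusted-p threshold; the boundary conventions are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import COMPARISONS, CountMatrix
from .expression import size_factors

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)


@dataclass(frozen=True)
class DEThresholds:
    """DEG definition: fold-change and FDR cutoffs with boundary modes."""

    lfc: float = 1.0
    alpha: float = 0.05
    lfc_inclusive: bool = True  # |log2fc| >= lfc (vs strictly >)
    alpha_inclusive: bool = False  # padj < alpha (vs <=)

    def passes(self, log2fc: np.ndarray, padj: np.ndarray) -> np.ndarray:
        a = np.abs(log2fc)
        fc_ok = a >= self.lfc if self.lfc_inclusive else a > self.lfc
        p_ok = padj <= self.alpha if self.alpha_inclusive else padj < self.alpha
        return fc_ok & p_ok


def estimate_dispersion(
    counts: CountMatrix, factors: pd.Series | None = None
) -> pd.Series:
    """Per-gene NB dispersion by method of moments with median shrinkage.

    Stage means are removed (pooled within-stage variance) so planted
    fold changes do not inflate the estimate; the raw estimate
    ``max((s^2 - m) / m^2, 1e-8)`` is shrunk halfway on the log scale toward
    the across-gene median.
    """
    if factors is None:
        factors = size_factors(counts)
    stages = counts.design["stage"]
    for stage, group in counts.design.groupby("stage"):
        if len(group) < 2:
            raise ValueError(
                f"stage {stage!r} has a single replicate; use a pooled dispersion"
            )
    norm = counts.counts.div(factors.reindex(counts.samples), axis=1)
    arr = norm.to_numpy(dtype=float)
    ss = np.zeros(arr.shape[0])
    total_df = 0
    for stage in stages.unique():
        cols = [i for i, s in enumerate(stages) if s == stage]
        sub = arr[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        total_df += len(cols) - 1
    s2 = ss / total_df
    m = arr.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - m) / m**2
    raw = np.where(np.isfinite(raw), raw, DISPERSION_FLOOR)
    raw = np.maximum(raw, DISPERSION_FLOOR)
    med = float(np.median(raw))
    shrunk = np.exp(0.5 * (np.log(raw) + np.log(med)))
    shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    return pd.Series(shrunk, index=counts.genes, name="dispersion")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotone non-decreasing from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(n)
    out[order] = ranked
    return out


def de_test(
    counts: CountMatrix,
    comparison: str,
    factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Wald test of the later stage against the earlier stage.

    Returns one row per gene with columns ``log2fc`` (later over earlier),
    ``p``, ``padj``, ``is_deg``, ``up_stage``.  Genes with zero counts in
    every sample of both groups get p = padj = 1 (kept for alignment).
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    earlier, later = COMPARISONS[comparison]
    if factors is None:
        factors = size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors)
    norm = counts.counts.div(factors.reindex(counts.samples), axis=1)
    cols_e = counts.samples_for_stage(earlier)
    cols_l = counts.samples_for_stage(later)
    if len(cols_e) < 2 or len(cols_l) < 2:
        raise ValueError("both stages need at least two replicates")
    alpha = dispersion.reindex(counts.genes).to_numpy()
    mu_e = norm[cols_e].mean(axis=1).to_numpy()
    mu_l = norm[cols_l].mean(axis=1).to_numpy()
    log2fc = np.log2(mu_l + 0.5) - np.log2(mu_e + 0.5)
    # delta method: var(log2(mean + 0.5)) ~= var(mean) / ((mean+0.5) ln2)^2
    var_e = (mu_e + alpha * mu_e**2) / len(cols_e)
    var_l = (mu_l + alpha * mu_l**2) / len(cols_l)
    se2 = var_e / ((mu_e + 0.5) * LN2) ** 2 + var_l / ((mu_l + 0.5) * LN2) ** 2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    all_zero = (mu_e == 0) & (mu_l == 0)
    p = np.where(all_zero, 1.0, p)
    padj = bh_adjust(p)
    is_deg = thresholds.passes(log2fc, padj)
    up_stage = np.where(
        is_deg & (log2fc > 0), later, np.where(is_deg & (log2fc < 0), earlier, "none")
    )
    return pd.DataFrame(
        {
            "gene": counts.genes,
            "comparison": comparison,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "is_deg": is_deg,
            "up_stage": up_stage,
        }
    ).set_index("gene")


@dataclass
class DegSets:
    """Up-regulated gene sets per (comparison, stage) plus the DEG union."""

    up: dict[tuple[str, str], set[str]]
    union: set[str]
    per_comparison: dict[str, set[str]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.union)


def deg_sets(results: dict[str, pd.DataFrame]) -> DegSets:
    """Partition DEGs by up-stage and collect the clustering input union."""
    up: dict[tuple[str, str], set[str]] = {}
    per_comparison: dict[str, set[str]] = {}
    union: set[str] = set()
    for comparison, res in results.items():
        degs = res[res["is_deg"]]
        per_comparison[comparison] = set(degs.index)
        union |= set(degs.index)
        for stage in COMPARISONS[comparison]:
            up[(comparison, stage)] = set(degs.index[degs["up_stage"] == stage])
    return DegSets(up=up, union=union, per_comparison=per_comparison)


def up_stages(results: dict[str, pd.DataFrame], gene: str) -> set[str]:
    """Stages in which a gene is up-regulated, over all comparisons."""
    out = set()
    for res in results.values():
        if gene in res.index and res.loc[gene, "is_deg"]:
            out.add(res.loc[gene, "up_stage"])
    out.discard("none")
    return out
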