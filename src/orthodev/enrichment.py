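"""Hypergeometric over-representation of flat annotation term sets.

One upper-tail hypergeometric test per term with at least one query hit,
BH-adjusted over the tested terms.  Terms are flat sets (no ontology
hierarchy propagation); the default population is the annotated gene
universe supplied by the caller.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def hypergeom_upper(x: int, n: int, query: int, population: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(population, n, query).

    ``x``: query genes carrying the term, ``n``: population genes carrying
    the term.
    """
    if not (0 <= x <= min(n, query)) or not (x <= n <= population) or query > population:
        raise ValueError(
            f"inconsistent counts: x={x}, n={n}, query={query}, population={population}"
        )
    return float(stats.hypergeom.sf(x - 1, population, n, query))


def enrich(
    query: set[str],
    annotations: pd.DataFrame,
    population: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term over-representation in a query gene set.

    ``annotations`` is a two-column frame (gene, term), one row per pair.
    The population defaults to all annotated genes; the query must be a
    subset of it.  Terms with no query hit are not tested (this sets the
    BH denominator).  Results are sorted by padj then term id.
    """
    ann = annotations.rename(
        columns={annotations.columns[0]: "gene", annotations.columns[1]: "term"}
    )
    if population is None:
        population = set(ann["gene"])
    if not population:
        raise ValueError("empty population")
    if not query <= population:
        extra = sorted(query - population)[0]
        raise ValueError(f"query gene {extra!r} not in population")
    ann = ann[ann["gene"].isin(population)]
    pop_size = len(population)
    query_size = len(query)
    term_genes = ann.groupby("term")["gene"].agg(set)
    rows = []
    for term, genes in term_genes.items():
        x = len(genes & query)
        if x == 0:
            continue
        n = len(genes)
        rows.append(
            {
                "term": term,
                "x": x,
                "n": n,
                "query_size": query_size,
                "population_size": pop_size,
                "p": hypergeom_upper(x, n, query_size, pop_size),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "x", "n", "query_size", "population_size", "p"]
    )
    if len(result):
        result["padj"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["padj"] < alpha
        result = result.sort_values(["padj", "term"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        result["padj"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
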