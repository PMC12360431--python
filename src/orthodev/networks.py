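"""Bait-gene correlation subnetworks and cross-species comparison.

A bait (query) gene's Pearson correlation profile against all genes of its
species is thresholded either at empirical quantiles of the profile
(percentile mode) or at a fixed |PCC| cutoff (absolute mode).  Edge partners
are grouped into homolog families via the orthogroups, and two bait
networks are compared at the family level (presence and correlation sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .homology import HomologySet

MIN_VALUES_FOR_QUANTILES = 20


def pcc_profile(bait: str, expr: ExpressionMatrix) -> pd.Series:
    """Pearson correlation of every gene against the bait.

    Zero-variance genes are dropped; a constant bait is an error.
    """
    if bait not in expr.genes:
        raise KeyError(f"bait {bait!r} not in expression matrix")
    arr = expr.values.to_numpy(dtype=float)
    b = expr.values.loc[bait].to_numpy(dtype=float)
    if b.std() == 0:
        raise ValueError(f"bait {bait!r} has zero variance")
    centered = arr - arr.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.sqrt((centered**2).sum(axis=1)) * np.sqrt((bc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered @ bc) / denom
    out = pd.Series(r, index=expr.genes, name="pcc")
    return out[np.isfinite(out)]


def percentile_cutoffs(
    pcc_values, lower_rank: float = 0.05, upper_rank: float = 0.95
) -> tuple[float, float]:
    """Empirical-quantile cutoffs (linear interpolation) of a PCC profile."""
    vals = np.asarray(pd.Series(pcc_values).dropna(), dtype=float)
    if vals.size < MIN_VALUES_FOR_QUANTILES:
        raise ValueError(
            f"need at least {MIN_VALUES_FOR_QUANTILES} finite correlations"
        )
    lo = float(np.quantile(vals, lower_rank, method="linear"))
    hi = float(np.quantile(vals, upper_rank, method="linear"))
    return lo, hi


def absolute_cutoffs(threshold: float = 0.8) -> tuple[float, float]:
    """Fixed |PCC| > t cutoffs, for figure-style networks."""
    return -threshold, threshold


@dataclass
class BaitNetwork:
    bait: str
    edges: pd.DataFrame  # partner, pcc, sign
    cutoffs: tuple[float, float]
    families: dict[str, str] | None = None  # partner -> family id

    @property
    def partners(self) -> list[str]:
        return list(self.edges["partner"])


def build_network(
    bait: str, expr: ExpressionMatrix, cutoffs: tuple[float, float]
) -> BaitNetwork:
    """Edges to all genes at or beyond the cutoffs; the bait is excluded."""
    lo, hi = cutoffs
    if lo > hi:
        raise ValueError("cutoffs must be ordered (negative <= positive)")
    profile = pcc_profile(bait, expr).drop(index=bait, errors="ignore")
    keep = profile[(profile >= hi) | (profile <= lo)]
    edges = pd.DataFrame(
        {
            "partner": keep.index,
            "pcc": keep.to_numpy(),
            "sign": np.where(keep.to_numpy() >= hi, "positive", "negative"),
        }
    ).reset_index(drop=True)
    return BaitNetwork(bait=bait, edges=edges, cutoffs=(lo, hi))


def annotate_families(network: BaitNetwork, hs: HomologySet) -> dict[str, str]:
    """Group partners into homolog families (orthogroup id or singleton)."""
    g2g = hs.gene_to_group()
    families = {
        p: g2g.get(p, f"singleton:{p}") for p in network.edges["partner"]
    }
    network.families = families
    return families


@dataclass
class NetworkComparison:
    shared: pd.DataFrame  # family, sign_a, sign_b, concordant
    unique_a: list[str]
    unique_b: list[str]
    same_species: bool = False

    @property
    def n_concordant(self) -> int:
        return int(self.shared["concordant"].sum())

    @property
    def n_discordant(self) -> int:
        return int(len(self.shared) - self.n_concordant)


def _family_signs(network: BaitNetwork) -> dict[str, str]:
    if network.families is None:
        raise ValueError("annotate_families must run before comparison")
    signs: dict[str, set[str]] = {}
    for partner, pcc, sign in network.edges[["partner", "pcc", "sign"]].itertuples(
        index=False
    ):
        fam = network.families[partner]
        signs.setdefault(fam, set()).add(sign)
    return {
        fam: (next(iter(s)) if len(s) == 1 else "mixed") for fam, s in signs.items()
    }


def compare_networks(
    net_a: BaitNetwork, net_b: BaitNetwork, hs: HomologySet
) -> NetworkComparison:
    """Family-level comparison of two bait networks.

    Shared families are listed with per-network sign and a concordance flag
    (equal sign in both networks).  Same-species comparisons (the isoform
    use case) are allowed and flagged.
    """
    if net_a.families is None:
        annotate_families(net_a, hs)
    if net_b.families is None:
        annotate_families(net_b, hs)
    signs_a = _family_signs(net_a)
    signs_b = _family_signs(net_b)
    shared = sorted(set(signs_a) & set(signs_b))
    rows = [
        {
            "family": fam,
            "sign_a": signs_a[fam],
            "sign_b": signs_b[fam],
            "concordant": signs_a[fam] == signs_b[fam],
        }
        for fam in shared
    ]
    sp_a = net_a.bait.split("|", 1)[0]
    sp_b = net_b.bait.split("|", 1)[0]
    return NetworkComparison(
        shared=pd.DataFrame(rows, columns=["family", "sign_a", "sign_b", "concordant"]),
        unique_a=sorted(set(signs_a) - set(signs_b)),
        unique_b=sorted(set(signs_b) - set(signs_a)),
        same_species=sp_a == sp_b,
    )


def to_graphml(network: BaitNetwork, path) -> None:
    """Optional GraphML export for network viewers."""
    import networkx as nx

    g = nx.Graph()
    g.add_node(network.bait, role="bait")
    for partner, pcc, sign in network.edges[["partner", "pcc", "sign"]].itertuples(
        index=False
    ):
        fam = (network.families or {}).get(partner, "")
        g.add_node(partner, role="partner", family=fam)
        g.add_edge(network.bait, partner, pcc=float(pcc), sign=sign)
    nx.write_graphml(g, path)
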