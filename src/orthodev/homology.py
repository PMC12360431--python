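"""Orthogroup parsing, relationship classification, and cross-species
ortholog expression comparisons.

Orthogroups are read from OrthoMCL "groups" text files (one group per line,
``GROUPID: taxon|gene taxon|gene ...``).  Relationship classes are defined
for a species pair (A, B): one2one, one2many_A (many genes in A),
one2many_B, many2many.  Downstream comparisons (shared DE, synchrony,
stage/cluster overlap, gastrula core modules) operate on one-to-one pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import STAGES, ARCHETYPES
from .diffexpr import up_stages
from .report import percentage

RELATIONSHIP_CLASSES = ("one2one", "one2many_A", "one2many_B", "many2many")


@dataclass
class HomologySet:
    """Orthogroups over a species pair plus in-paralog pair lists."""

    species: tuple[str, str]
    groups: dict[str, dict[str, list[str]]]  # group -> species -> genes
    paralog_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def relationship(self, group_id: str) -> str:
        a, b = self.species
        members = self.groups[group_id]
        na, nb = len(members.get(a, [])), len(members.get(b, []))
        if na == 0 or nb == 0:
            return "single_species"
        if na == 1 and nb == 1:
            return "one2one"
        if nb == 1:
            return "one2many_A"
        if na == 1:
            return "one2many_B"
        return "many2many"

    def relationships(self) -> pd.Series:
        return pd.Series(
            {g: self.relationship(g) for g in self.groups}, name="class"
        )

    def ortholog_pairs(self) -> pd.DataFrame:
        """All cross-species gene pairs within each two-species group."""
        a, b = self.species
        rows = []
        for gid in sorted(self.groups):
            members = self.groups[gid]
            cls = self.relationship(gid)
            if cls == "single_species":
                continue
            for ga in members[a]:
                for gb in members[b]:
                    rows.append(
                        {"group": gid, "gene_a": ga, "gene_b": gb, "class": cls}
                    )
        return pd.DataFrame(rows, columns=["group", "gene_a", "gene_b", "class"])

    def one2one_pairs(self) -> pd.DataFrame:
        pairs = self.ortholog_pairs()
        return pairs[pairs["class"] == "one2one"].reset_index(drop=True)

    def gene_to_group(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for gid, members in self.groups.items():
            for genes in members.values():
                for g in genes:
                    out[g] = gid
        return out


def parse_groups(path, species: tuple[str, str] | None = None) -> HomologySet:
    """Parse an OrthoMCL groups file.

    Malformed lines raise with their line number; members must carry a
    ``taxon|`` prefix.  If ``species`` is not given, the two taxa are
    inferred (sorted) from the file.
    """
    groups: dict[str, dict[str, list[str]]] = {}
    taxa: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"line {lineno}: missing 'GROUPID:' prefix")
            gid, _, rest = line.partition(":")
            gid = gid.strip()
            members: dict[str, list[str]] = {}
            for token in rest.split():
                if "|" not in token:
                    raise ValueError(
                        f"line {lineno}: member {token!r} lacks 'taxon|' prefix"
                    )
                taxon = token.split("|", 1)[0]
                taxa.add(taxon)
                members.setdefault(taxon, []).append(token)
            if gid in groups:
                raise ValueError(f"line {lineno}: duplicate group id {gid!r}")
            groups[gid] = members
    if species is None:
        if len(taxa) != 2:
            raise ValueError(f"expected two taxa in groups file, found {sorted(taxa)}")
        species = tuple(sorted(taxa))  # type: ignore[assignment]
    return HomologySet(species=species, groups=groups)


def write_groups(hs: HomologySet, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(hs.groups):
            members = hs.groups[gid]
            tokens = []
            for sp in hs.species:
                tokens.extend(members.get(sp, []))
            fh.write(f"{gid}: {' '.join(tokens)}\n")


def relationship_summary(hs: HomologySet) -> dict:
    """Counts and percentages per relationship class, over groups and pairs."""
    rel = hs.relationships()
    rel = rel[rel != "single_species"]
    pairs = hs.ortholog_pairs()
    n_groups = int(len(rel))
    counts = {cls: int((rel == cls).sum()) for cls in RELATIONSHIP_CLASSES}
    percents = {
        cls: percentage(counts[cls], n_groups, 1) if n_groups else 0.0
        for cls in RELATIONSHIP_CLASSES
    }
    return {
        "n_groups": n_groups,
        "n_pairs": int(len(pairs)),
        "group_counts": counts,
        "group_percent": percents,
    }


def shared_de_partition(
    pairs: pd.DataFrame, deg_a: set[str], deg_b: set[str]
) -> dict[str, pd.DataFrame]:
    """Partition one-to-one pairs by species-level DE status.

    A species-level DEG is any gene in the union of DEGs over both
    comparisons.  Every pair lands in exactly one of both / only_a /
    only_b / neither.
    """
    in_a = pairs["gene_a"].isin(deg_a)
    in_b = pairs["gene_b"].isin(deg_b)
    return {
        "both": pairs[in_a & in_b],
        "only_a": pairs[in_a & ~in_b],
        "only_b": pairs[~in_a & in_b],
        "neither": pairs[~in_a & ~in_b],
    }


@dataclass
class SynchronyStats:
    comparison: str
    same_by_stage: dict[str, int]
    n_asynchronous: int

    @property
    def n_same(self) -> int:
        return sum(self.same_by_stage.values())

    @property
    def percent_same(self) -> int:
        total = self.n_same + self.n_asynchronous
        return int(round(100 * self.n_same / total)) if total else 0


def synchrony_stats(
    pairs: pd.DataFrame,
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    comparison: str,
) -> SynchronyStats:
    """Same-stage vs asynchronous DE among pairs both-DE in a comparison."""
    same_by_stage: dict[str, int] = {}
    n_async = 0
    up_a = results_a["up_stage"]
    up_b = results_b["up_stage"]
    deg_a = results_a["is_deg"]
    deg_b = results_b["is_deg"]
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        if not (deg_a.get(ga, False) and deg_b.get(gb, False)):
            continue
        sa, sb = up_a[ga], up_b[gb]
        if sa == sb and sa != "none":
            same_by_stage[sa] = same_by_stage.get(sa, 0) + 1
        else:
            n_async += 1
    return SynchronyStats(
        comparison=comparison, same_by_stage=same_by_stage, n_asynchronous=n_async
    )


def stage_overlap_matrix(
    results_a: dict[str, pd.DataFrame],
    results_b: dict[str, pd.DataFrame],
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Stage x stage counts of pairs up in (sA, sB) in any comparison."""
    mat = pd.DataFrame(0, index=list(STAGES), columns=list(STAGES), dtype=int)
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        for sa in up_stages(results_a, ga):
            for sb in up_stages(results_b, gb):
                mat.loc[sa, sb] += 1
    return mat


@dataclass
class ClusterOverlap:
    matrix: pd.DataFrame  # 6x6 archetype counts, A rows x B cols
    n_pairs: int  # both-DE pair count (denominator)
    n_unassigned: int  # both-DE pairs with an unclustered member

    @property
    def trace(self) -> int:
        return int(np.trace(self.matrix.to_numpy()))

    @property
    def percent_same(self) -> float:
        return percentage(self.trace, self.n_pairs, 1) if self.n_pairs else 0.0


def cluster_overlap(
    pairs: pd.DataFrame,
    labels_a: pd.Series,
    labels_b: pd.Series,
    n_de_pairs: int | None = None,
) -> ClusterOverlap:
    """6x6 archetype overlap of one-to-one pairs (A archetype x B archetype).

    ``labels_*`` map clustered genes to archetype labels.  Pairs with an
    unclustered member are excluded from the matrix but counted.  The
    same-archetype percent uses ``n_de_pairs`` (the both-DE pair count) as
    denominator, defaulting to matrix total + unassigned.
    """
    mat = pd.DataFrame(0, index=list(ARCHETYPES), columns=list(ARCHETYPES), dtype=int)
    unassigned = 0
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        ca = labels_a.get(ga)
        cb = labels_b.get(gb)
        if ca is None or cb is None or pd.isna(ca) or pd.isna(cb):
            unassigned += 1
            continue
        mat.loc[ca, cb] += 1
    if n_de_pairs is None:
        n_de_pairs = int(mat.to_numpy().sum()) + unassigned
    return ClusterOverlap(matrix=mat, n_pairs=n_de_pairs, n_unassigned=unassigned)


def gastrula_core(
    pairs: pd.DataFrame,
    results_a: dict[str, pd.DataFrame],
    results_b: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Pairs whose genes are up-regulated at G in both species.

    "Up at G" means up_stage = G in at least one comparison for that
    species.
    """
    keep = [
        "G" in up_stages(results_a, ga) and "G" in up_stages(results_b, gb)
        for ga, gb in zip(pairs["gene_a"], pairs["gene_b"])
    ]
    return pairs[np.array(keep, dtype=bool)].reset_index(drop=True)


G_STAGE_ARCHETYPES = frozenset({"C2", "C3", "C4"})


def g_cluster_core(
    pairs: pd.DataFrame, labels_a: pd.Series, labels_b: pd.Series
) -> pd.DataFrame:
    """Pairs with both members in the gastrula-elevated archetypes C2-C4."""
    keep = [
        labels_a.get(ga) in G_STAGE_ARCHETYPES
        and labels_b.get(gb) in G_STAGE_ARCHETYPES
        for ga, gb in zip(pairs["gene_a"], pairs["gene_b"])
    ]
    return pairs[np.array(keep, dtype=bool)].reset_index(drop=True)
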