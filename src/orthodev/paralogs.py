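"""In-paralog pair classification and expression-divergence scoring.

Pairs are classified per comparison by DE status (P1 both DE, P2 exactly
one, P3 neither) and by cluster membership (Pk1 both clustered, Pk2 one,
Pk3 neither), then scored for pattern similarity (same up-stage for P1,
same archetype for Pk1) and replicate-level Pearson correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

P_CLASSES = ("P1", "P2", "P3")
PK_CLASSES = ("Pk1", "Pk2", "Pk3")


def _pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs[["gene1", "gene2"]].copy()
    return pd.DataFrame(pairs, columns=["gene1", "gene2"])


def classify_p(pairs, de_results: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Label each pair P1/P2/P3 by DE status in one comparison."""
    df = _pairs_frame(pairs)
    is_deg = de_results["is_deg"]
    for col in ("gene1", "gene2"):
        missing = df[col][~df[col].isin(is_deg.index)]
        if len(missing):
            raise KeyError(f"gene {missing.iloc[0]!r} absent from DE table")
    d1 = is_deg.reindex(df["gene1"]).to_numpy(dtype=bool)
    d2 = is_deg.reindex(df["gene2"]).to_numpy(dtype=bool)
    n_de = d1.astype(int) + d2.astype(int)
    df["comparison"] = comparison
    df["p_class"] = np.select([n_de == 2, n_de == 1], ["P1", "P2"], default="P3")
    up = de_results["up_stage"]
    df["up1"] = up.reindex(df["gene1"]).to_numpy()
    df["up2"] = up.reindex(df["gene2"]).to_numpy()
    df["same_pattern"] = (df["p_class"] == "P1") & (df["up1"] == df["up2"])
    return df


def classify_pk(pairs, archetype_labels: pd.Series) -> pd.DataFrame:
    """Label each pair Pk1/Pk2/Pk3 by cluster membership.

    ``archetype_labels`` maps clustered genes to archetypes; genes absent
    from the index are unclustered.
    """
    df = _pairs_frame(pairs)
    c1 = df["gene1"].map(archetype_labels)
    c2 = df["gene2"].map(archetype_labels)
    n_in = c1.notna().astype(int) + c2.notna().astype(int)
    df["pk_class"] = np.select([n_in == 2, n_in == 1], ["Pk1", "Pk2"], default="Pk3")
    df["cluster1"] = c1
    df["cluster2"] = c2
    df["same_cluster"] = (df["pk_class"] == "Pk1") & (c1 == c2)
    return df


def class_counts(df: pd.DataFrame, column: str) -> dict[str, int]:
    classes = P_CLASSES if column == "p_class" else PK_CLASSES
    vc = df[column].value_counts()
    return {c: int(vc.get(c, 0)) for c in classes}


def pattern_similarity(classified: pd.DataFrame) -> float:
    """Fraction of P1 (or Pk1) pairs with the same pattern.

    For a P-classified frame this is the same up-stage in the comparison;
    for a Pk-classified frame, the same archetype label.
    """
    if "p_class" in classified.columns:
        sub = classified[classified["p_class"] == "P1"]
        flag = "same_pattern"
    else:
        sub = classified[classified["pk_class"] == "Pk1"]
        flag = "same_cluster"
    if len(sub) == 0:
        return float("nan")
    return float(sub[flag].mean())


def pair_pcc(
    pairs, expr: ExpressionMatrix, threshold: float = 0.9
) -> tuple[pd.Series, float]:
    """Per-pair Pearson correlation over the species' samples.

    Pairs with an absent or zero-variance member get NaN and drop out of
    the high-correlation fraction's denominator.
    """
    df = _pairs_frame(pairs)
    values = expr.values
    out = np.full(len(df), np.nan)
    for i, (g1, g2) in enumerate(zip(df["gene1"], df["gene2"])):
        if g1 not in values.index or g2 not in values.index:
            continue
        x = values.loc[g1].to_numpy(dtype=float)
        y = values.loc[g2].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        out[i] = np.corrcoef(x, y)[0, 1]
    pcc = pd.Series(out, index=df.index, name="pcc")
    defined = pcc.dropna()
    frac = float((defined > threshold).mean()) if len(defined) else float("nan")
    return pcc, frac
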