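"""K-means coexpression clustering of DEGs and archetype labeling.

Each species' DEG union is clustered on per-gene standardized VST profiles
(k-means++, ten restarts, up to 1,000 iterations).  For k = 6 the clusters
are mapped one-to-one onto the six stage archetypes (C1..C6) by maximizing
total cosine similarity between z-scored centroid stage means and z-scored
archetype templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .containers import ARCHETYPE_UP, ARCHETYPES, STAGES, ExpressionMatrix


def standardize_genes(
    vst: ExpressionMatrix, genes
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each gene's profile across the species' samples.

    Zero-variance genes become all-zero rows and are returned in the flagged
    list (they are excluded from clustering downstream).
    """
    genes = pd.Index(genes)
    missing = genes.difference(vst.genes)
    if len(missing):
        raise KeyError(f"gene {missing[0]!r} not in expression matrix")
    sub = vst.values.loc[genes]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    flagged = list(sub.index[sd == 0])
    sd_safe = sd.replace(0, 1.0)
    z = sub.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[flagged] = 0.0
    return z, flagged


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> cluster index (1..k)
    centroids: pd.DataFrame  # k x samples
    inertia: float
    design: pd.DataFrame
    archetype_map: dict[int, str] | None = None
    excluded: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def archetype_labels(self) -> pd.Series:
        """Per-gene archetype label (requires an archetype map)."""
        if self.archetype_map is None:
            raise ValueError("archetypes not assigned yet")
        return self.labels.map(self.archetype_map)


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int = 6,
    max_iter: int = 1000,
    n_restarts: int = 10,
    seed: int = 0,
    design: pd.DataFrame | None = None,
) -> ClusterAssignment:
    """Best-of-``n_restarts`` k-means++ clustering, deterministic given seed."""
    if len(matrix) < k:
        raise ValueError(f"need at least {k} genes to form {k} clusters")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
    ).fit(matrix.to_numpy())
    labels = pd.Series(km.labels_ + 1, index=matrix.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_, index=range(1, k + 1), columns=matrix.columns
    )
    return ClusterAssignment(
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        design=design if design is not None else pd.DataFrame(),
    )


def elbow_curve(
    matrix: pd.DataFrame, k_max: int, seed: int = 0, n_restarts: int = 10
) -> tuple[pd.DataFrame, int]:
    """Total within-cluster SS for k = 1..k_max and the elbow suggestion.

    The suggested k maximizes the second difference of the curve on the
    log scale (relative curvature), which makes the suggestion independent
    of the data's overall scale and robust to the steep early drops every
    decreasing WSS curve shows.
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    if len(matrix) < k_max:
        raise ValueError("fewer genes than k_max")
    rows = []
    for k in range(1, k_max + 1):
        km = KMeans(
            n_clusters=k, n_init=n_restarts, max_iter=1000, random_state=seed
        ).fit(matrix.to_numpy())
        rows.append({"k": k, "wss": float(km.inertia_)})
    curve = pd.DataFrame(rows)
    wss = curve["wss"].to_numpy()
    if len(wss) >= 3:
        log_wss = np.log(np.maximum(wss, 1e-12 * max(wss[0], 1.0)))
        second = log_wss[:-2] - 2 * log_wss[1:-1] + log_wss[2:]
        suggested = int(curve["k"].iloc[1 + int(np.argmax(second))])
    else:
        suggested = 2
    return curve, suggested


def _zscore_rows(arr: np.ndarray) -> np.ndarray:
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (arr - mean) / sd


def archetype_templates() -> pd.DataFrame:
    """The six binary up-stage templates over (PC, G, S)."""
    rows = {
        label: [1.0 if s in up else 0.0 for s in STAGES]
        for label, up in ARCHETYPE_UP.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(STAGES))


def assign_archetypes(
    assignment: ClusterAssignment, design: pd.DataFrame | None = None
) -> dict[int, str]:
    """Optimal one-to-one mapping of the six clusters onto C1..C6.

    Centroid stage means are z-scored and scored against z-scored templates
    by cosine similarity; the bijection maximizing total similarity is
    chosen (ties resolved deterministically by the Hungarian algorithm).
    """
    if assignment.k != 6:
        raise ValueError("archetype mapping is defined only for k = 6")
    if design is None:
        design = assignment.design
    stage_means = np.column_stack(
        [
            assignment.centroids[
                [s for s in assignment.centroids.columns if design.loc[s, "stage"] == st]
            ]
            .mean(axis=1)
            .to_numpy()
            for st in STAGES
        ]
    )
    cz = _zscore_rows(stage_means)
    tz = _zscore_rows(archetype_templates().to_numpy())
    # cosine similarity matrix clusters x templates
    cn = cz / np.linalg.norm(cz, axis=1, keepdims=True)
    tn = tz / np.linalg.norm(tz, axis=1, keepdims=True)
    sim = cn @ tn.T
    rows, cols = linear_sum_assignment(-sim)
    mapping = {int(r) + 1: ARCHETYPES[c] for r, c in zip(rows, cols)}
    assignment.archetype_map = mapping
    return mapping
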