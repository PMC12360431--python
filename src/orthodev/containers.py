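"""Core in-memory containers shared across the pipeline.

Expression data live in pandas DataFrames (genes x samples) wrapped together
with a sample design table.  Sample columns follow the
``<species>_<stage>_<replicate>`` naming convention used by all readers and
writers in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Developmental stages in chronological order: prawn chip (flattened
#: blastula), gastrula, sphere (early larva).
STAGES: tuple[str, ...] = ("PC", "G", "S")

#: The six stage-wise up-regulation archetypes.  Each maps to the set of
#: stages in which genes of that archetype are up-regulated.
ARCHETYPE_UP: dict[str, tuple[str, ...]] = {
    "C1": ("PC",),
    "C2": ("PC", "G"),
    "C3": ("G",),
    "C4": ("G", "S"),
    "C5": ("S",),
    "C6": ("PC", "S"),
}

ARCHETYPES: tuple[str, ...] = tuple(ARCHETYPE_UP)

#: Label for genes with no stage-dependent expression.
FLAT = "flat"

#: Consecutive-stage comparisons, mapping to (earlier, later) stage.
COMPARISONS: dict[str, tuple[str, str]] = {
    "PCvsG": ("PC", "G"),
    "GvsS": ("G", "S"),
}


def sample_name(species: str, stage: str, replicate: int) -> str:
    return f"{species}_{stage}_{replicate}"


def make_design(
    species: str,
    stages: tuple[str, ...] = STAGES,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Build a sample design table for one species.

    Returns a DataFrame indexed by sample id with columns
    ``species``, ``stage``, ``replicate``.
    """
    rows = []
    for stage in stages:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": sample_name(species, stage, rep),
                    "species": species,
                    "stage": stage,
                    "replicate": rep,
                }
            )
    design = pd.DataFrame(rows).set_index("sample")
    return design


def design_from_columns(columns) -> pd.DataFrame:
    """Recover a design table from ``<species>_<stage>_<rep>`` column names."""
    rows = []
    for col in columns:
        parts = str(col).rsplit("_", 2)
        if len(parts) != 3 or parts[1] not in STAGES:
            raise ValueError(f"sample name {col!r} is not <species>_<stage>_<rep>")
        rows.append(
            {
                "sample": col,
                "species": parts[0],
                "stage": parts[1],
                "replicate": int(parts[2]),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def _check_design(values: pd.DataFrame, design: pd.DataFrame) -> None:
    if list(values.columns) != list(design.index):
        raise ValueError("sample columns do not match the design table")
    if design[["species", "stage", "replicate"]].duplicated().any():
        raise ValueError("duplicate (species, stage, replicate) in design")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with a sample design."""

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        _check_design(self.counts, self.design)
        arr = self.counts.to_numpy()
        if arr.size == 0:
            self.counts = self.counts.astype(np.int64)
        elif not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_for_stage(self, stage: str) -> list[str]:
        if stage not in set(self.design["stage"]):
            raise KeyError(f"stage {stage!r} absent from design")
        return list(self.design.index[self.design["stage"] == stage])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="gene")
        counts.columns.name = "sample"
        return cls(counts=counts, design=design_from_columns(counts.columns))


@dataclass
class ExpressionMatrix:
    """Non-negative real expression values (TPM or VST), genes x samples."""

    values: pd.DataFrame
    design: pd.DataFrame
    kind: str = "TPM"

    def __post_init__(self) -> None:
        if self.kind not in ("TPM", "VST"):
            raise ValueError(f"unknown expression kind {self.kind!r}")
        _check_design(self.values, self.design)
        if self.kind == "TPM":
            sums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1e6, atol=1e-3):
                raise ValueError("TPM columns must sum to 1e6")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_for_stage(self, stage: str) -> list[str]:
        if stage not in set(self.design["stage"]):
            raise KeyError(f"stage {stage!r} absent from design")
        return list(self.design.index[self.design["stage"] == stage])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene")
        values.columns.name = "sample"
        return cls(values=values, design=design_from_columns(values.columns), kind=kind)
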