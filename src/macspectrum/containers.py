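"""Core in-memory containers shared by every analysis stage.

The pipeline operates on a gene-by-sample matrix of log2 intensities plus a
sample annotation table (the *design*): one row per array with its stimulation
condition, harvest time, donor, and a flag marking the unstimulated baseline
condition that anchors the activation spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("condition", "time_h", "donor", "is_baseline")


def validate_design(design: pd.DataFrame) -> None:
    """Check the design-table invariants.

    Exactly one condition carries ``is_baseline=True`` (uniformly across its
    samples), every condition has at least two replicates, and sample ids
    (the index) are unique.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design.index.has_duplicates:
        dups = design.index[design.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    base_flags = design.groupby("condition", observed=True)["is_baseline"].agg(["any", "all"])
    inconsistent = base_flags.index[base_flags["any"] & ~base_flags["all"]].tolist()
    if inconsistent:
        raise ValueError(f"is_baseline not uniform within condition(s): {inconsistent}")
    n_base = int(base_flags["all"].sum())
    if n_base != 1:
        raise ValueError(f"exactly one baseline condition required, found {n_base}")
    sizes = design.groupby("condition", observed=True).size()
    small = sizes.index[sizes < 2].tolist()
    if small:
        raise ValueError(f"condition(s) with fewer than 2 samples: {small}")


def baseline_condition(design: pd.DataFrame) -> str:
    """Return the label of the (unique) baseline condition."""
    labels = design.loc[design["is_baseline"], "condition"].unique()
    if len(labels) != 1:
        raise ValueError(f"expected one baseline condition, found {list(labels)}")
    return str(labels[0])


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities with sample annotations.

    Attributes
    ----------
    values : pd.DataFrame
        Rows indexed by gene id, columns by sample id, finite floats.
    design : pd.DataFrame
        Indexed by sample id with columns ``condition, time_h, donor,
        is_baseline``; column order matches ``values``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        validate_design(self.design)
        if list(self.values.columns) != list(self.design.index):
            # align rather than fail when it is a pure reordering
            if set(self.values.columns) != set(self.design.index):
                raise ValueError("values columns and design index name different samples")
            self.design = self.design.loc[self.values.columns]
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values contain NaN/inf; impute or filter upstream")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design["condition"]:
            seen.setdefault(str(c))
        return list(seen)

    @property
    def baseline(self) -> str:
        return baseline_condition(self.design)

    def samples_of(self, condition: str) -> list[str]:
        mask = self.design["condition"] == condition
        return list(self.design.index[mask])

    def condition_means(self) -> pd.DataFrame:
        """Genes x conditions matrix of per-condition mean log2 intensity."""
        cols = {c: self.values[self.samples_of(c)].mean(axis=1) for c in self.conditions}
        return pd.DataFrame(cols, index=self.values.index)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene id(s): {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.design.copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.design.copy())


@dataclass
class SpectrumVector:
    """Mean 3-D displacement of one condition cluster from the baseline centroid."""

    cluster_id: int
    members: list[str]
    vector: np.ndarray  # shape (3,)
    is_baseline: bool = False

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))

    @property
    def direction(self) -> np.ndarray:
        m = self.magnitude
        if m == 0:
            return np.zeros(3)
        return self.vector / m


@dataclass
class GeneModule:
    """A coexpression module with its eigengene summary."""

    module_id: int
    genes: list[str]
    eigengene: pd.Series = field(default=None)  # per-sample score
    variance_explained: float = float("nan")
    kme: pd.Series = field(default=None)  # gene -> correlation with eigengene

    def __len__(self) -> int:
        return len(self.genes)
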