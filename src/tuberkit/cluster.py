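"""Phenetic clustering of species trait means.

Species are rows of a feature matrix of per-species measurement means
(default: all six variables; a maximum-curvature-only variant is also
used).  The dendrogram uses Euclidean distances and Ward's minimum-variance
linkage with heights on the distance scale (the Ward.D2 convention of the
major statistics packages), drawn with leaves coloured by subgenus and
exportable as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch

from .measurement import MEASUREMENT_VARIABLES

__all__ = [
    "FeatureMatrix",
    "build_feature_matrix",
    "ward_dendrogram",
    "cluster_assignments",
    "export_newick",
    "plot_dendrogram",
]

DEFAULT_VARIABLES = tuple(f"{v}_mean" for v in MEASUREMENT_VARIABLES)


@dataclass(frozen=True)
class FeatureMatrix:
    """Species-by-variables matrix of trait means with subgenus annotation."""

    data: pd.DataFrame  # index: species, columns: variables
    subgenus: pd.Series | None = None
    standardized: bool = False

    @property
    def species(self) -> list:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def build_feature_matrix(summaries: pd.DataFrame, variables=None, standardize: bool = False) -> FeatureMatrix:
    """Assemble the clustering matrix from a species-summary table.

    ``variables`` may name raw measurement variables ("max_curvature") or
    summary columns ("max_curvature_mean"); default is the six measurement
    means.  Optional z-score standardisation per column (off by default).
    """
    if variables is None:
        cols = list(DEFAULT_VARIABLES)
    else:
        if len(variables) == 0:
            raise ValueError("empty variable selection")
        cols = [v if v in summaries.columns else f"{v}_mean" for v in variables]
    if "species" in summaries.columns:
        summaries = summaries.set_index("species")
    if len(summaries) < 2:
        raise ValueError("need at least 2 species")
    missing_cols = [c for c in cols if c not in summaries.columns]
    if missing_cols:
        raise ValueError(f"summary table lacks columns {missing_cols}")
    data = summaries[cols].astype(float)
    bad = data.isna().any(axis=1)
    if bad.any():
        raise ValueError(f"missing values for species: {list(data.index[bad])}")
    if standardize:
        data = (data - data.mean()) / data.std(ddof=1)
    subg = summaries["subgenus"] if "subgenus" in summaries.columns else None
    return FeatureMatrix(data=data, subgenus=subg, standardized=standardize)


def ward_dendrogram(matrix: FeatureMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Agglomerative merge history under Ward's criterion (scipy linkage
    format, heights on the Euclidean distance scale).

    Deterministic given the matrix; scipy breaks ties by smallest cluster
    index.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < 2:
        raise ValueError("need at least 2 rows to cluster")
    return sch.linkage(X, method="ward")


def cluster_assignments(linkage: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels (1..k) from a cut of the dendrogram into k clusters."""
    return sch.fcluster(linkage, t=k, criterion="maxclust")


def _needs_quoting(label: str) -> bool:
    return any(c in label for c in " ():,;[]'")


def _quote(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_newick(linkage: np.ndarray, labels) -> str:
    """Newick string with branch lengths equal to merge-height differences."""
    n = linkage.shape[0] + 1
    if len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    tree = sch.to_tree(linkage)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{_quote(str(labels[node.id]))}:{node.dist:.10g}"
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            sub = rec(child)
            # rec() writes the child's own height; replace with the branch length
            name, _, _ = sub.rpartition(":")
            parts.append(f"{name}:{node.dist - child.dist:.10g}")
        return f"({parts[0]},{parts[1]}):{node.dist:.10g}"

    body = rec(tree)
    name, _, _ = body.rpartition(":")
    return f"{name};"


def plot_dendrogram(
    linkage: np.ndarray,
    labels,
    subgenus=None,
    colors=None,
    ax=None,
):
    """Horizontal dendrogram with leaf labels coloured by subgenus.

    ``subgenus`` maps each label to its subgenus; default colouring is
    Behenantha red, Silene blue.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.28 * len(labels) + 1))
    sch.dendrogram(
        linkage,
        labels=list(labels),
        orientation="right",
        ax=ax,
        color_threshold=0.0,
        above_threshold_color="0.3",
    )
    if subgenus is not None:
        colors = colors or {"Behenantha": "red", "Silene": "blue"}
        lookup = dict(subgenus) if not isinstance(subgenus, dict) else subgenus
        for tick in ax.get_ymajorticklabels():
            tick.set_color(colors.get(lookup.get(tick.get_text()), "black"))
    ax.set_xlabel("Ward linkage height (Euclidean distance)")
    return ax.figure
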