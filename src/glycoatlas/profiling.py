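"""Profile scaling, Canberra dissimilarity and Ward clustering.

The atlas is explored two ways: a column z-scored matrix for heatmap
display (each glycoform on its own scale), and hierarchical clustering
of the raw absolute profiles under the Canberra distance

    d(x, y) = sum_i |x_i - y_i| / (|x_i| + |y_i|)

which is sensitive to differences among low-abundance glycoforms and
indifferent to outliers, followed by Ward agglomeration and a fixed-k
cut.  Both common Ward conventions are available: ``ward.D2`` (the
recurrence applied to squared dissimilarities, scipy's behaviour) and
``ward.D`` (applied to the dissimilarities directly, as in older R
usage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .quantification import ProfileMatrix

__all__ = [
    "ScaledMatrix",
    "ClusteringResult",
    "zscore",
    "canberra",
    "ward_cluster",
    "cut_and_purity",
    "to_newick",
]


@dataclass
class ScaledMatrix:
    """Column z-scored profile matrix (display scale)."""

    values: pd.DataFrame
    mask: pd.DataFrame
    samples: pd.DataFrame


def zscore(matrix: ProfileMatrix) -> ScaledMatrix:
    """Column z-scores with sample SD (n-1 denominator).

    Zeros from non-detections participate in the mean and SD, matching
    heatmap convention.  Zero-variance columns map to all-zero columns.
    Requires at least two samples.
    """
    if matrix.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    v = matrix.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    z = (v - mean).div(sd.where(sd > 0, np.inf), axis=1)
    return ScaledMatrix(z, matrix.mask.copy(), matrix.samples.copy())


def canberra(x, y) -> float:
    """Canberra distance; terms with x_i = y_i = 0 contribute 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    denom = np.abs(x) + np.abs(y)
    num = np.abs(x - y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / denom, 0.0)
    return float(terms.sum())


@dataclass
class ClusteringResult:
    """Ward linkage over pairwise Canberra distances.

    ``linkage`` is a scipy linkage matrix; ``labels`` the sample ids in
    input order; ``distance_matrix`` the condensed pairwise distances.
    """

    linkage: np.ndarray
    labels: list[str]
    class_labels: list[str]
    distance_matrix: np.ndarray
    method: str


def _pairwise(matrix: ProfileMatrix, distance: str) -> np.ndarray:
    v = matrix.values.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError("profile matrix contains NaN")
    if distance == "canberra":
        # scipy's canberra uses the same 0/0 -> 0 convention
        return pdist(v, metric="canberra")
    if distance == "euclidean":
        return pdist(v, metric="euclidean")
    raise ValueError(f"unknown distance {distance!r}")


def ward_cluster(
    matrix: ProfileMatrix,
    distance: str = "canberra",
    variant: str = "ward.D2",
) -> ClusteringResult:
    """Agglomerative Ward clustering over the pairwise distance matrix.

    ``ward.D2`` applies the Lance-Williams Ward recurrence to squared
    dissimilarities (scipy's ``linkage(..., 'ward')`` on a condensed
    matrix); ``ward.D`` applies it to the dissimilarities as given,
    reproduced here by clustering the square roots and squaring the
    merge heights.  Merge ties break deterministically toward the
    lowest pair index (scipy's behaviour on the condensed matrix).
    """
    if matrix.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    dist = _pairwise(matrix, distance)
    if variant == "ward.D2":
        Z = hierarchy.linkage(dist, method="ward")
    elif variant == "ward.D":
        Z = hierarchy.linkage(np.sqrt(dist), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown Ward variant {variant!r}")
    return ClusteringResult(
        linkage=Z,
        labels=list(matrix.values.index),
        class_labels=list(matrix.samples["class_label"]),
        distance_matrix=dist,
        method=f"{distance}/{variant}",
    )


def cut_and_purity(result: ClusteringResult, k: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cut the tree into *k* groups and report group purity.

    A group is pure when all its members share one class label.
    Returns (groups, report): *groups* has columns ``sample_id,
    class_label, group``; *report* one row per group with member count,
    member classes and a ``pure`` flag, plus ``attrs['n_pure']``.
    """
    n = len(result.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    assignment = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    groups = pd.DataFrame(
        {
            "sample_id": result.labels,
            "class_label": result.class_labels,
            "group": assignment,
        }
    )
    rows = []
    for group_id, sub in groups.groupby("group"):
        classes = sorted(sub["class_label"].unique())
        rows.append(
            {
                "group": group_id,
                "n_members": len(sub),
                "classes": ";".join(classes),
                "pure": len(classes) == 1,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["n_pure"] = int(report["pure"].sum())
    return groups, report


def to_newick(result: ClusteringResult) -> str:
    """Export the dendrogram as a Newick string with merge-height branch
    lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float | None) -> str:
        if node.is_leaf():
            name = result.labels[node.id]
            if parent_height is None:
                return name
            return f"{name}:{parent_height:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        if parent_height is None:
            return f"({left},{right})"
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

    return walk(tree, None) + ";"
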