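"""Ward hierarchical clustering of strains from gene presence/absence.

Strains are points in {0,1}^n_clusters; the distance is Euclidean (the
natural geometry for Ward linkage — the squared distance between two
strains is the number of clusters on which they disagree), with Jaccard
available for sensitivity analysis.  Linkage and tree cutting are
delegated to scipy; the dendrogram is exportable as Newick with merge
heights as branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .panmatrix import PanMatrix

__all__ = ["DistanceMatrix", "Dendrogram", "content_distance", "ward_linkage", "cut"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # square symmetric, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(d < 0):
            raise ValueError("negative distances")
        self.d = d

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (n-1, 4)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string; each branch length is the height difference
        between a node's merge and its parent's merge."""
        n = len(self.labels)
        names: dict[int, str] = {i: self.labels[i] for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for idx, (i, j, h, _size) in enumerate(self.linkage):
            i, j = int(i), int(j)
            node = n + idx
            left = f"{names[i]}:{h - height[i]:.10g}"
            right = f"{names[j]}:{h - height[j]:.10g}"
            names[node] = f"({left},{right})"
            height[node] = float(h)
        return names[n + len(self.linkage) - 1] + ";"


def content_distance(matrix: PanMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise strain distance from presence/absence profiles.

    Euclidean distance equals sqrt(#discordant clusters) on binary data.
    """
    X = matrix.df.to_numpy().T.astype(float)  # strains x clusters
    if X.shape[0] < 2:
        raise ValueError("need >= 2 strains")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("matrix must be binary")
    if metric not in ("euclidean", "jaccard"):
        raise ValueError(f"unsupported metric {metric!r}")
    d = squareform(pdist(X, metric=metric))
    return DistanceMatrix(labels=matrix.genome_ids, d=d)


def ward_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative Ward clustering (Lance-Williams update on the
    condensed distance matrix); merge heights are monotone."""
    if len(dist.labels) < 2:
        raise ValueError("need >= 2 leaves")
    Z = hierarchy.linkage(dist.condensed(), method="ward")
    return Dendrogram(labels=list(dist.labels), linkage=Z)


def cut(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut into k groups; labels are renumbered 1..k in leaf order."""
    n = len(dendrogram.labels)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in 1..{n}")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(dendrogram.linkage)
    relabel: dict[int, int] = {}
    for leaf in leaf_order:
        c = int(raw[leaf])
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    return {dendrogram.labels[i]: relabel[int(raw[i])] for i in range(n)}
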