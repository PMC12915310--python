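"""Dissimilarity matrices and UPGMA dendrograms.

Jaccard distances on binary GCF profiles, Bray-Curtis on abundance profiles,
average-linkage (UPGMA) agglomeration with a documented tie-break, and
cophenetic matrices scaled so a two-leaf tree reproduces its input distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "jaccard_matrix",
    "bray_curtis_matrix",
    "Dendrogram",
    "upgma",
    "cophenetic",
    "distance_matrix_to_frame",
    "read_distance_tsv",
    "write_distance_tsv",
]


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    raise TypeError("expected a labeled pandas DataFrame (rows = profiles)")


def jaccard_matrix(presence: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity between binary rows.

    d(i, j) = 1 - |intersection| / |union|. Two all-zero rows get distance 0
    by convention (the index is undefined there); this is logged.
    """
    presence = _as_frame(presence)
    values = presence.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    inter = values @ values.T
    sizes = values.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    both_empty = union == 0
    if np.triu(both_empty, 1).any():
        warnings.warn("all-zero profile pair(s): Jaccard distance set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[both_empty] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=list(presence.index))


def bray_curtis_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between nonnegative rows.

    d(i, j) = sum |x - y| / sum (x + y); two all-zero rows get 0 by
    convention, logged as for Jaccard.
    """
    table = _as_frame(table)
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    both_empty = den == 0
    if np.triu(both_empty, 1).any():
        warnings.warn("all-zero profile pair(s): Bray-Curtis distance set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    d[both_empty] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=list(table.index))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree: n - 1 merges over n labeled leaves.

    Each merge is (left member indices, right member indices, height); merge
    heights are non-decreasing, so the tree is ultrametric with leaf-to-root
    distance equal to the final height.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[tuple[int, ...], tuple[int, ...], float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.labels) - 1:
            raise ValueError("a dendrogram on n leaves needs exactly n - 1 merges")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Ultrametric Newick export (branch lengths from merge heights)."""
        height_of: dict[frozenset[int], float] = {frozenset([i]): 0.0 for i in range(self.n_leaves)}
        newick: dict[frozenset[int], str] = {
            frozenset([i]): self.labels[i] for i in range(self.n_leaves)
        }
        node = ""
        for left, right, h in self.merges:
            lk, rk = frozenset(left), frozenset(right)
            bl = h - height_of[lk]
            br = h - height_of[rk]
            key = lk | rk
            node = f"({newick.pop(lk)}:{bl:.10g},{newick.pop(rk)}:{br:.10g})"
            newick[key] = node
            height_of[key] = h
        return node + ";\n"


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration with cluster-size weighting.

    The pair of clusters with the smallest average inter-cluster distance is
    merged at height = that distance / 2, so the cophenetic distance between
    two leaves (2 x merge height) reproduces the merging distance and a
    two-leaf tree is a fixed point. Ties are broken by the lexicographically
    smallest (min label, min label) pair of the candidate clusters.
    """
    d = np.asarray(dist.data, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    labels = tuple(str(i) for i in dist.ids)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")

    clusters: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    cdist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        def _key(pair: frozenset) -> tuple:
            a, b = sorted(pair)
            la = min(labels[i] for i in clusters[a])
            lb = min(labels[i] for i in clusters[b])
            return (cdist[pair], *sorted((la, lb)))

        best = min(cdist, key=_key)
        a, b = sorted(best)
        h = cdist[best] / 2.0
        left, right = clusters.pop(a), clusters.pop(b)
        merges.append((left, right, h))
        merged = left + right
        na, nb = len(left), len(right)
        for other in clusters:
            da = cdist.pop(frozenset((a, other)))
            db = cdist.pop(frozenset((b, other)))
            cdist[frozenset((next_id, other))] = (na * da + nb * db) / (na + nb)
        del cdist[best]
        clusters[next_id] = merged
        next_id += 1
    return Dendrogram(labels=labels, merges=tuple(merges))


def cophenetic(dendrogram: Dendrogram) -> DistanceMatrix:
    """Cophenetic matrix: d(i, j) = 2 x height of the lowest common merge."""
    n = dendrogram.n_leaves
    out = np.zeros((n, n))
    for left, right, h in dendrogram.merges:
        for i in left:
            for j in right:
                out[i, j] = out[j, i] = 2.0 * h
    return DistanceMatrix(out, ids=list(dendrogram.labels))


def distance_matrix_to_frame(dm: DistanceMatrix) -> pd.DataFrame:
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def read_distance_tsv(path: str) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_tsv(dm: DistanceMatrix, path: str) -> None:
    distance_matrix_to_frame(dm).to_csv(path, sep="\t")
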