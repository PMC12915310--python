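"""Tree and distance-matrix concordance with permutation null models.

Two leaf-labeled trees are compared by the Pearson correlation of their
leaf-to-leaf distances (cophenetic for dendrograms, patristic for
phylograms) and by Baker's Gamma — the rank correlation, over all leaf
pairs, of the highest cluster count at which the pair still co-occurs when
the tree is cut from the root down. Significance comes from permuting the
leaf labels of the second tree, which preserves its topology and heights and
so asks exactly: is the agreement better than chance relabeling?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .distances import Dendrogram, cophenetic
from .phylo import patristic

__all__ = [
    "ConcordanceResult",
    "cophenetic_pearson",
    "merge_levels",
    "bakers_gamma",
    "permutation_null",
    "mantel",
]


@dataclass
class ConcordanceResult:
    statistic_name: str
    observed: float
    p_value: float
    n_permutations: int
    seed: int | None
    null_values: np.ndarray = field(repr=False)

    @property
    def r_squared(self) -> float:
        return self.observed**2


def _align(dm_a: DistanceMatrix, dm_b: DistanceMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ids_a, ids_b = set(dm_a.ids), set(dm_b.ids)
    if ids_a != ids_b:
        diff = sorted(ids_a ^ ids_b)
        raise ValueError(f"label sets differ; symmetric difference: {diff[:10]}")
    labels = sorted(ids_a)
    a = dm_a.filter(labels).data
    b = dm_b.filter(labels).data
    return a, b, labels


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise ValueError("zero variance in distance vector")
    return float((x * y).sum() / denom)


def cophenetic_pearson(dist_a: DistanceMatrix, dist_b: DistanceMatrix) -> float:
    """Pearson correlation of two leaf-distance matrices, paired by label.

    Entries are paired by leaf label, never by matrix order, over the
    n(n-1)/2 unordered pairs.
    """
    a, b, labels = _align(dist_a, dist_b)
    if len(labels) < 4:
        raise ValueError("need at least 4 leaves")
    return _pearson(squareform(a, checks=False), squareform(b, checks=False))


def _leaf_distance(obj) -> DistanceMatrix:
    if isinstance(obj, DistanceMatrix):
        return obj
    if isinstance(obj, Dendrogram):
        return cophenetic(obj)
    if isinstance(obj, dendropy.Tree):
        return patristic(obj)
    raise TypeError(f"cannot extract leaf distances from {type(obj).__name__}")


def merge_levels(tree) -> pd.DataFrame:
    """Per-leaf-pair merge level k for a dendrogram or rooted phylogram.

    k(i, j) is the largest number of clusters k such that, cutting the tree
    into its k highest-level clusters, i and j still share a cluster. Cutting
    removes internal nodes from the root down — by merge height (descending)
    for dendrograms and by root distance (ascending) for phylograms, which
    yields the same cut sequence an ultrametric tree's height cuts give. A
    cherry in an n-leaf tree has k = n - 1; the two sides of the root have
    k = 1.
    """
    if isinstance(tree, Dendrogram):
        labels = list(tree.labels)
        n = len(labels)
        out = np.zeros((n, n), dtype=int)
        # merges are height-ascending; the LCA merge at ascending index t has
        # descending rank (n - 1) - t, which is k for all pairs it unites
        for t, (left, right, _h) in enumerate(tree.merges):
            k = (n - 1) - t
            for i in left:
                for j in right:
                    out[i, j] = out[j, i] = k
        return pd.DataFrame(out, index=labels, columns=labels)

    if isinstance(tree, dendropy.Tree):
        if not tree.is_rooted:
            raise ValueError("merge levels require a rooted tree")
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) < 3:
            raise ValueError("need at least 3 leaves")
        labels = sorted(leaves)
        idx = {lab: i for i, lab in enumerate(labels)}
        depth = {id(tree.seed_node): 0.0}
        internals = []
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
            if not node.is_leaf():
                internals.append(node)
        internals.sort(
            key=lambda nd: (depth[id(nd)], min(lf.taxon.label for lf in nd.leaf_iter()))
        )
        rank = {id(nd): r + 1 for r, nd in enumerate(internals)}
        n = len(labels)
        out = np.zeros((n, n), dtype=int)
        leafsets: dict[int, list[int]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[id(node)] = [idx[node.taxon.label]]
                continue
            children = [leafsets.pop(id(c)) for c in node.child_nodes()]
            k = rank[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            out[i, j] = out[j, i] = k
            leafsets[id(node)] = [x for ch in children for x in ch]
        return pd.DataFrame(out, index=labels, columns=labels)

    raise TypeError(f"cannot compute merge levels for {type(tree).__name__}")


def _merge_level_matrix(obj) -> DistanceMatrix:
    df = merge_levels(obj)
    m = df.to_numpy(dtype=float)
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(m, ids=list(df.index))


def bakers_gamma(tree_a, tree_b, flavor: str = "spearman") -> float:
    """Baker's Gamma: rank correlation of per-pair merge levels of two trees.

    The default flavor is Spearman with midranks (the index is a rank
    correlation of merge stages); ``pearson`` on the raw levels is offered as
    a dialect.
    """
    if flavor not in ("spearman", "pearson"):
        raise ValueError(f"unknown flavor {flavor!r}")
    a, b, _ = _align(_merge_level_matrix(tree_a), _merge_level_matrix(tree_b))
    va, vb = squareform(a, checks=False), squareform(b, checks=False)
    if flavor == "spearman":
        va, vb = rankdata(va), rankdata(vb)
    return _pearson(va, vb)


_STATISTICS = ("cophenetic_pearson", "bakers_gamma")


def permutation_null(
    statistic: str,
    tree_a,
    tree_b,
    n_perm: int = 999,
    seed: int | None = None,
    flavor: str = "spearman",
) -> ConcordanceResult:
    """Leaf-label permutation test of tree concordance.

    The labels of ``tree_b`` are permuted (topology and heights fixed)
    ``n_perm`` times and the statistic recomputed; the one-sided (greater)
    p-value uses the plus-one correction p = (1 + #{null >= obs}) /
    (n_perm + 1), so it can never be zero.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_STATISTICS}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for usable p-value resolution")
    if statistic == "cophenetic_pearson":
        ma, mb, _ = _align(_leaf_distance(tree_a), _leaf_distance(tree_b))
        va, vb_sq = squareform(ma, checks=False), mb
    else:
        ma, mb, _ = _align(_merge_level_matrix(tree_a), _merge_level_matrix(tree_b))
        va, vb_sq = squareform(ma, checks=False), mb
        if flavor == "spearman":
            va = rankdata(va)
            # relabeling permutes the pair vector, so its midranks permute with
            # it; ranking the square matrix entries once is therefore exact
            vb_sq = squareform(rankdata(squareform(mb, checks=False)), checks=False)

    vb = squareform(vb_sq, checks=False)
    observed = _pearson(va, vb)
    rng = np.random.default_rng(seed)
    n = vb_sq.shape[0]
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        null[t] = _pearson(va, squareform(vb_sq[np.ix_(perm, perm)], checks=False))
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return ConcordanceResult(
        statistic_name=statistic,
        observed=observed,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        null_values=null,
    )


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> ConcordanceResult:
    """Mantel test: Pearson r between label-paired distance matrices.

    The null simultaneously permutes rows and columns of ``dist_b``;
    one-sided (greater) p with the plus-one correction. ``result.r_squared``
    reports the distance-distance correlation R^2.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a, b, labels = _align(dist_a, dist_b)
    if len(labels) < 4:
        raise ValueError("need at least 4 labels")
    va = squareform(a, checks=False)
    observed = _pearson(va, squareform(b, checks=False))
    rng = np.random.default_rng(seed)
    n = len(labels)
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        null[t] = _pearson(va, squareform(b[np.ix_(perm, perm)], checks=False))
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return ConcordanceResult(
        statistic_name="mantel_r",
        observed=observed,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        null_values=null,
    )
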