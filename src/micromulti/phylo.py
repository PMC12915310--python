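"""Phylogenetic tree I/O and leaf-to-leaf (patristic) distances.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package; this module wraps the small amount of tree plumbing the analyses
need — Newick round-trips, leaf-label extraction and patristic distance
matrices — so the statistical modules never touch dendropy internals.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = [
    "read_newick",
    "write_newick",
    "to_newick",
    "leaf_labels",
    "patristic",
]


def read_newick(source: str) -> dendropy.Tree:
    """Parse a rooted Newick tree from a file path or a literal Newick string."""
    if source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=source, schema="newick")
    tree.is_rooted = True
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree))


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tree has duplicate leaf labels")
    return sorted(labels)


def patristic(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the unique path between every leaf pair.

    Missing branch lengths raise; a silent zero default would corrupt every
    downstream distance comparison.
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"branch length missing on edge above node {edge.head_node}"
            )
    labels = leaf_labels(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    # root-to-node depths, then d(i,j) = depth_i + depth_j - 2*depth_MRCA
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    out = np.zeros((n, n))
    # postorder accumulation of leaf sets per node; cross-child pairs have
    # this node as their MRCA
    leafsets: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = [(idx[node.taxon.label], depth[id(node)])]
            continue
        children = [leafsets.pop(id(c)) for c in node.child_nodes()]
        merged: list[tuple[int, float]] = []
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i, di in children[a]:
                    for j, dj in children[b]:
                        d = di + dj - 2.0 * depth[id(node)]
                        out[i, j] = out[j, i] = d
            merged.extend(children[a])
        merged.extend(children[-1])
        leafsets[id(node)] = merged
    return DistanceMatrix(out, ids=labels)
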