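"""Phylogeny handling: newick IO and patristic distances.

Trees are scikit-bio ``TreeNode`` objects throughout the package; this
module adds the validation the downstream null models rely on (unique tip
labels, branch lengths present and non-negative) and a convenient patristic
distance matrix aligned to a taxon ordering.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

__all__ = ["read_tree", "validate_tree", "patristic_matrix"]


def validate_tree(tree: TreeNode) -> TreeNode:
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        seen, dups = set(), set()
        for n in names:
            (dups if n in seen else seen).add(n)
        raise ValueError(f"duplicate tip labels: {sorted(dups)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                f"missing branch length on node {node.name or '<internal>'}"
            )
        if node.length < 0:
            raise ValueError(
                f"negative branch length on node {node.name or '<internal>'}"
            )
    return tree


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; every branch must carry a length."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def patristic_matrix(tree: TreeNode, taxon_ids=None) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip path-length distances.

    Returns ``(D, ids)`` where ``D[i, j]`` is the patristic distance between
    ``ids[i]`` and ``ids[j]``. When ``taxon_ids`` is given the matrix is
    restricted to (and ordered by) those tips; a taxon absent from the tree
    is an error listing the offenders.
    """
    dm = tree.tip_tip_distances()
    if taxon_ids is None:
        return dm.data.copy(), list(dm.ids)
    missing = [t for t in taxon_ids if t not in dm.ids]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    sub = dm.filter(list(taxon_ids))
    return sub.data.copy(), list(sub.ids)
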