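"""Faith's phylogenetic diversity and mean pairwise distance.

Trees are rooted dendropy trees with branch lengths; communities are sets of
tip labels.  Faith's PD is the branch-length sum of the minimal subtree
spanning a community's tips (including the path to the root by default, the
convention of the standard community-phylogenetics toolkits); MPD is the
unweighted mean patristic distance over all unordered tip pairs.  MNTD (mean
nearest-taxon distance) is provided as a clearly separate index because
verbal definitions of "average distance between closest relatives" describe
it rather than MPD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _check_community(tree: dendropy.Tree, community) -> set:
    comm = set(community)
    tips = set(_tip_labels(tree))
    unknown = comm - tips
    if unknown:
        raise ValueError(f"community members not on tree: {sorted(unknown)}")
    return comm


def faith_pd(tree: dendropy.Tree, community, include_root: bool = True) -> float:
    """Sum of branch lengths of the minimal subtree spanning ``community``.

    ``include_root=True`` keeps the path from the community's MRCA up to the
    root; with ``False`` the subtree is rooted at the MRCA.
    """
    comm = _check_community(tree, community)
    if not comm:
        raise ValueError("community is empty")
    total = 0.0
    counts: dict[int, int] = {}
    n_comm = len(comm)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in comm else 0
        else:
            c = sum(counts[id(ch)] for ch in node.child_nodes())
        counts[id(node)] = c
        if node.parent_node is None or node.edge.length is None:
            continue
        if c >= 1 and (include_root or c < n_comm):
            total += node.edge.length
    return float(total)


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Dense tip-to-tip patristic distance matrix (labels x labels)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = np.zeros((len(taxa), len(taxa)))
    for i, t1 in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            d = pdm.patristic_distance(t1, taxa[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def mpd(tree_or_matrix, community) -> float:
    """Mean patristic distance over all unordered pairs (presence-based)."""
    dmat = (
        tree_or_matrix
        if isinstance(tree_or_matrix, pd.DataFrame)
        else patristic_matrix(tree_or_matrix)
    )
    comm = sorted(set(community))
    unknown = set(comm) - set(dmat.index)
    if unknown:
        raise ValueError(f"community members not on tree: {sorted(unknown)}")
    if len(comm) < 2:
        raise ValueError("MPD needs at least 2 species")
    sub = dmat.loc[comm, comm].values
    iu = np.triu_indices(len(comm), 1)
    return float(sub[iu].mean())


def mntd(tree_or_matrix, community) -> float:
    """Mean nearest-taxon distance (the 'closest relative' index)."""
    dmat = (
        tree_or_matrix
        if isinstance(tree_or_matrix, pd.DataFrame)
        else patristic_matrix(tree_or_matrix)
    )
    comm = sorted(set(community))
    if len(comm) < 2:
        raise ValueError("MNTD needs at least 2 species")
    sub = dmat.loc[comm, comm].values.astype(float)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())
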