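"""Distance trees and parsimony.

The neighbor-joining implementation is deliberately in-repo: branch lengths
of break-count trees are the estimator for per-branch rearrangement counts,
so the clamping and tie-breaking behaviour must be pinned down rather than
delegated. ``skbio.tree.nj`` serves as an independent cross-check in the
test suite, never as the implementation.
"""

from __future__ import annotations

from typing import Hashable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

__all__ = ["nj", "tree_path_lengths", "fitch_sets", "fitch_changes"]


def nj(distances: np.ndarray, taxa: Sequence[str], clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Parameters
    ----------
    distances
        Symmetric nonnegative (n, n) matrix with zero diagonal.
    taxa
        Tip labels, one per matrix row, in matrix order.
    clamp_negative
        Clamp negative branch lengths to 0 and transfer the deficit to the
        sister branch, preserving the path length between the joined pair.

    Ties in the Q criterion break deterministically toward the lowest
    (row, column) index pair. The returned tree is unrooted in the usual NJ
    sense: its root is the final trifurcation (or the 2-taxon join).
    """
    D = np.array(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if len(taxa) != n:
        raise ValueError("taxa labels must match matrix size")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("diagonal must be zero")

    nodes: list[TreeNode] = [TreeNode(name=str(t)) for t in taxa]
    if n == 2:
        root = TreeNode()
        for node, length in zip(nodes, (D[0, 1] / 2, D[0, 1] / 2)):
            node.length = length
            root.append(node)
        return root

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic argmin: first (i, j) with i < j in index order
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if clamp_negative:
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
            li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[i], active[j]
        parent = TreeNode()
        nodes[gi].length = li
        nodes[gj].length = lj
        parent.append(nodes[gi])
        parent.append(nodes[gj])
        # distances from the new node to every remaining taxon
        new_row = 0.5 * (D[gi, :] + D[gj, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # final trifurcation
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode()
    for g, length in zip((a, b, c), (la, lb, lc)):
        nodes[g].length = length
        root.append(nodes[g])
    return root


def tree_path_lengths(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Pairwise path lengths between all tips, keyed by sorted name pairs."""
    tips = list(tree.tips())
    out: dict[tuple[str, str], float] = {}
    dm = tree.tip_tip_distances([t.name for t in tips])
    ids = dm.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            key = tuple(sorted((ids[i], ids[j])))
            out[key] = float(dm[i, j])
    return out


# ---------------------------------------------------------------------------
# Fitch parsimony


def fitch_sets(tree: TreeNode, tip_states: Mapping[str, Hashable]) -> dict[TreeNode, frozenset]:
    """Bottom-up Fitch state sets for every node of a rooted tree.

    ``tip_states`` maps tip names to single character states. The returned
    mapping assigns each node its Fitch set: for a tip, the singleton of its
    state; for an internal node, the intersection of its children's sets if
    nonempty, else their union. The root's set is exactly the set of root
    states attainable in a minimum-mutation labelling; ambiguity is
    preserved, never arbitrarily resolved.
    """
    sets: dict[TreeNode, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip():
            if node.name not in tip_states:
                raise KeyError(f"no state for tip {node.name!r}")
            sets[node] = frozenset([tip_states[node.name]])
        else:
            child_sets = [sets[c] for c in node.children]
            inter = frozenset.intersection(*child_sets)
            sets[node] = inter if inter else frozenset.union(*child_sets)
    return sets


def fitch_changes(tree: TreeNode, tip_states: Mapping[str, Hashable]) -> int:
    """Minimum number of state changes on the tree (Fitch parsimony score)."""
    changes = 0
    sets: dict[TreeNode, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip():
            sets[node] = frozenset([tip_states[node.name]])
        else:
            child_sets = [sets[c] for c in node.children]
            current = child_sets[0]
            for cs in child_sets[1:]:
                inter = current & cs
                if inter:
                    current = inter
                else:
                    current = current | cs
                    changes += 1
            sets[node] = current
    return changes
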