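"""Neighbor-joining trees and clade-membership decisions.

The molybdopterin disambiguation step places candidate arrA/aioA
sequences in a tree with family references, decoys (NapA etc.) and an
outgroup family; a query is accepted for a family iff it falls inside
the pure clade spanned by that family's references after rooting on the
outgroup.  Trees are :class:`skbio.TreeNode` objects (Newick-ready).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import CladeError, DataError
from .homology import ReferenceSet


@dataclass(frozen=True)
class CladeDecision:
    """Clade-membership verdict for one query against one target family."""

    query_id: str
    family: str
    accepted: bool
    mrca_leafset: frozenset[str]


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-matrix ties break on the lexicographic pair of cluster labels
    (a cluster is labelled by its smallest leaf id).  Negative branch
    lengths are clamped to 0 with the deficit shifted to the sibling
    branch, preserving the pair's summed length.  The result is unrooted
    (trifurcating root).
    """
    ids = list(distances.ids)
    n = len(ids)
    if n < 3:
        raise DataError("nj_tree: need at least 3 taxa")
    D: dict[tuple[int, int], float] = {}
    mat = np.asarray(distances.data, dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = mat[i, j]

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    nodes: dict[int, TreeNode] = {i: TreeNode(name=ids[i]) for i in range(n)}
    labels: dict[int, str] = {i: ids[i] for i in range(n)}
    active = list(range(n))
    nxt = n

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d(i, k) for k in active) for i in active}
        best_q = None
        best_pair = None
        best_key = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - R[i] - R[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best_q is None or q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and key < best_key
                ):
                    best_q, best_pair, best_key = q, (i, j), key
        i, j = best_pair
        dij = d(i, j)
        li = dij / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes.pop(i), nodes.pop(j)
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        nodes[nxt] = parent
        labels[nxt] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            D[(min(k, nxt), max(k, nxt))] = (d(i, k) + d(j, k) - dij) / 2.0
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = sorted(active, key=lambda x: labels[x])
    li = (d(i, j) + d(i, k) - d(j, k)) / 2.0
    lj = (d(i, j) + d(j, k) - d(i, k)) / 2.0
    lk = (d(i, k) + d(j, k) - d(i, j)) / 2.0
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        child = nodes.pop(idx)
        child.length = max(length, 0.0)
        root.append(child)
    return root


def _clade_leafset(tree: TreeNode, leaf_names: list[str]) -> frozenset[str]:
    if len(leaf_names) == 1:
        return frozenset(leaf_names)
    mrca = tree.lca(leaf_names)
    if mrca.is_tip():
        return frozenset({mrca.name})
    return frozenset(t.name for t in mrca.tips())


def assign_clades(
    tree: TreeNode,
    refs: list[ReferenceSet],
    queries: set[str],
    outgroup_family: str,
) -> list[CladeDecision]:
    """Root on the outgroup family and test query clade membership.

    For each target family F, the clade is the leafset under the MRCA of
    F's reference leaves in the rooted tree.  A query is accepted for F
    iff it lies in that clade and the clade contains no reference leaf of
    any other family (decoys and outgroup included); a contaminated
    reference clade aborts with :class:`CladeError` rather than guessing.
    """
    tip_names = {t.name for t in tree.tips()}
    by_family = {r.family: r for r in refs}
    og = by_family.get(outgroup_family)
    if og is None:
        raise CladeError(f"outgroup family {outgroup_family!r} not among references")
    og_leaves = [m.id for m in og.members if m.id in tip_names]
    if not og_leaves:
        raise CladeError(f"outgroup family {outgroup_family!r} has no leaf in the tree")
    try:
        if len(og_leaves) == 1:
            rooted = tree.root_at(
                tree.find(og_leaves[0]), above=True, branch_attrs=[]
            )
        else:
            rooted = tree.root_by_outgroup(og_leaves, branch_attrs=[])
    except Exception as exc:
        raise CladeError(f"cannot root on outgroup {outgroup_family!r}: {exc}") from exc

    ref_leaf_family = {
        m.id: r.family for r in refs for m in r.members if m.id in tip_names
    }
    decisions: list[CladeDecision] = []
    for ref in refs:
        if ref.role != "target":
            continue
        leaves = [m.id for m in ref.members if m.id in tip_names]
        if not leaves:
            raise CladeError(f"family {ref.family!r} has no reference leaf in the tree")
        clade = _clade_leafset(rooted, leaves)
        foreign = {
            l for l in clade if ref_leaf_family.get(l, ref.family) != ref.family
        }
        if foreign:
            raise CladeError(
                f"reference clade not recovered for {ref.family!r}: "
                f"contaminated by {sorted(foreign)}"
            )
        for q in sorted(queries):
            decisions.append(
                CladeDecision(
                    query_id=q,
                    family=ref.family,
                    accepted=q in clade,
                    mrca_leafset=clade,
                )
            )
    return decisions
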