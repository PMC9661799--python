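"""Tree inference: neighbor joining on MEDs, rooting at the diploid,
minimum-event ancestral reconstruction, branch lengths and tree utilities.

The tree topology comes from neighbor joining on the symmetric MED matrix;
the tree is then rooted on the diploid's pendant branch and ancestral
copy-number profiles are assigned so that the total number of events along
the tree (sum over branches of the asymmetric MED, directed away from the
diploid root) is small.  Exact ancestral reconstruction is a Steiner
problem (NP-complete), so we use a monotone local search: internal nodes
are initialized bottom-up with the pairwise ancestor of their children and
then re-optimized coordinate-wise given their neighbors until a full sweep
yields no improvement.  The objective never increases, every run is
deterministic, and the final branch lengths are the asymmetric MEDs along
the tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import count

import numpy as np

from .genome_model import DIPLOID_ID, Cohort, CopyNumberProfile, GenomeLayout, profile_units
from .med_model import (
    DistanceMatrix,
    EventModel,
    med_asymmetric,
    med_symmetric,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "neighbor_joining",
    "root_at_diploid",
    "reconstruct_ancestors",
    "tree_stats",
    "robinson_foulds",
    "to_newick",
]


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to the parent
    support: int | None = None  # integer percent, internal branches only
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)
    profile: CopyNumberProfile | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> frozenset:
        return frozenset(leaf.name for leaf in self.leaves())

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def find(self, name: str) -> "TreeNode":
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)


def to_newick(tree: TreeNode, lengths: bool = True) -> str:
    def fmt_len(x: float) -> str:
        if math.isclose(x, round(x)):
            return str(int(round(x)))
        return f"{x:.6g}"

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            label = node.name or ""
        else:
            inner = ",".join(rec(c) for c in node.children)
            label = f"({inner})" + ("" if node.support is None else str(node.support))
        if lengths and node.parent is not None:
            label += f":{fmt_len(node.length)}"
        return label

    return rec(tree) + ";"


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Deterministic NJ; Q-criterion ties broken by the smallest index pair.

    Returns an unrooted tree represented with a trifurcating root (the
    last three lineages joined); use :func:`root_at_diploid` afterwards.
    Negative branch-length estimates are clamped to 0 with a warning.
    """
    D = np.asarray(dm.matrix, dtype=float)
    n = D.shape[0]
    if n < 3:
        if n != 2:
            raise ValueError("neighbor joining needs >= 2 taxa")
        root = TreeNode()
        a = root.add(TreeNode(name=dm.ids[0]))
        b = root.add(TreeNode(name=dm.ids[1]))
        a.length = float(D[0, 1])
        b.length = 0.0
        return root

    nodes = [TreeNode(name=sid) for sid in dm.ids]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = count(n)

    def d(i, j):
        return dist[(i, j)] if (i, j) in dist else dist[(j, i)]

    node_of = {i: nodes[i] for i in range(n)}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-9:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        u = next(next_id)
        parent = TreeNode()
        for child_idx, ln in ((i, li), (j, lj)):
            child = node_of[child_idx]
            if ln < -1e-9:
                logger.warning("negative NJ branch length %.3f clamped to 0", ln)
            child.length = max(0.0, ln)
            parent.add(child)
        for k in active:
            if k not in (i, j):
                dist[(u, k)] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        node_of[u] = parent
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    root = TreeNode()
    for idx, ln in (
        (i, 0.5 * (d(i, j) + d(i, k) - d(j, k))),
        (j, 0.5 * (d(i, j) + d(j, k) - d(i, k))),
        (k, 0.5 * (d(i, k) + d(j, k) - d(i, j))),
    ):
        child = node_of[idx]
        if ln < -1e-9:
            logger.warning("negative NJ branch length %.3f clamped to 0", ln)
        child.length = max(0.0, ln)
        root.add(child)
    return root


def _validate_matrix(dm: DistanceMatrix) -> None:
    # DistanceMatrix validates on construction; kept for explicit API errors
    DistanceMatrix(dm.ids, dm.matrix)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------


def root_at_diploid(tree: TreeNode, diploid_id: str = DIPLOID_ID) -> TreeNode:
    """Place the root on the diploid's pendant branch.

    The diploid remains a leaf child of the new root (carrying its pendant
    branch length); the rest of the tree hangs from the root's other child
    with length 0.  Rooting an already-rooted tree is idempotent.
    """
    try:
        dip = tree.find(diploid_id)
    except KeyError:
        raise ValueError(f"diploid leaf {diploid_id!r} not in tree") from None
    if dip.parent is None:
        raise ValueError("diploid cannot be the root")
    if dip.parent.parent is None and len(dip.parent.children) == 2:
        return tree  # already rooted on the diploid's branch

    # re-hang the tree from the diploid's attachment point
    attach = dip.parent
    attach.children = [c for c in attach.children if c is not dip]

    # flip parent pointers along the path attach -> old root; the length of
    # each flipped edge stays on the edge
    path = []
    p = attach
    while p is not None:
        path.append(p)
        p = p.parent
    edge_lengths = [n.length for n in path]
    for k in range(len(path) - 1):
        child, par = path[k], path[k + 1]
        par.children = [c for c in par.children if c is not child]
        child.children.append(par)
        par.parent = child
        par.length = edge_lengths[k]
    attach.parent = None
    # drop degree-2 pass-through nodes created by unrooting (old root)
    _suppress_unifurcations(attach)

    root = TreeNode()
    root.add(dip)  # keeps its pendant branch length
    attach.length = 0.0
    root.add(attach)
    return root


def _suppress_unifurcations(node: TreeNode) -> None:
    for child in list(node.children):
        _suppress_unifurcations(child)
    for child in list(node.children):
        if len(child.children) == 1 and child.is_leaf is False and child.name is None:
            (grand,) = child.children
            grand.length += child.length
            grand.parent = node
            node.children[node.children.index(child)] = grand


# ---------------------------------------------------------------------------
# ancestral reconstruction
# ---------------------------------------------------------------------------


def reconstruct_ancestors(
    tree: TreeNode,
    cohort: Cohort,
    model: EventModel,
    max_sweeps: int = 10,
) -> TreeNode:
    """Assign internal profiles minimizing total events; set branch lengths.

    The tree must be rooted (see :func:`root_at_diploid`) with leaf names
    matching the cohort.  The root profile is fixed to the diploid.
    """
    layout = cohort.layout
    for leaf in tree.leaves():
        leaf.profile = cohort[leaf.name]
    tree.profile = cohort.diploid

    internal = [
        n for n in tree.postorder() if not n.is_leaf and n.parent is not None
    ]
    # bottom-up initialization with pairwise ancestors
    for node in internal:
        profs = [c.profile for c in node.children]
        if len(profs) == 1:
            node.profile = profs[0].copy()
        else:
            _, anc = med_symmetric(profs[0], profs[1], model, layout, return_ancestor=True)
            node.profile = anc
        node.profile.sample_id = f"internal_{id(node) % 10**6}"

    def branch_cost(parent: TreeNode, child: TreeNode) -> float:
        return med_asymmetric(parent.profile, child.profile, model, layout)

    def total() -> float:
        return sum(branch_cost(n.parent, n) for n in tree.postorder() if n.parent)

    obj = total()
    if math.isinf(obj):
        raise ValueError("infinite branch length: topology/profiles inconsistent")
    cap = model.config.cap
    for _ in range(max_sweeps):
        improved = False
        for node in internal:
            neighbors = [(node.parent, node), *[(node, c) for c in node.children]]
            local = sum(branch_cost(p, c) for p, c in neighbors)
            prof = node.profile
            for hap in prof.haplotypes():
                for pos in range(hap.shape[0]):
                    orig = hap[pos]
                    best_v, best_c = orig, local
                    for v in range(cap + 1):
                        if v == orig:
                            continue
                        hap[pos] = v
                        c = sum(branch_cost(p, ch) for p, ch in neighbors)
                        if c < best_c:
                            best_v, best_c = v, c
                    hap[pos] = best_v
                    if best_v != orig:
                        local = best_c
                        improved = True
        new_obj = total()
        assert new_obj <= obj + 1e-9, "local search must not increase the objective"
        obj = new_obj
        if not improved:
            break

    for n in tree.postorder():
        if n.parent is not None:
            ln = branch_cost(n.parent, n)
            if math.isinf(ln):
                raise ValueError("infinite branch after reconstruction")
            n.length = int(ln)
    return tree


# ---------------------------------------------------------------------------
# statistics and comparisons
# ---------------------------------------------------------------------------


def tree_stats(tree: TreeNode, diploid_id: str = DIPLOID_ID) -> dict:
    """Tree length, trunk length, maximal root-to-leaf length, trunk fraction.

    The trunk is the path from the (diploid) root to the most recent
    common ancestor of all non-diploid sample nodes (named nodes; in NJ
    trees these are exactly the leaves).
    """
    leaves = [
        n for n in tree.postorder()
        if n.name is not None and n.name != diploid_id and n.parent is not None
    ]
    tree_length = sum(n.length for n in tree.postorder() if n.parent is not None)

    depth: dict[int, float] = {id(tree): 0.0}
    for n in tree.preorder():
        for c in n.children:
            depth[id(c)] = depth[id(n)] + c.length

    def path_to_root(n: TreeNode) -> list[TreeNode]:
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    if leaves:
        common = set(map(id, path_to_root(leaves[0])))
        for l in leaves[1:]:
            common &= set(map(id, path_to_root(l)))
        mrca = next(n for n in path_to_root(leaves[0]) if id(n) in common)
        trunk = depth[id(mrca)]
        max_rtl = max(depth[id(l)] for l in leaves if l.is_leaf)
    else:
        trunk = max_rtl = 0.0
    fraction = trunk / max_rtl if max_rtl > 0 else (1.0 if leaves else 0.0)
    return {
        "tree_length": tree_length,
        "trunk_length": trunk,
        "max_root_to_leaf": max_rtl,
        "trunk_fraction": fraction,
    }


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted splits, each as a frozenset pair."""
    all_leaves = tree.leaf_names()
    splits = set()
    for n in tree.postorder():
        if n.parent is None:
            continue
        side = n.leaf_names()
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset((side, frozenset(other))))
    return splits


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Number of bipartitions present in exactly one of the two trees."""
    if t1.leaf_names() != t2.leaf_names():
        raise ValueError("trees have different leaf sets")
    return len(_bipartitions(t1) ^ _bipartitions(t2))
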