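"""Tree comparison suite: Robinson-Foulds, Kendall-Colijn, branch score.

Four distances, each with the scaling denominator that makes values
comparable across datasets of different size n:

========  ==========================================  ====================
distance  measures                                    scaling denominator
========  ==========================================  ====================
RF        topology (bipartition symmetric difference) 2n - 3 branches
KC_T      rooted topology (Kendall-Colijn, λ = 0)     C(n,2) leaf pairs
KC        topology + branch lengths (λ = 0.5)         C(n,2) + n
BS        branch lengths over matched bipartitions    Σ branch lengths of
                                                      both trees
========  ==========================================  ====================

RF and BS compare unrooted trees; the Kendall-Colijn distances require
rooted trees, conventionally rooted at an outgroup (the root is placed at
the midpoint of the outgroup's pendant edge).  BS uses the square-root
(distance) form and includes pendant bipartitions; RF excludes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .errors import ChloronormError, FormatError

DISTANCE_KINDS = ("RF", "KC_T", "KC", "BS")
KC_LAMBDAS = {"KC_T": 0.0, "KC": 0.5}


@dataclass
class PhyloTree:
    """A phylogenetic tree with branch lengths.

    Thin wrapper over a dendropy tree.  ``rooted`` distinguishes a tree
    whose basal bifurcation is meaningful from an unrooted tree that merely
    happens to be stored with a basal split.
    """

    tree: dendropy.Tree
    rooted: bool = False

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(sorted(lf.taxon.label for lf in self.tree.leaf_node_iter()))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def total_branch_length(self) -> float:
        return sum(
            nd.edge.length or 0.0
            for nd in self.tree
            if nd.parent_node is not None
        )


def read_newick(path: str | Path) -> PhyloTree:
    """Parse a Newick file, preserving branch lengths to printed precision.

    The tree is taken as rooted iff its basal node is a bifurcation (the
    usual convention for trees written with an explicit root)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick in {path}: {exc}") from exc
    rooted = len(tree.seed_node.child_nodes()) == 2
    return PhyloTree(tree=tree, rooted=rooted)


def tree_from_newick(newick: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a Newick string (convenience mirror of :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from exc
    if rooted is None:
        rooted = len(tree.seed_node.child_nodes()) == 2
    return PhyloTree(tree=tree, rooted=rooted)


def write_newick(t: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            t.tree.as_string(schema="newick", suppress_rooting=True)
        )


def root_at(t: PhyloTree, outgroup: str) -> PhyloTree:
    """Root the tree on the outgroup's pendant edge, split at its midpoint."""
    tree = t.tree.clone(depth=1)
    node = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup:
            node = lf
            break
    if node is None:
        raise ChloronormError(
            f"outgroup {outgroup!r} not among leaves {sorted(t.leaf_labels)}"
        )
    half = (node.edge.length or 0.0) / 2.0
    tree.reroot_at_edge(node.edge, length1=half, length2=half)
    tree.is_rooted = True
    return PhyloTree(tree=tree, rooted=True)


def _check_leaf_sets(t1: PhyloTree, t2: PhyloTree) -> tuple[str, ...]:
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        only1 = sorted(set(l1) - set(l2))
        only2 = sorted(set(l2) - set(l1))
        raise ChloronormError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    return l1


def bipartitions(t: PhyloTree, include_trivial: bool = False) -> dict[frozenset, float]:
    """Bipartitions of the unrooted tree as {canonical side: branch length}.

    The canonical side is the one *not* containing the lexicographically
    smallest leaf label.  When the stored tree has a basal bifurcation its
    two basal edges describe the same bipartition; their lengths are summed.
    Missing branch lengths count as 0.
    """
    labels = t.leaf_labels
    n = len(labels)
    smallest = labels[0]
    below: dict[int, frozenset] = {}
    out: dict[frozenset, float] = {}
    for nd in t.tree.postorder_node_iter():
        if not nd.child_nodes():
            below[id(nd)] = frozenset({nd.taxon.label})
        else:
            below[id(nd)] = frozenset().union(*(below[id(c)] for c in nd.child_nodes()))
        if nd.parent_node is None:
            continue
        side = below[id(nd)]
        size = len(side)
        if not include_trivial and not (2 <= size <= n - 2):
            continue
        canon = frozenset(labels) - side if smallest in side else side
        out[canon] = out.get(canon, 0.0) + (nd.edge.length or 0.0)
    return out


def n_branches(t: PhyloTree) -> int:
    """Number of distinct branches of the unrooted tree (2n-3 if binary)."""
    return len(bipartitions(t, include_trivial=True))


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two nontrivial bipartition sets (unrooted comparison)."""
    _check_leaf_sets(t1, t2)
    b1 = set(bipartitions(t1))
    b2 = set(bipartitions(t2))
    return len(b1 ^ b2)


def bs_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Branch score distance: sqrt of the summed squared branch-length
    differences over the union of all bipartitions, pendant ones included;
    a bipartition absent from one tree contributes length 0 there."""
    _check_leaf_sets(t1, t2)
    b1 = bipartitions(t1, include_trivial=True)
    b2 = bipartitions(t2, include_trivial=True)
    total = 0.0
    for key in set(b1) | set(b2):
        d = b1.get(key, 0.0) - b2.get(key, 0.0)
        total += d * d
    return math.sqrt(total)


def _require_rooted(t: PhyloTree) -> None:
    if not t.rooted or len(t.tree.seed_node.child_nodes()) != 2:
        raise ChloronormError(
            "Kendall-Colijn distance requires rooted trees; root both trees "
            "at an outgroup with root_at() first"
        )


def kc_vector(t: PhyloTree, lam: float) -> np.ndarray:
    """The Kendall-Colijn vector at weighting λ.

    One entry per leaf pair (i<j, lexicographic): (1-λ) times the edge
    count from the root to the pair's MRCA plus λ times the root-to-MRCA
    path length.  Then one entry per leaf (lexicographic):
    (1-λ)·1 + λ·(pendant branch length).
    """
    _require_rooted(t)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    labels = t.leaf_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depth: dict[int, int] = {}
    pathlen: dict[int, float] = {}
    root = t.tree.seed_node
    depth[id(root)] = 0
    pathlen[id(root)] = 0.0
    for nd in t.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        depth[id(nd)] = depth[id(nd.parent_node)] + 1
        pathlen[id(nd)] = pathlen[id(nd.parent_node)] + (nd.edge.length or 0.0)
    pair_entries = np.zeros(n * (n - 1) // 2)
    leaf_entries = np.zeros(n)
    below: dict[int, list[int]] = {}

    def pair_pos(i: int, j: int) -> int:
        # position of pair (i<j) in lexicographic order over C(n,2)
        return i * (2 * n - i - 1) // 2 + (j - i - 1)

    for nd in t.tree.postorder_node_iter():
        if not nd.child_nodes():
            i = index[nd.taxon.label]
            below[id(nd)] = [i]
            leaf_entries[i] = (1 - lam) * 1.0 + lam * (nd.edge.length or 0.0)
            continue
        child_sets = [below[id(c)] for c in nd.child_nodes()]
        value = (1 - lam) * depth[id(nd)] + lam * pathlen[id(nd)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        lo, hi = (i, j) if i < j else (j, i)
                        pair_entries[pair_pos(lo, hi)] = value
        below[id(nd)] = [i for s in child_sets for i in s]
    return np.concatenate([pair_entries, leaf_entries])


def kc_distance(t1: PhyloTree, t2: PhyloTree, lam: float) -> float:
    """Kendall-Colijn distance: Euclidean norm of the difference of the two
    trees' KC vectors at weighting λ (λ=0 topology only)."""
    _check_leaf_sets(t1, t2)
    v1 = kc_vector(t1, lam)
    v2 = kc_vector(t2, lam)
    return float(np.linalg.norm(v1 - v2))


def scaling_denominator(
    kind: str, n: int, t1: PhyloTree | None = None, t2: PhyloTree | None = None
) -> float:
    """The per-distance scaling denominator for n leaves.

    RF: 2n-3 branches of a resolved unrooted tree (applied as a formula
    even to multifurcating inputs); KC_T: C(n,2) leaf pairs; KC: C(n,2)+n;
    BS: the summed branch lengths of both trees.
    """
    if kind == "RF":
        if n < 4:
            raise ValueError("RF scaling needs n >= 4")
        return float(2 * n - 3)
    if kind == "KC_T":
        return float(n * (n - 1) // 2)
    if kind == "KC":
        return float(n * (n - 1) // 2 + n)
    if kind == "BS":
        if t1 is None or t2 is None:
            raise ValueError("BS scaling needs both trees")
        total = t1.total_branch_length() + t2.total_branch_length()
        if total <= 0.0:
            raise ChloronormError("BS scaling undefined: all branch lengths zero")
        return total
    raise ValueError(f"unknown distance kind {kind!r}")


def scaled(
    value: float,
    kind: str,
    n: int,
    t1: PhyloTree | None = None,
    t2: PhyloTree | None = None,
) -> float:
    """Scale a raw distance by its denominator (see :func:`scaling_denominator`)."""
    return value / scaling_denominator(kind, n, t1, t2)


def all_rooted_topologies(labels: list[str], branch_length: float = 1.0) -> list[str]:
    """Newick strings for all (2k-3)!! rooted binary topologies on ``labels``.

    Built by inserting each successive leaf on every edge (and above the
    root) of every smaller tree; 5 labels give the familiar 105 topologies.
    All branch lengths are set to ``branch_length``.  Attaching one extra
    leaf at the root of each tree enumerates all unrooted binary topologies
    on k+1 labels exactly once.
    """
    if len(labels) < 2:
        raise ValueError("need at least two labels")

    def insertions(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for sub in insertions(left, leaf):
                yield (sub, right)
            for sub in insertions(right, leaf):
                yield (left, sub)

    trees = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        trees = [new for t in trees for new in insertions(t, leaf)]

    def to_newick(tree) -> str:
        if isinstance(tree, str):
            return f"{tree}:{branch_length}"
        return f"({to_newick(tree[0])},{to_newick(tree[1])}):{branch_length}"

    return [f"({to_newick(t[0])},{to_newick(t[1])});" for t in trees]


def compare_suite(
    t1: PhyloTree,
    t2: PhyloTree,
    outgroup: str | None = None,
    lengths_comparable: bool = True,
) -> dict:
    """One report row with raw and scaled RF, KC_T, KC and BS.

    The Kendall-Colijn distances are computed after rooting both trees at
    ``outgroup`` (required unless both trees are already rooted).  When
    branch lengths are not comparable between the inputs — trees from
    different inference methods — only the topology-only distances RF and
    KC_T are reported and the row is flagged ``topology_only``.
    """
    labels = _check_leaf_sets(t1, t2)
    n = len(labels)
    if outgroup is not None:
        r1, r2 = root_at(t1, outgroup), root_at(t2, outgroup)
    else:
        r1, r2 = t1, t2
    row: dict = {"n": n, "topology_only": not lengths_comparable}
    rf = rf_distance(t1, t2)
    row["RF"] = rf
    row["RF_scaled"] = scaled(rf, "RF", n)
    kct = kc_distance(r1, r2, KC_LAMBDAS["KC_T"])
    row["KC_T"] = kct
    row["KC_T_scaled"] = scaled(kct, "KC_T", n)
    if lengths_comparable:
        kc = kc_distance(r1, r2, KC_LAMBDAS["KC"])
        row["KC"] = kc
        row["KC_scaled"] = scaled(kc, "KC", n)
        bs = bs_distance(t1, t2)
        row["BS"] = bs
        row["BS_scaled"] = scaled(bs, "BS", n, t1, t2)
    else:
        row["KC"] = row["KC_scaled"] = row["BS"] = row["BS_scaled"] = None
    return row
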