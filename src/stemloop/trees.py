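"""Unrooted phylogenetic trees with branch lengths.

``PhyloTree`` is a light rooted representation of an unrooted tree (the
root is an arbitrary internal vertex; a degree-2 root is suppressed on
construction so topology-level operations see the unrooted object).
Newick reading/writing delegates parsing to dendropy.
"""

from __future__ import annotations

import copy

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "children")

    def __init__(self, name=None, length=0.0, children=None):
        self.name = name
        self.length = float(length)
        self.children = children if children is not None else []

    @property
    def is_leaf(self):
        return not self.children


class PhyloTree:
    """Unrooted tree; leaf labels unique; branch lengths >= 0, finite."""

    def __init__(self, root: Node):
        self.root = root
        self._suppress_degree2_root()
        self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(data=text, schema="newick",
                                   preserve_underscores=True)
        except Exception as exc:
            raise TreeError(f"newick parse failed: {exc}") from exc

        def conv(dn):
            name = dn.taxon.label if dn.taxon is not None else None
            length = dn.edge.length if dn.edge.length is not None else 0.0
            return Node(name=name, length=length,
                        children=[conv(c) for c in dn.child_nodes()])

        return cls(conv(dt.seed_node))

    def to_newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def copy(self) -> "PhyloTree":
        t = object.__new__(PhyloTree)
        t.root = copy.deepcopy(self.root)
        return t

    # -- basic accessors ----------------------------------------------------

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def taxa(self):
        return sorted(n.name for n in self.leaves())

    def n_edges(self):
        return len(self.postorder()) - 1

    def total_length(self):
        return sum(n.length for n in self.postorder() if n is not self.root)

    def validate(self):
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            raise TreeError("duplicate leaf labels")
        if any(n.name is None for n in self.leaves()):
            raise TreeError("unnamed leaf")
        for n in self.postorder():
            if n is self.root:
                continue
            if not np.isfinite(n.length) or n.length < 0:
                raise TreeError(f"invalid branch length {n.length}")

    def _suppress_degree2_root(self):
        # an unrooted tree's root vertex must have degree >= 3 (or be a cherry)
        while len(self.root.children) == 2 and sum(
                1 for c in self.root.children if not c.is_leaf) >= 1:
            a, b = self.root.children
            keep = a if not a.is_leaf else b
            other = b if keep is a else a
            other.length += keep.length
            self.root = Node(children=keep.children + [other])

    # -- bipartitions -------------------------------------------------------

    def bipartitions(self):
        """Non-trivial splits as canonical frozensets: the side *not*
        containing the lexicographically smallest taxon."""
        taxa = frozenset(self.taxa())
        if not taxa:
            return set()
        ref = min(taxa)
        splits = set()

        def walk(node):
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(taxa) - 1:
                side = below if ref not in below else taxa - below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def bipartition_sides(self):
        """All non-trivial splits as (side, complement) pairs."""
        taxa = frozenset(self.taxa())
        return [(s, taxa - s) for s in self.bipartitions()]

    # -- editing ------------------------------------------------------------

    def restrict(self, keep) -> "PhyloTree":
        """Tree induced on the leaf subset ``keep`` (lengths additively merged)."""
        keep = set(keep)
        missing = keep - set(self.taxa())
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")

        def prune(node):
            if node.is_leaf:
                return node if node.name in keep else None
            kids = [k for k in (prune(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            node.children = kids
            return node

        t = self.copy()
        root = prune(t.root)
        if root is None:
            raise TreeError("restriction removed all leaves")
        if root.is_leaf:
            raise TreeError("restriction left a single leaf")
        root.length = 0.0
        return PhyloTree(root)

    def nni_neighbors(self):
        """All trees one nearest-neighbor interchange away.

        For each internal edge (u, v) the two alternative arrangements are
        produced by swapping each child subtree of v with one fixed
        neighbor subtree on the u side.
        """
        out = []
        base = self.postorder()
        index = {id(n): i for i, n in enumerate(base)}

        def edit(v_id, x_id, y_id):
            t = self.copy()
            nodes = t.postorder()
            v, x, y = nodes[index[v_id]], nodes[index[x_id]], nodes[index[y_id]]
            u = next(n for n in nodes if v in n.children)
            u.children[u.children.index(y)] = x
            v.children[v.children.index(x)] = y
            return t

        for v in base:
            if v.is_leaf or v is self.root:
                continue
            u = next(n for n in base if v in n.children)
            side = [c for c in u.children if c is not v]
            if not side:
                continue
            y = side[0]
            for x in v.children:
                out.append(edit(id(v), id(x), id(y)))
        return out


# ---------------------------------------------------------------------------
# tree generators

def quartet(taxa, split_pair, inner=0.1, outer=0.1) -> PhyloTree:
    """Quartet tree with ``split_pair`` (two taxa) on one side of the
    internal edge."""
    taxa = list(taxa)
    if len(taxa) != 4:
        raise TreeError("quartet needs exactly 4 taxa")
    a, b = split_pair
    c, d = [t for t in taxa if t not in split_pair]
    cherry = Node(length=inner, children=[Node(a, outer), Node(b, outer)])
    return PhyloTree(Node(children=[cherry, Node(c, outer), Node(d, outer)]))


def all_quartets(taxa, inner=0.1, outer=0.1):
    """The three unrooted topologies on four taxa."""
    t = sorted(taxa)
    return [quartet(t, (t[0], p), inner, outer) for p in t[1:]]


def balanced_tree(n_taxa: int, branch_length: float, prefix="t") -> PhyloTree:
    """Fully balanced binary tree; ``n_taxa`` must be a power of two >= 4.
    Every edge has length ``branch_length``."""
    if n_taxa < 4 or n_taxa & (n_taxa - 1):
        raise TreeError("balanced tree needs a power-of-two taxon count >= 4")
    nodes = [Node(f"{prefix}{i}", branch_length) for i in range(n_taxa)]
    while len(nodes) > 2:
        nodes = [Node(length=branch_length, children=[nodes[i], nodes[i + 1]])
                 for i in range(0, len(nodes), 2)]
    a, b = nodes
    return PhyloTree(Node(children=a.children + [b]))


def pectinate_tree(n_taxa: int, branch_length: float, prefix="t") -> PhyloTree:
    """Caterpillar (fully asymmetric) tree; every edge ``branch_length``."""
    if n_taxa < 4:
        raise TreeError("need >= 4 taxa")
    node = Node(length=branch_length, children=[
        Node(f"{prefix}0", branch_length), Node(f"{prefix}1", branch_length)])
    for i in range(2, n_taxa - 1):
        node = Node(length=branch_length,
                    children=[node, Node(f"{prefix}{i}", branch_length)])
    return PhyloTree(Node(children=node.children +
                          [Node(f"{prefix}{n_taxa - 1}", branch_length)]))


def pectinate_ultrametric(n_taxa: int, depth: float, prefix="t") -> PhyloTree:
    """Caterpillar tree with join events evenly spaced in time; all tips at
    distance ``depth`` from the root."""
    if n_taxa < 4:
        raise TreeError("need >= 4 taxa")
    step = depth / (n_taxa - 1)
    node = Node(length=step, children=[Node(f"{prefix}0", step),
                                       Node(f"{prefix}1", step)])
    for i in range(2, n_taxa - 1):
        node = Node(length=step,
                    children=[node, Node(f"{prefix}{i}", (i) * step)])
    return PhyloTree(Node(children=[node,
                                    Node(f"{prefix}{n_taxa - 1}",
                                         (n_taxa - 1) * step)]))


def pectinate_asymmetric(n_taxa: int, depth: float, ratio: float = 8.0,
                         prefix="t") -> PhyloTree:
    """Rate-asymmetric caterpillar: short internal edges and pendant
    branches alternating long (``depth``) and short (``depth / ratio``),
    so consecutive long branches are non-adjacent.  This is the
    long-branch-attraction-prone shape in which saturation first misleads
    distance reconstruction; used as the asymmetric reference topology for
    critical saturation thresholds."""
    if n_taxa < 4:
        raise TreeError("need >= 4 taxa")
    step = depth / ratio

    def pend(i):
        return depth if i % 2 == 0 else step

    node = Node(length=step, children=[Node(f"{prefix}0", pend(0)),
                                       Node(f"{prefix}1", pend(1))])
    for i in range(2, n_taxa - 1):
        node = Node(length=step,
                    children=[node, Node(f"{prefix}{i}", pend(i))])
    return PhyloTree(Node(children=node.children +
                          [Node(f"{prefix}{n_taxa - 1}", pend(n_taxa - 1))]))


def felsenstein_zone_tree(p: float, q: float, taxa=("A", "B", "C", "D")) -> PhyloTree:
    """Quartet with two long non-sister branches (A and C length p), short
    branches and internal edge length q: ((A:p,B:q):q,C:p,D:q)."""
    a, b, c, d = taxa
    cherry = Node(length=q, children=[Node(a, p), Node(b, q)])
    return PhyloTree(Node(children=[cherry, Node(c, p), Node(d, q)]))


def random_tree(taxa, rng, mean_branch=0.1) -> PhyloTree:
    """Random topology by sequential leaf attachment; exponential lengths."""
    taxa = list(taxa)
    if len(taxa) < 4:
        raise TreeError("need >= 4 taxa")
    order = list(rng.permutation(taxa))

    def bl():
        return float(rng.exponential(mean_branch)) + 1e-4

    root = Node(children=[Node(order[0], bl()), Node(order[1], bl()),
                          Node(order[2], bl())])
    tree = PhyloTree(root)
    for name in order[3:]:
        nodes = [n for n in tree.postorder() if n is not tree.root]
        target = nodes[rng.integers(len(nodes))]
        parent = next(n for n in tree.postorder() if target in n.children)
        mid = Node(length=bl(), children=[target, Node(name, bl())])
        parent.children[parent.children.index(target)] = mid
        tree = PhyloTree(tree.root)
    return tree


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dist: np.ndarray, names) -> PhyloTree:
    """Classic NJ on a symmetric distance matrix; negative estimated branch
    lengths are clipped to zero."""
    names = list(names)
    n = len(names)
    if n < 4:
        raise TreeError("NJ needs >= 4 taxa")
    D = np.asarray(dist, dtype=float).copy()
    nodes = [Node(name) for name in names]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        i, j = np.unravel_index(np.argmin(Qm), Qm.shape)
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[ai].length = max(li, 0.0)
        nodes[aj].length = max(lj, 0.0)
        new = Node(children=[nodes[ai], nodes[aj]])
        newd = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newd
        D[:-1, -1] = newd
        D[-1, -1] = 0.0
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, l in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(l, 0.0)
    return PhyloTree(Node(children=[nodes[a], nodes[b], nodes[c]]))
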