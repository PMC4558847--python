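"""Study trees: construction, polytomy resolution, distances, Newick I/O.

Three tree families drive the simulation designs:

* an eight-leaf *balanced* tree (two mirrored four-leaf halves joined by a
  central branch; 13 equal-length branches) used for divergence estimation,
  with branches classed as ``external`` (8 leaf branches), ``middle`` (4
  cherry stems) and ``root`` (the central branch, on which the root sits
  halfway);
* an eight-leaf *polytomy* tree whose root is a degree-4 multifurcation
  joining two short and two long two-leaf subtrees;
* an eight- or 32-leaf *Felsenstein-style* tree: two long and two short
  subtrees separated by a single short internal branch, the classic design
  for provoking long-branch attraction.

Larger supertrees (64 / 512 leaves) embed the balanced tree exactly, so the
induced subtree on the eight core taxa reproduces it branch for branch.
"""

from __future__ import annotations

import io
from itertools import combinations

import numpy as np

__all__ = [
    "PhyloTree",
    "Node",
    "TreeStructureError",
    "NewickParseError",
    "make_balanced_tree",
    "make_polytomy_tree",
    "resolve_polytomy",
    "make_felsenstein_tree",
    "felsenstein_candidates",
    "embed_in_supertree",
    "rf_distance",
    "read_newick",
    "write_newick",
]


class TreeStructureError(ValueError):
    pass


class NewickParseError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "parent", "children", "branch_class")

    def __init__(self, name=None, length=0.0, branch_class=None):
        self.name = name
        self.length = length
        self.parent = None
        self.children = []
        self.branch_class = branch_class

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted container for a (possibly conceptually unrooted) tree.

    Branch lengths live on child nodes (``node.length`` is the edge above
    ``node``); the root's ``length`` is ignored.
    """

    def __init__(self, root: Node):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if len(set(names)) != len(names):
            raise TreeStructureError("leaf labels must be unique")
        for node in self.postorder():
            if node is not self.root and node.length < 0:
                raise TreeStructureError("branch lengths must be non-negative")

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def preorder(self):
        return self.postorder()[::-1]

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self):
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(name)

    # -- measures ----------------------------------------------------------
    def tree_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def scale_to(self, total: float) -> "PhyloTree":
        """Rescale all branch lengths so they sum to ``total`` (in place)."""
        cur = self.tree_length()
        if cur <= 0:
            raise TreeStructureError("cannot scale a zero-length tree")
        for node in self.postorder():
            if node is not self.root:
                node.length *= total / cur
        return self

    def depths(self):
        """Root-to-tip path length per leaf name."""
        out = {}

        def walk(node, d):
            for c in node.children:
                walk(c, d + c.length)
            if node.is_leaf:
                out[node.name] = d

        walk(self.root, 0.0)
        return out

    def path_length_matrix(self):
        """Leaf-to-leaf path length matrix (names sorted), as (names, matrix)."""
        names = sorted(self.leaf_names())
        idx = {n: i for i, n in enumerate(names)}
        below = {}
        dist = np.zeros((len(names), len(names)))
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = [(idx[node.name], 0.0)]
                continue
            merged = []
            kids = [
                [(i, d + c.length) for i, d in below.pop(id(c))]
                for c in node.children
            ]
            for a, b in combinations(kids, 2):
                for i, di in a:
                    for j, dj in b:
                        dist[i, j] = dist[j, i] = di + dj
            for k in kids:
                merged.extend(k)
            below[id(node)] = merged
        return names, dist

    def bipartitions(self):
        """Canonical non-trivial splits of the unrooted tree (frozensets)."""
        all_names = frozenset(self.leaf_names())
        ref = min(all_names)
        splits = set()
        below = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
                continue
            side = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = side
            if node is self.root:
                continue
            if len(side) < 2 or len(all_names - side) < 2:
                continue
            splits.add(side if ref in side else all_names - side)
        return splits

    def copy(self) -> "PhyloTree":
        def clone(node):
            new = Node(node.name, node.length, node.branch_class)
            for c in node.children:
                new.add(clone(c))
            return new

        return PhyloTree(clone(self.root))

    def __repr__(self):
        return f"PhyloTree({len(self.leaves())} leaves, TL={self.tree_length():.4g})"


# ---------------------------------------------------------------------------
# Constructors for the three study-tree families


def _cherry(stem: float, leaf_len: float, names, branch_class=None) -> Node:
    node = Node(length=stem, branch_class=branch_class)
    for nm in names:
        node.add(Node(nm, leaf_len, branch_class="external"))
    return node


def make_balanced_tree(tree_length: float) -> PhyloTree:
    """Eight-leaf balanced tree with 13 equal branches summing to ``tree_length``.

    The root sits halfway along the central branch, so the two root-child
    edges (class ``root``) each carry half of one branch unit.
    """
    if tree_length <= 0:
        raise TreeStructureError("tree_length must be positive")
    b = tree_length / 13.0
    root = Node()
    names = [f"t{i}" for i in range(1, 9)]
    for half, (n1, n2) in zip(range(2), [(names[:2], names[2:4]), (names[4:6], names[6:])]):
        mid = Node(length=b / 2, branch_class="root")
        mid.add(_cherry(b, b, n1, branch_class="middle"))
        mid.add(_cherry(b, b, n2, branch_class="middle"))
        root.add(mid)
    return PhyloTree(root)


def make_polytomy_tree(short_branch: float = 0.06, long_branch: float = 0.7) -> PhyloTree:
    """Eight-leaf tree with a degree-4 root: two short and two long cherries.

    Within each subtree the stem and both leaf branches share one length, so
    root-to-tip depth is twice the branch length (0.12 short / 1.4 long at
    the defaults).
    """
    if short_branch <= 0 or long_branch <= 0:
        raise TreeStructureError("branch lengths must be positive")
    root = Node()
    root.add(_cherry(short_branch, short_branch, ["s1", "s2"], branch_class="short"))
    root.add(_cherry(short_branch, short_branch, ["s3", "s4"], branch_class="short"))
    root.add(_cherry(long_branch, long_branch, ["l1", "l2"], branch_class="long"))
    root.add(_cherry(long_branch, long_branch, ["l3", "l4"], branch_class="long"))
    return PhyloTree(root)


def resolve_polytomy(tree: PhyloTree):
    """The three bifurcating resolutions of a single degree-4 multifurcation.

    Returns ``(candidates, lba_index)``: three trees, each pairing the four
    subtrees across a new zero-length internal branch (a starting value for
    optimization), plus the index of the resolution grouping the two
    longest-depth subtrees together (the LBA candidate).
    """
    root = tree.root
    if len(root.children) != 4:
        raise TreeStructureError(
            "tree must have exactly one degree-4 multifurcation at the root"
        )
    if any(len(n.children) > 3 for n in tree.postorder() if n is not root):
        raise TreeStructureError("multiple multifurcations present")

    def subtree_depth(node):
        return max(
            node.length + d
            for nm, d in PhyloTree(_copy_node(node)).depths().items()
        ) if not node.is_leaf else node.length

    def _copy_node(node):
        new = Node(node.name, 0.0, node.branch_class)
        for c in node.children:
            new.add(_copy_subtree(c))
        return new

    def _copy_subtree(node):
        new = Node(node.name, node.length, node.branch_class)
        for c in node.children:
            new.add(_copy_subtree(c))
        return new

    subs = root.children
    depths = [subtree_depth(s) for s in subs]
    deep_pair = frozenset(sorted(range(4), key=lambda i: -depths[i])[:2])
    pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    candidates, lba_index = [], None
    for k, (pa, pb) in enumerate(pairings):
        new_root = Node()
        inner = Node(length=0.0)
        for i in pa:
            new_root.add(_copy_subtree(subs[i]))
        for i in pb:
            inner.add(_copy_subtree(subs[i]))
        new_root.add(inner)
        candidates.append(PhyloTree(new_root))
        if frozenset(pa) == deep_pair or frozenset(pb) == deep_pair:
            lba_index = k
    return candidates, lba_index


def _balanced_subtree(nleaves: int, depth: float, names, branch_class=None) -> Node:
    """Balanced subtree whose stem-to-tip path is ``depth``, all edges equal."""
    levels = int(np.log2(nleaves)) + 1  # stem + internal levels
    b = depth / levels

    def build(k, nms, is_stem):
        node = Node(length=b, branch_class=branch_class if is_stem else None)
        if k == 1:
            node.name = nms[0]
            node.branch_class = "external" if not is_stem else branch_class
            return node
        half = k // 2
        node.add(build(half, nms[:half], False))
        node.add(build(k - half, nms[half:], False))
        return node

    return build(nleaves, names, True)


def make_felsenstein_tree(
    short_depth: float,
    long_depth: float,
    internal_branch: float,
    ntaxa: int = 8,
) -> PhyloTree:
    """Felsenstein-style tree: two long, two short subtrees, short internal branch.

    In the generating topology each side of the internal branch holds one
    long and one short subtree (the long branches are *not* together, so
    grouping them is the LBA error).  Subtrees are balanced with 2
    (``ntaxa=8``) or 8 (``ntaxa=32``) leaves; all branches within a subtree
    are equal and its attachment-to-tip depth is ``short_depth`` (α) or
    ``long_depth`` (β).
    """
    if short_depth <= 0 or long_depth <= 0 or internal_branch <= 0:
        raise TreeStructureError("depths and internal branch must be positive")
    if ntaxa not in (8, 32):
        raise TreeStructureError("ntaxa must be 8 or 32")
    return _felsenstein_pairing(short_depth, long_depth, internal_branch, ntaxa, 0)


def _felsenstein_subtrees(alpha, beta, ntaxa):
    k = ntaxa // 4
    mk = lambda tag, depth, cls, i: _balanced_subtree(
        k, depth, [f"{tag}{i}_{j}" for j in range(1, k + 1)], branch_class=cls
    )
    return [
        mk("L", beta, "long", 1),
        mk("S", alpha, "short", 1),
        mk("L", beta, "long", 2),
        mk("S", alpha, "short", 2),
    ]


def _felsenstein_pairing(alpha, beta, internal, ntaxa, pairing_index) -> PhyloTree:
    # pairing 0: (L1,S1 | L2,S2)  -- the generating ("correct") topology
    # pairing 1: (L1,L2 | S1,S2)  -- groups the two long subtrees (LBA)
    # pairing 2: (L1,S2 | L2,S1)
    subs = _felsenstein_subtrees(alpha, beta, ntaxa)
    pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (2, 1))]
    pa, pb = pairings[pairing_index]
    root = Node()
    for i in pa:
        root.add(subs[i])
    inner = Node(length=internal, branch_class="internal")
    for i in pb:
        inner.add(subs[i])
    root.add(inner)
    return PhyloTree(root)


def felsenstein_candidates(short_depth, long_depth, internal_branch, ntaxa=8):
    """The three arrangements of the four subtrees around the internal branch.

    Returns ``(candidates, correct_index, lba_index)`` with candidate branch
    lengths set to the generating values (index 0 is the generating tree).
    """
    cands = [
        _felsenstein_pairing(short_depth, long_depth, internal_branch, ntaxa, i)
        for i in range(3)
    ]
    return cands, 0, 1


def embed_in_supertree(core: PhyloTree, n_total: int, seed: int):
    """Embed the eight-taxon core tree exactly inside a larger tree.

    Extra leaves are attached at uniformly random positions along core
    branches (splitting them, which preserves all core path lengths), with
    pendant lengths drawn uniform(0.05, 0.5 × the original core branch
    length).  Returns ``(supertree, core_taxon_names)``; deterministic for a
    given seed.
    """
    if n_total <= len(core.leaf_names()):
        raise TreeStructureError("n_total must exceed the core leaf count")
    rng = np.random.default_rng(seed)
    tree = core.copy()
    core_names = sorted(tree.leaf_names())
    # segments: child nodes whose edge lies on a core path, with the original
    # core branch length they derive from
    segments = [
        (node, node.length)
        for node in tree.postorder()
        if node is not tree.root and node.length > 0
    ]
    for i in range(n_total - len(core_names)):
        k = rng.integers(len(segments))
        node, orig = segments[k]
        pos = rng.uniform(0.0, node.length)
        pend = rng.uniform(0.05, 0.5 * orig)
        parent = node.parent
        split = Node(length=node.length - pos, branch_class=node.branch_class)
        parent.children[parent.children.index(node)] = split
        split.parent = parent
        node.length = pos
        split.add(node)
        split.add(Node(f"x{i + 1}", pend))
        segments[k] = (node, orig)
        segments.append((split, orig))
    return PhyloTree(tree.root), core_names


def induced_subtree_path_lengths(tree: PhyloTree, taxa):
    """Path-length matrix restricted to ``taxa`` (names sorted)."""
    names, D = tree.path_length_matrix()
    keep = sorted(taxa)
    idx = [names.index(t) for t in keep]
    return keep, D[np.ix_(idx, idx)]


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds distance: bipartitions present in exactly one tree."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees must share an identical leaf set")
    return len(t1.bipartitions() ^ t2.bipartitions())


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy)


def read_newick(text: str) -> PhyloTree:
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode):
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def write_newick(tree: PhyloTree) -> str:
    buf = io.StringIO()

    def fmt(node):
        if node.children:
            buf.write("(")
            for i, c in enumerate(node.children):
                if i:
                    buf.write(",")
                fmt(c)
            buf.write(")")
        if node.name:
            buf.write(node.name)
        if node.parent is not None:
            buf.write(f":{node.length:.10g}")

    fmt(tree.root)
    buf.write(";")
    return buf.getvalue()
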