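"""Phylogenetic tree container used across the package.

A :class:`PhyloTree` is a rooted node structure that can also represent an
unrooted tree (conventionally stored with a trifurcating root).  Branch
lengths live on the edge above each node (``node.length``); bootstrap
support values label internal edges and are stored on the child node of the
edge so they survive serialization as internal Newick labels.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator, Optional, Sequence


class Node:
    """One tree node; ``length`` and ``support`` describe the edge above it."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.support: Optional[float] = None
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length}, kids={len(self.children)})"


class NewickError(ValueError):
    """Raised on malformed Newick input; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


class PhyloTree:
    """Rooted or unrooted phylogeny with branch lengths and edge supports."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    # ------------------------------------------------------------------ basics
    def _validate(self) -> None:
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.name!r}")

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def copy(self) -> "PhyloTree":
        def _dup(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            for child in node.children:
                new.add_child(_dup(child))
            return new

        return PhyloTree(_dup(self.root), rooted=self.rooted)

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    # ------------------------------------------------------------- newick I/O
    def to_newick(self, support_decimals: int = 6, length_decimals: int = 10) -> str:
        def fmt_len(x: Optional[float]) -> str:
            if x is None:
                return ""
            return ":" + f"{x:.{length_decimals}g}"

        def fmt_support(x: Optional[float]) -> str:
            if x is None:
                return ""
            if float(x).is_integer():
                return str(int(x))
            return f"{x:.{support_decimals}g}"

        def walk(node: Node) -> str:
            if node.is_leaf:
                return _quote_label(node.name or "") + fmt_len(node.length)
            inner = ",".join(walk(c) for c in node.children)
            label = node.name or fmt_support(node.support)
            return f"({inner}){_quote_label(label)}{fmt_len(node.length)}"

        return walk(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: Optional[bool] = None) -> "PhyloTree":
        root, pos = _parse_newick_node(text, 0)
        # allow trailing whitespace / semicolon
        rest = text[pos:].strip()
        if rest not in ("", ";"):
            raise NewickError(f"unexpected trailing text {rest[:10]!r}", pos)
        # internal labels that parse as numbers are bootstrap supports
        for node in PhyloTree(root)._iter_nodes():
            if node.children and node.name:
                try:
                    node.support = float(node.name)
                    node.name = None
                except ValueError:
                    pass
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    def _iter_nodes(self) -> Iterator[Node]:
        return self.postorder()

    # ---------------------------------------------------------- bipartitions
    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        """Canonical splits: each internal edge as the frozenset of leaf
        names on the side *not* containing the lexicographically smallest
        leaf.  Trivial splits (single leaf) are excluded by default."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        splits: set[frozenset] = set()
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is self.root:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            if not include_trivial and (len(side) < 2 or len(all_leaves - side) < 2):
                continue
            splits.add(side)
        return splits

    def topology_hash(self) -> int:
        return hash((frozenset(self.leaf_names()), frozenset(self.bipartitions())))

    def rf_distance(self, other: "PhyloTree") -> int:
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise ValueError("trees have different leaf sets")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    # ---------------------------------------------------------------- rooting
    def _adjacency(self):
        """Undirected edge map: node -> list of (neighbor, length, support)."""
        adj: dict[int, list] = {}
        nodes: dict[int, Node] = {}
        for node in self.postorder():
            nodes[id(node)] = node
            adj.setdefault(id(node), [])
            for child in node.children:
                length = child.length if child.length is not None else 0.0
                support = child.support if not child.is_leaf else None
                adj[id(node)].append((child, length, support))
                adj.setdefault(id(child), []).append((node, length, support))
        return adj, nodes

    def unrooted(self) -> "PhyloTree":
        """Return an unrooted copy (trifurcating root) of this tree."""
        tree = self.copy()
        root = tree.root
        if len(root.children) == 2:
            a, b = root.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:  # two-leaf tree cannot be unrooted further
                tree.rooted = False
                return tree
            merged = (a.length or 0.0) + (b.length or 0.0)
            root.children = []
            for child in keep.children:
                root.add_child(child)
            fold.length = merged
            if fold.support is None:
                fold.support = keep.support
            root.add_child(fold)
        tree.rooted = False
        return tree

    def root_with_outgroup(self, outgroup: Iterable[str]) -> "PhyloTree":
        """Root on the edge separating ``outgroup`` from everything else.

        The outgroup must form one side of a bipartition of the unrooted
        tree; the split edge's length is divided equally between the two
        root children."""
        outgroup = frozenset(outgroup)
        leaves = frozenset(self.leaf_names())
        missing = outgroup - leaves
        if missing:
            raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
        if not outgroup or outgroup == leaves:
            raise ValueError("outgroup must be a proper non-empty subset of the leaves")
        tree = self.unrooted()
        below: dict[int, frozenset] = {}
        target: Optional[Node] = None
        for node in tree.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is tree.root:
                continue
            if below[id(node)] == outgroup or leaves - below[id(node)] == outgroup:
                target = node
        if target is None:
            raise ValueError(
                f"outgroup {sorted(outgroup)} is not monophyletic in the unrooted tree"
            )
        return _reroot_at_edge(tree, target)

    # -------------------------------------------------------------- monophyly
    def is_monophyletic(self, taxa: Iterable[str]) -> tuple[bool, Optional[Node]]:
        """True iff some node's descendant leaf set equals ``taxa`` exactly."""
        taxa = frozenset(taxa)
        leaves = frozenset(self.leaf_names())
        if not taxa <= leaves:
            raise ValueError(f"taxa not in tree: {sorted(taxa - leaves)}")
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if below[id(node)] == taxa:
                return True, node
        return False, None


def _reroot_at_edge(tree: PhyloTree, child: Node) -> PhyloTree:
    """Place a new root in the middle of the edge above ``child``.

    Rebuilds the tree from the undirected adjacency so supports (edge
    attributes) are preserved regardless of previous orientation."""
    adj, _ = tree._adjacency()
    parent = child.parent
    edge_len = child.length if child.length is not None else 0.0
    edge_support = child.support if not child.is_leaf else None

    def build(node: Node, came_from: Node) -> Node:
        new = Node(node.name if node.is_leaf else None)
        neighbors = adj[id(node)]
        for nbr, length, support in neighbors:
            if nbr is came_from:
                continue
            sub = build(nbr, node)
            sub.length = length
            if not sub.is_leaf:
                sub.support = support
            new.children.append(sub)
            sub.parent = new
        return new

    root = Node()
    left = build(child, parent)
    right = build(parent, child)
    left.length = right.length = edge_len / 2.0
    if not left.is_leaf:
        left.support = edge_support
    if not right.is_leaf:
        right.support = edge_support
    root.add_child(left)
    root.add_child(right)
    return PhyloTree(root, rooted=True)


# ------------------------------------------------------------------ consensus
def majority_rule_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Strict >50% majority-rule consensus with percentage labels.

    All input trees must share one leaf set.  Retained bipartitions are
    pairwise compatible by construction and are assembled into a tree rooted
    arbitrarily at the reference leaf's side."""
    if not trees:
        raise ValueError("no input trees")
    leaf_set = frozenset(trees[0].leaf_names())
    for t in trees[1:]:
        if frozenset(t.leaf_names()) != leaf_set:
            raise ValueError("input trees have differing leaf sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    kept = {s: 100.0 * c / n for s, c in counts.items() if c * 2 > n}

    # nested construction: larger clades first (splits are the side without
    # the reference leaf, so they behave as clades of a ref-rooted tree)
    root = Node()
    for name in sorted(leaf_set):
        root.add_child(Node(name))
    for split in sorted(kept, key=len, reverse=True):
        _insert_clade(root, split, kept[split])
    return PhyloTree(root, rooted=False)


def _insert_clade(root: Node, clade: frozenset, support: float) -> None:
    """Group the children of the smallest node containing ``clade``."""
    node = root
    while True:
        for child in node.children:
            below = frozenset(l.name for l in _leaves_under(child))
            if clade < below:
                node = child
                break
        else:
            break
    members = [c for c in node.children
               if frozenset(l.name for l in _leaves_under(c)) <= clade]
    covered = frozenset().union(*(frozenset(l.name for l in _leaves_under(c))
                                  for c in members))
    if covered != clade:  # incompatible with an already-inserted split
        return
    new = Node()
    new.support = support
    for m in members:
        node.children.remove(m)
        new.add_child(m)
    node.add_child(new)


def _leaves_under(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


# ------------------------------------------------------------- newick parser
_LABEL_STOP = set("(),:;[]")


def _quote_label(label: str) -> str:
    if label and any(c in label for c in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _parse_label(text: str, pos: int) -> tuple[str, int]:
    if pos < len(text) and text[pos] == "'":
        out, i = [], pos + 1
        while i < len(text):
            if text[i] == "'":
                if i + 1 < len(text) and text[i + 1] == "'":
                    out.append("'")
                    i += 2
                    continue
                return "".join(out), i + 1
            out.append(text[i])
            i += 1
        raise NewickError("unterminated quoted label", pos)
    i = pos
    while i < len(text) and text[i] not in _LABEL_STOP and not text[i].isspace():
        i += 1
    return text[pos:i], i


def _parse_newick_node(text: str, pos: int) -> tuple[Node, int]:
    while pos < len(text) and text[pos].isspace():
        pos += 1
    if pos >= len(text):
        raise NewickError("unexpected end of input", pos)
    node = Node()
    if text[pos] == "(":
        open_pos = pos
        pos += 1
        while True:
            child, pos = _parse_newick_node(text, pos)
            node.add_child(child)
            while pos < len(text) and text[pos].isspace():
                pos += 1
            if pos >= len(text):
                raise NewickError("unbalanced parentheses", open_pos)
            if text[pos] == ",":
                pos += 1
                continue
            if text[pos] == ")":
                pos += 1
                break
            raise NewickError(f"expected ',' or ')', found {text[pos]!r}", pos)
    label, pos = _parse_label(text, pos)
    if label:
        node.name = label
    if pos < len(text) and text[pos] == ":":
        pos += 1
        start = pos
        while pos < len(text) and (text[pos] in "+-.eE" or text[pos].isdigit()):
            pos += 1
        try:
            node.length = float(text[start:pos])
        except ValueError:
            raise NewickError(f"malformed branch length {text[start:pos]!r}", start)
        if not math.isfinite(node.length):
            raise NewickError("non-finite branch length", start)
    return node, pos


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
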