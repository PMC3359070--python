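"""Unrooted phylogenetic trees: structure, Newick I/O and split algebra.

The package's central object is an unrooted, leaf-labelled tree whose edge
lengths are expected substitutions per site.  Trees are stored as an
adjacency map between integer node ids; leaves carry unique string labels.
A node of any degree is accepted in memory, but the simulation-study
builders always produce fully resolved trees (internal nodes of degree 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "Tree",
    "Bipartition",
    "NewickError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "rf_distance",
    "prune_taxa",
    "nni_neighbors",
]


@dataclass(frozen=True)
class Bipartition:
    """One side of a two-way split of the leaf set, canonically oriented.

    The stored side is the one *not* containing the lexicographically
    smallest leaf label, so equal splits compare equal regardless of which
    side they were built from.
    """

    side: frozenset

    @classmethod
    def from_split(cls, side: Iterable[str], all_leaves: Iterable[str]) -> "Bipartition":
        side = frozenset(side)
        all_leaves = frozenset(all_leaves)
        if not side or side == all_leaves:
            raise ValueError("a bipartition needs two non-empty sides")
        if not side <= all_leaves:
            raise ValueError("split side contains labels outside the leaf set")
        anchor = min(all_leaves)
        if anchor in side:
            side = all_leaves - side
        return cls(side)

    def __iter__(self):
        return iter(self.side)

    def __len__(self):
        return len(self.side)


class NewickError(ValueError):
    """Malformed Newick input; `pos` is the 0-based character position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at character {pos})")
        self.pos = pos


class Tree:
    """Unrooted tree over integer node ids with labelled leaves."""

    def __init__(self) -> None:
        self._adj: dict[int, dict[int, float]] = {}
        self._label: dict[int, str] = {}
        self._next = 0

    # -- construction -------------------------------------------------

    def add_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self._adj[nid] = {}
        if label is not None:
            if not label:
                raise ValueError("leaf labels must be non-empty")
            if label in self._label.values():
                raise ValueError(f"duplicate leaf label {label!r}")
            self._label[nid] = label
        return nid

    def connect(self, u: int, v: int, length: float) -> None:
        length = float(length)
        if not length >= 0 or length != length or length == float("inf"):
            raise ValueError(f"edge length must be finite and >= 0, got {length}")
        if u == v:
            raise ValueError("self edges are not allowed")
        self._adj[u][v] = length
        self._adj[v][u] = length

    def disconnect(self, u: int, v: int) -> float:
        length = self._adj[u].pop(v)
        self._adj[v].pop(u)
        return length

    def remove_node(self, v: int) -> None:
        for w in list(self._adj[v]):
            self.disconnect(v, w)
        del self._adj[v]
        self._label.pop(v, None)

    def copy(self) -> "Tree":
        t = Tree()
        t._adj = {u: dict(nb) for u, nb in self._adj.items()}
        t._label = dict(self._label)
        t._next = self._next
        return t

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return list(self._adj)

    def neighbors(self, v: int) -> dict[int, float]:
        return self._adj[v]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def is_leaf(self, v: int) -> bool:
        return v in self._label

    def label_of(self, v: int) -> str:
        return self._label[v]

    def leaf_ids(self) -> dict[str, int]:
        return {lab: nid for nid, lab in self._label.items()}

    def leaf_labels(self) -> frozenset:
        return frozenset(self._label.values())

    @property
    def n_leaves(self) -> int:
        return len(self._label)

    def edges(self) -> Iterator[tuple[int, int, float]]:
        for u, nb in self._adj.items():
            for v, length in nb.items():
                if u < v:
                    yield u, v, length

    def length(self, u: int, v: int) -> float:
        return self._adj[u][v]

    def set_length(self, u: int, v: int, length: float) -> None:
        length = float(length)
        if not length >= 0 or length == float("inf"):
            raise ValueError(f"edge length must be finite and >= 0, got {length}")
        self._adj[u][v] = length
        self._adj[v][u] = length

    def side_leaves(self, u: int, v: int) -> frozenset:
        """Labels of the leaves on the ``v`` side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            w = stack.pop()
            if w in self._label:
                out.append(self._label[w])
            for x in self._adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(out)

    def internal_edges(self) -> list[tuple[int, int]]:
        """Edges with both endpoints internal (induce non-trivial splits)."""
        return [
            (u, v)
            for u, v, _ in self.edges()
            if not self.is_leaf(u) and not self.is_leaf(v)
        ]

    def path_length(self, a: str, b: str) -> float:
        ids = self.leaf_ids()
        start, goal = ids[a], ids[b]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            w = stack.pop()
            if w == goal:
                return dist[w]
            for x, ln in self._adj[w].items():
                if x not in dist:
                    dist[x] = dist[w] + ln
                    stack.append(x)
        raise ValueError("tree is disconnected")

    # -- invariant check ----------------------------------------------

    def validate(self) -> None:
        for v in self._adj:
            if v in self._label and len(self._adj[v]) > 1:
                raise ValueError(f"labelled node {self._label[v]!r} is not a tip")
        n_nodes = len(self._adj)
        n_edges = sum(len(nb) for nb in self._adj.values()) // 2
        if n_nodes and n_edges != n_nodes - 1:
            raise ValueError("edge count inconsistent with a tree")


# -- Newick ------------------------------------------------------------

_LABEL_STOP = set("(),:;")


def parse_newick(text: str) -> Tree:
    """Parse a single Newick tree; degree-2 nodes are suppressed (unrooted).

    Branch lengths are optional on input; internal node labels are accepted
    and discarded.  Raises :class:`NewickError` with a character position on
    malformed input.
    """
    tree = Tree()
    s = text
    pos = 0

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_STOP and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def read_length() -> float:
        nonlocal pos
        skip_ws()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None
        return 0.0

    def read_clade() -> tuple[int, float]:
        nonlocal pos
        skip_ws()
        if pos >= len(s):
            raise NewickError("unexpected end of input", pos)
        if s[pos] == "(":
            open_pos = pos
            pos += 1
            children = [read_clade()]
            skip_ws()
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(read_clade())
                skip_ws()
            if pos >= len(s) or s[pos] != ")":
                raise NewickError("unbalanced parentheses", open_pos)
            pos += 1
            read_label()  # internal label, ignored
            node = tree.add_node()
            for child, ln in children:
                tree.connect(node, child, ln)
            return node, read_length()
        label = read_label()
        if not label:
            raise NewickError("expected a leaf label", pos)
        try:
            node = tree.add_node(label)
        except ValueError as exc:
            raise NewickError(str(exc), pos - len(label)) from None
        return node, read_length()

    root, _ = read_clade()
    skip_ws()
    if pos >= len(s) or s[pos] != ";":
        raise NewickError("missing semicolon", pos)
    pos += 1
    skip_ws()
    if pos != len(s):
        raise NewickError("trailing characters after semicolon", pos)

    # suppress degree-2 nodes left by rooted serializations
    for v in list(tree._adj):
        if tree.degree(v) == 2 and not tree.is_leaf(v):
            (a, la), (b, lb) = tree._adj[v].items()
            tree.remove_node(v)
            tree.connect(a, b, la + lb)
    return tree


def _format_length(length: float) -> str:
    return format(float(length), ".10g")


def write_newick(tree: Tree) -> str:
    """Serialize to Newick with branch lengths to 10 significant digits.

    The serialization root is an arbitrary internal node (highest degree,
    smallest id as tie-break); the choice does not affect the unrooted
    topology or any split.
    """
    if tree.n_leaves == 0:
        raise ValueError("cannot serialize an empty tree")
    if tree.n_leaves == 1:
        return tree.label_of(tree.nodes[0]) + ";"
    if tree.n_leaves == 2:
        (u, v, ln), = tree.edges()
        return f"({tree.label_of(u)}:{_format_length(ln)},{tree.label_of(v)}:0);"
    internal = [v for v in tree.nodes if not tree.is_leaf(v)]
    root = max(internal, key=lambda v: (tree.degree(v), -v)) if internal else tree.nodes[0]

    def subtree(v: int, parent: int | None) -> str:
        if tree.is_leaf(v):
            return tree.label_of(v)
        parts = [
            f"{subtree(w, v)}:{_format_length(ln)}"
            for w, ln in tree.neighbors(v).items()
            if w != parent
        ]
        return "(" + ",".join(parts) + ")"

    return subtree(root, None) + ";"


# -- split algebra -----------------------------------------------------


def bipartitions(tree: Tree) -> frozenset:
    """Non-trivial splits (those induced by internal edges)."""
    leaves = tree.leaf_labels()
    if len(leaves) < 3:
        raise ValueError("bipartitions need at least 3 leaves")
    return frozenset(
        Bipartition.from_split(tree.side_leaves(u, v), leaves)
        for u, v in tree.internal_edges()
    )


def rf_distance(tree1: Tree, tree2: Tree) -> int:
    """Robinson–Foulds distance: |symmetric difference of split sets|."""
    l1, l2 = tree1.leaf_labels(), tree2.leaf_labels()
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first = {sorted(l1 - l2)}, "
            f"only in second = {sorted(l2 - l1)}"
        )
    return len(bipartitions(tree1) ^ bipartitions(tree2))


def prune_taxa(tree: Tree, keep: Iterable[str]) -> Tree:
    """Restriction of the tree to ``keep``; suppressed edges sum lengths."""
    keep = frozenset(keep)
    unknown = keep - tree.leaf_labels()
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 3:
        raise ValueError("need at least 3 leaves after pruning")
    t = tree.copy()
    # iteratively strip unwanted tips and bare internal tips they expose
    changed = True
    while changed:
        changed = False
        for v in list(t._adj):
            if t.degree(v) <= 1 and (not t.is_leaf(v) or t.label_of(v) not in keep):
                t.remove_node(v)
                changed = True
    for v in list(t._adj):
        if t.degree(v) == 2 and not t.is_leaf(v):
            (a, la), (b, lb) = t._adj[v].items()
            t.remove_node(v)
            t.connect(a, b, la + lb)
    return t


# -- NNI ---------------------------------------------------------------


def nni_neighbors(tree: Tree) -> list[tuple[Tree, tuple[int, int]]]:
    """All nearest-neighbor-interchange rearrangements of a resolved tree.

    Returns ``(neighbor, (u, v))`` pairs where (u, v) is the internal edge
    (node ids valid in the neighbor) around which subtrees were swapped.
    Each internal edge yields its two distinct rearrangements.
    """
    out = []
    for u, v in tree.internal_edges():
        u_nb = [w for w in tree.neighbors(u) if w != v]
        v_nb = [w for w in tree.neighbors(v) if w != u]
        if len(u_nb) != 2 or len(v_nb) != 2:
            continue  # multifurcation: no elementary swap defined here
        b = u_nb[1]
        for c in v_nb:
            t = tree.copy()
            lb = t.disconnect(u, b)
            lc = t.disconnect(v, c)
            t.connect(u, c, lc)
            t.connect(v, b, lb)
            out.append((t, (u, v)))
    return out
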