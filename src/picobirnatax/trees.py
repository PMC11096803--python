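"""Phylogenetic tree model, Newick I/O, rooting, and bipartition machinery.

Trees are stored as mutable node hierarchies. Branch support values
(SH-aLRT-style percentages in [0, 100]) are attached to internal nodes and
conceptually belong to the edge above the node; rerooting moves them with
their edge. Polytomies are first class and are never silently resolved.

Two Newick support dialects are accepted: numeric internal-node labels
(IQ-TREE style, ``(...)85:0.1``) and bracketed numeric comments
(``(...)[85]:0.1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence


class NewickParseError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


@dataclass(eq=False)
class Node:
    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def tips(self) -> Iterator["Node"]:
        if self.is_tip:
            yield self
        else:
            for child in self.children:
                yield from child.tips()

    def tip_set(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tips())


class Tree:
    """A (possibly unrooted) phylogeny.

    An unrooted tree is stored rooted at an arbitrary node with
    ``rooted=False``; bipartition extraction is independent of that choice.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- basic accessors -------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def tips(self) -> list[Node]:
        return list(self.root.tips())

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.root.tips()]

    def tip_set(self) -> frozenset[str]:
        return self.root.tip_set()

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.root.tips())

    def find_tip(self, label: str) -> Node:
        for t in self.root.tips():
            if t.label == label:
                return t
        raise KeyError(f"tip label not in tree: {label!r}")

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        return [
            n
            for n in self.postorder()
            if not n.is_tip and (include_root or n is not self.root)
        ]

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(label=node.label, length=node.length, support=node.support)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return Tree(rec(self.root), rooted=self.rooted)

    def _validate(self) -> None:
        labels = [t.label for t in self.root.tips()]
        if any(lab is None for lab in labels):
            raise TreeValidationError("every tip must carry a label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeValidationError(
                f"duplicate tip labels: {sorted(dupes)}"
            )
        for n in self.postorder():
            if n.length is not None and n.length < 0:
                raise TreeValidationError(
                    f"negative branch length {n.length} on node {n.label!r}"
                )
            if n.support is not None and not (0 <= n.support <= 100):
                raise TreeValidationError(
                    f"support {n.support} outside [0, 100]"
                )

    # -- topology edits --------------------------------------------------

    def suppress_unifurcations(self) -> None:
        """Remove internal nodes with a single child, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_tip or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    if node.length is not None and child.length is not None:
                        child.length = child.length + node.length
                    elif child.length is None:
                        child.length = node.length
                    parent.children[idx] = child
                    child.parent = parent
                changed = True

    def reroot_at_node(self, node: Node) -> None:
        """Make ``node`` the root, reversing edges on the path to the old root.

        Edge lengths and supports travel with their edges. Any resulting
        unifurcation at the old root is suppressed.
        """
        if node is self.root:
            return
        chain = []
        n = node
        while n.parent is not None:
            chain.append((n, n.parent))
            n = n.parent
        for child, parent in reversed(chain):
            parent.children.remove(child)
            child.children.append(parent)
            parent.parent = child
            parent.length = child.length
            parent.support = child.support
        node.parent = None
        node.length = None
        node.support = None
        self.root = node
        self.suppress_unifurcations()

    def reroot_on_edge(self, child: Node, dist_below: float) -> None:
        """Root on the edge above ``child``, ``dist_below`` from ``child``.

        The edge's support is replicated on both root-adjacent halves (they
        represent the same bipartition).
        """
        if child.parent is None:
            raise ValueError("cannot root on the edge above the root")
        if child.length is None:
            raise ValueError("edge has no length")
        if not (0 <= dist_below <= child.length):
            raise ValueError("dist_below outside edge length")
        parent = child.parent
        new = Node(length=child.length - dist_below, support=child.support)
        idx = parent.children.index(child)
        parent.children[idx] = new
        new.parent = parent
        new.add_child(child)
        child.length = dist_below
        self.reroot_at_node(new)
        self.rooted = True


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------


def _parse_label(text: str, i: int) -> tuple[Optional[str], int]:
    if i < len(text) and text[i] == "'":
        j = i + 1
        out = []
        while True:
            if j >= len(text):
                raise NewickParseError("unterminated quoted label", i)
            if text[j] == "'":
                if j + 1 < len(text) and text[j + 1] == "'":
                    out.append("'")
                    j += 2
                    continue
                return "".join(out), j + 1
            out.append(text[j])
            j += 1
    j = i
    while j < len(text) and text[j] not in "(),:;[]'":
        j += 1
    label = text[i:j].strip()
    return (label or None), j


def _parse_comment(text: str, i: int) -> tuple[Optional[str], int]:
    if i < len(text) and text[i] == "[":
        j = text.find("]", i)
        if j == -1:
            raise NewickParseError("unterminated comment", i)
        return text[i + 1 : j], j + 1
    return None, i


def _as_support(raw: Optional[str]) -> Optional[float]:
    if raw is None:
        return None
    s = raw.strip().lstrip("&")
    try:
        val = float(s)
    except ValueError:
        return None
    return val if 0 <= val <= 100 else None


def parse_newick(text: str, rooted: Optional[bool] = None) -> Tree:
    """Parse one Newick tree.

    Internal-node support is read from numeric node labels or numeric
    bracket comments (values in [0, 100]); non-numeric labels are kept as
    names. ``rooted=None`` infers rootedness from the root degree: a basal
    bifurcation is treated as rooted, a basal polytomy as unrooted.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty input", 0)

    def parse_clade(i: int) -> tuple[Node, int]:
        node = Node()
        if text[i] == "(":
            i += 1
            while True:
                child, i = parse_clade(i)
                node.add_child(child)
                if i >= len(text):
                    raise NewickParseError("unbalanced parentheses", i)
                if text[i] == ",":
                    i += 1
                    continue
                if text[i] == ")":
                    i += 1
                    break
                raise NewickParseError(
                    f"expected ',' or ')', found {text[i]!r}", i
                )
            label, i = _parse_label(text, i)
            comment, i = _parse_comment(text, i)
            support = _as_support(label)
            if support is not None:
                node.support = support
            else:
                node.label = label
                node.support = _as_support(comment)
        else:
            if text[i] in "),;:":
                raise NewickParseError("expected a tip label", i)
            label, i = _parse_label(text, i)
            _, i = _parse_comment(text, i)
            node.label = label
        if i < len(text) and text[i] == ":":
            j = i + 1
            k = j
            while k < len(text) and text[k] not in "(),;[]":
                k += 1
            try:
                node.length = float(text[j:k].strip())
            except ValueError:
                raise NewickParseError("malformed branch length", j) from None
            i = k
            comment, i = _parse_comment(text, i)
            if node.support is None and not node.is_tip:
                node.support = _as_support(comment)
        return node, i

    root, i = parse_clade(0)
    if i >= len(text) or text[i] != ";":
        raise NewickParseError("expected ';' terminating the tree", i)
    if rooted is None:
        rooted = len(root.children) == 2 or root.is_tip or len(root.children) == 1
    return Tree(root, rooted=rooted)


_UNQUOTED_SAFE = set(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-/|"
)


def _format_label(label: str) -> str:
    if label and all(c in _UNQUOTED_SAFE for c in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Tree, support_as_label: bool = True) -> str:
    """Serialize a tree; supports written as internal-node labels by default."""

    def rec(node: Node) -> str:
        if node.is_tip:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.support is not None:
                if support_as_label:
                    s += repr(node.support) if node.support % 1 else str(int(node.support))
                else:
                    s += f"[{node.support!r}]"
            elif node.label is not None:
                s += _format_label(node.label)
        if node.length is not None:
            s += f":{node.length!r}"
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


def _undirected_adjacency(tree: Tree) -> dict[Node, list[tuple[Node, float]]]:
    adj: dict[Node, list[tuple[Node, float]]] = {}
    for node in tree.postorder():
        adj.setdefault(node, [])
        for c in node.children:
            if c.length is None:
                raise ValueError("midpoint rooting requires all branch lengths")
            adj[node].append((c, c.length))
            adj.setdefault(c, []).append((node, c.length))
    return adj


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path.

    Ties among maximal paths are broken by the lexicographically smallest
    (sorted) tip-label pair. Returns a new rooted tree.
    """
    tree = tree.copy()
    tips = tree.tips()
    if len(tips) < 2:
        tree.rooted = True
        return tree
    adj = _undirected_adjacency(tree)

    def distances_from(src: Node) -> dict[Node, float]:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            n = stack.pop()
            for nb, w in adj[n]:
                if nb not in dist:
                    dist[nb] = dist[n] + w
                    stack.append(nb)
        return dist

    best: Optional[tuple[float, tuple[str, str], Node, Node]] = None
    tipdist = {t: distances_from(t) for t in tips}
    for a in tips:
        for b in tips:
            if a.label >= b.label:
                continue
            d = tipdist[a][b]
            key = (a.label, b.label)
            if best is None or d > best[0] + 1e-12 or (
                abs(d - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (d, key, a, b)
    total, _, a, b = best
    # walk the unique a->b path accumulating length until total/2
    parent_of: dict[Node, tuple[Optional[Node], float]] = {a: (None, 0.0)}
    stack = [a]
    while stack:
        n = stack.pop()
        for nb, w in adj[n]:
            if nb not in parent_of:
                parent_of[nb] = (n, w)
                stack.append(nb)
    path = [b]
    while path[-1] is not a:
        path.append(parent_of[path[-1]][0])
    path.reverse()  # a ... b
    target = total / 2.0
    acc = 0.0
    for prev, nxt in zip(path, path[1:]):
        w = next(wt for nb, wt in adj[prev] if nb is nxt)
        if acc + w >= target - 1e-12:
            offset = target - acc  # distance from `prev` along edge prev-nxt
            if offset <= 1e-12:
                tree.reroot_at_node(prev)
                tree.rooted = True
                return tree
            if w - offset <= 1e-12:
                tree.reroot_at_node(nxt)
                tree.rooted = True
                return tree
            # edge is stored on whichever of prev/nxt is the child
            if nxt.parent is prev:
                tree.reroot_on_edge(nxt, w - offset)
            else:
                tree.reroot_on_edge(prev, offset)
            return tree
        acc += w
    raise AssertionError("midpoint not found on path")  # pragma: no cover


class OutgroupError(ValueError):
    pass


def root_with_outgroup(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Root on the stem edge separating ``outgroup`` tips from the rest.

    The outgroup must form one side of an edge under some rooting; otherwise
    an :class:`OutgroupError` names the tips that break monophyly.
    """
    out = frozenset(outgroup)
    if not out:
        raise ValueError("outgroup is empty")
    tree = tree.copy()
    taxa = tree.tip_set()
    missing = out - taxa
    if missing:
        raise KeyError(f"outgroup tips not in tree: {sorted(missing)}")
    if out == taxa:
        raise OutgroupError("outgroup contains every tip")
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = node.tip_set()
        if side == out or side == taxa - out:
            if node.length is not None:
                tree.reroot_on_edge(node, node.length / 2.0)
            else:
                node.length = 0.0
                tree.reroot_on_edge(node, 0.0)
            tree.rooted = True
            return tree
    # diagnose: find the clade that best covers the outgroup and report strays
    mrca_node = mrca(tree, out) if len(tree.root.children) else tree.root
    strays = sorted(mrca_node.tip_set() - out)
    raise OutgroupError(
        f"outgroup {sorted(out)} is not monophyletic under any rooting; "
        f"conflicting ingroup tips inside its smallest covering clade: {strays}"
    )


# ---------------------------------------------------------------------------
# Bipartitions / monophyly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial unrooted split, canonicalized to its smaller side.

    Equal-sized sides tie-break to the lexicographically smaller sorted
    tip-label tuple, so the representation is rooting-invariant.
    """

    side: frozenset[str]

    @staticmethod
    def canonical(side: frozenset[str], taxa: frozenset[str]) -> "Bipartition":
        other = taxa - side
        if len(side) < len(other):
            return Bipartition(side)
        if len(other) < len(side):
            return Bipartition(other)
        return Bipartition(min(side, other, key=lambda s: tuple(sorted(s))))


def bipartitions(tree: Tree) -> set[Bipartition]:
    """All non-trivial splits induced by internal edges.

    Rooting-invariant: the two root-adjacent edges of a rooted bifurcating
    tree induce the same split, which is collected once. Trees with fewer
    than four tips have no non-trivial splits.
    """
    taxa = tree.tip_set()
    if len(taxa) < 4:
        return set()
    out: set[Bipartition] = set()
    for node in tree.postorder():
        if node is tree.root or node.is_tip:
            continue
        side = node.tip_set()
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        out.add(Bipartition.canonical(side, taxa))
    return out


def mrca(tree: Tree, tips: Iterable[str]) -> Node:
    """Most recent common ancestor of ``tips`` on a rooted tree."""
    want = set(tips)
    if not want:
        raise ValueError("empty tip set")
    unknown = want - set(tree.tip_labels())
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    node = tree.find_tip(next(iter(want)))
    while not want <= set(n.label for n in node.tips()):
        node = node.parent
    return node


def is_monophyletic(
    tree: Tree, tips: Iterable[str]
) -> tuple[bool, Optional[float]]:
    """Whether ``tips`` form an exact clade; returns (flag, MRCA support)."""
    want = frozenset(tips)
    node = mrca(tree, want)
    return node.tip_set() == want, node.support


def restrict_to(tree: Tree, tips: Iterable[str]) -> Tree:
    """Induced subtree on ``tips``; unifurcations suppressed."""
    keep = set(tips)
    unknown = keep - set(tree.tip_labels())
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    tree = tree.copy()

    def rec(node: Node) -> Optional[Node]:
        if node.is_tip:
            return node if node.label in keep else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    new_root = rec(tree.root)
    if new_root is None:
        raise ValueError("restriction removed every tip")
    new_root.parent = None
    out = Tree(new_root, rooted=tree.rooted)
    out.suppress_unifurcations()
    return out
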