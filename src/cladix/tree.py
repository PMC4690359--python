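"""Rooted trees, Newick I/O, clade (bipartition) logic and consensus.

Trees are rooted throughout the package: the search module roots on the
designated outgroup, and all supports, synapomorphies and reconstructions
are reported on rooted clades.  Polytomies are first-class — every
algorithm accepts multifurcating nodes.
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Iterable, Iterator, Sequence

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "majority_rule_consensus",
    "parse_newick",
    "prune_to_common_taxa",
    "strict_consensus",
    "tree_from_clades",
    "write_newick",
]


class TreeError(ValueError):
    pass


class Node:
    """A node of a rooted tree.

    ``label`` is the taxon name on leaves and an optional annotation
    label on internal nodes; ``length`` is the branch length to the
    parent (``None`` when absent); ``annotations`` carries support
    values, ages and reconstruction vectors.
    """

    __slots__ = ("children", "parent", "label", "length", "annotations")

    def __init__(self, label: str | None = None,
                 length: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.length = length
        self.annotations: dict = {}

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        # Iterative to stay safe on pectinate trees of hundreds of leaves.
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:
        return f"<Node {self.label!r} children={len(self.children)}>"


class Tree:
    """A rooted, possibly multifurcating tree with unique leaf labels."""

    def __init__(self, root: Node):
        self.root = root
        labels = [lf.label for lf in root.leaves()]
        if any(l is None for l in labels):
            raise TreeError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")

    # -- basics ---------------------------------------------------------
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.label for lf in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length)
            c.annotations = dict(node.annotations)
            for ch in node.children:
                c.add_child(clone(ch))
            return c
        return Tree(clone(self.root))

    def find_leaf(self, label: str) -> Node:
        for lf in self.leaves():
            if lf.label == label:
                return lf
        raise KeyError(label)

    # -- clades ---------------------------------------------------------
    def clades(self, include_trivial: bool = False
               ) -> set[frozenset[str]]:
        """Leaf-label sets of internal branches (rooted bipartitions).

        Trivial clades (single leaves and the full leaf universe) are
        excluded unless requested.
        """
        universe = self.leaf_names()
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if include_trivial or (1 < len(s) < len(universe)):
                    out.add(s)
        if include_trivial:
            out |= {frozenset([l]) for l in universe}
            out.add(universe)
        return out

    def clade_map(self) -> dict[int, frozenset[str]]:
        """id(node) → leaf set below, for annotation workflows."""
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
        return below

    def __repr__(self) -> str:
        return f"<Tree {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# Newick I/O


def _quote_label(label: str) -> str:
    if any(c in label for c in " \t(),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, include_support: bool = False) -> str:
    """Serialize to Newick; branch lengths keep full precision."""
    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = _quote_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += _quote_label(node.label)
            elif include_support and "support" in node.annotations:
                s += f"{node.annotations['support']:g}"
        if node.length is not None:
            s += f":{node.length!r}"
        return s

    return fmt(tree.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse one Newick tree; errors name the offending position."""
    s = text.strip()
    if not s.endswith(";"):
        raise TreeError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> TreeError:
        return TreeError(f"{msg} at position {pos}")

    def parse_label() -> str | None:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            j = pos + 1
            out = []
            while True:
                k = s.find("'", j)
                if k < 0:
                    raise error("unterminated quoted label")
                if k + 1 < len(s) and s[k + 1] == "'":
                    out.append(s[j:k + 1])
                    j = k + 2
                else:
                    out.append(s[j:k])
                    pos = k + 1
                    return "".join(out)
        j = pos
        while j < len(s) and s[j] not in "(),:;":
            j += 1
        label = s[pos:j].strip()
        pos = j
        return label or None

    def parse_length() -> float | None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            j = pos
            while j < len(s) and s[j] not in "(),;":
                j += 1
            try:
                val = float(s[pos:j])
            except ValueError:
                raise error(f"bad branch length {s[pos:j]!r}")
            pos = j
            return val
        return None

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            node.label = parse_label()
        else:
            label = parse_label()
            if label is None:
                raise error("expected a leaf label")
            node.label = label
        node.length = parse_length()
        return node

    root = parse_node()
    if pos != len(s):
        raise error(f"trailing characters {s[pos:]!r}")
    return Tree(root)


# ---------------------------------------------------------------------------
# consensus


def _check_same_leaves(trees: Sequence[Tree]) -> frozenset[str]:
    first = trees[0].leaf_names()
    for t in trees[1:]:
        if t.leaf_names() != first:
            diff = sorted(first ^ t.leaf_names())
            raise TreeError(
                f"trees have different leaf sets; symmetric difference: {diff}")
    return first


def tree_from_clades(universe: Iterable[str],
                     clades: Iterable[frozenset[str]],
                     annotate: Callable[[frozenset[str]], dict] | None = None
                     ) -> Tree:
    """Build the rooted tree whose internal branches are exactly the given
    pairwise-compatible non-trivial clades."""
    universe = frozenset(universe)
    nodes: dict[frozenset[str], Node] = {}
    ordered = sorted(set(clades) | {universe}, key=len, reverse=True)
    for clade in ordered:
        n = Node()
        if annotate is not None and clade != universe:
            n.annotations.update(annotate(clade))
        nodes[clade] = n
    # attach each clade/leaf to the smallest strict superset
    def smallest_superset(s: frozenset[str]) -> Node:
        best = None
        for clade in ordered:
            if len(clade) > len(s) and s < clade:
                if best is None or len(clade) < len(best):
                    best = clade
        return nodes[best]

    for clade in ordered:
        if clade != universe:
            smallest_superset(clade).add_child(nodes[clade])
    for leaf in sorted(universe):
        smallest_superset(frozenset([leaf])).add_child(Node(leaf))
    return Tree(nodes[universe])


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the clades present in every input tree."""
    if not trees:
        raise TreeError("strict_consensus needs at least one tree")
    universe = _check_same_leaves(trees)
    shared = trees[0].clades()
    for t in trees[1:]:
        shared &= t.clades()
    return tree_from_clades(universe, shared)


def majority_rule_consensus(trees: Sequence[Tree],
                            threshold: float = 0.5) -> Tree:
    """Tree of clades occurring with frequency strictly above ``threshold``.

    Frequencies are annotated on internal nodes as ``support``.  A clade
    at exactly the threshold frequency is excluded.  Thresholds below 0.5
    could admit incompatible clades and are rejected.
    """
    if not trees:
        raise TreeError("majority_rule_consensus needs at least one tree")
    if threshold < 0.5:
        raise TreeError("threshold must be >= 0.5 for a well-defined tree")
    universe = _check_same_leaves(trees)
    counts: Counter[frozenset[str]] = Counter()
    for t in trees:
        counts.update(t.clades())
    n = len(trees)
    keep = {c for c, k in counts.items() if k / n > threshold}
    freq = {c: counts[c] / n for c in keep}
    return tree_from_clades(universe, keep,
                            annotate=lambda c: {"support": freq[c]})


# ---------------------------------------------------------------------------
# taxon-set trimming


def _prune_to(tree: Tree, keep: frozenset[str]) -> Tree:
    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kids = [b for b in (build(c) for c in node.children) if b is not None]
        if not kids:
            return None
        if len(kids) == 1:
            # suppress the degree-2 node; branch lengths add up
            child = kids[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        new = Node(node.label, node.length)
        for k in kids:
            new.add_child(k)
        return new

    pruned = build(tree.root)
    assert pruned is not None
    pruned.length = None  # a root branch has no meaning
    return Tree(pruned)


def prune_to_common_taxa(tree_a: Tree, tree_b: Tree) -> tuple[Tree, Tree]:
    """Restrict both trees to their shared leaf set (≥3 taxa), suppressing
    the degree-2 nodes that pruning creates."""
    shared = tree_a.leaf_names() & tree_b.leaf_names()
    if len(shared) < 3:
        raise TreeError(
            f"only {len(shared)} shared taxa; at least 3 are required")
    return _prune_to(tree_a, shared), _prune_to(tree_b, shared)
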