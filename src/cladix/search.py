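"""Heuristic maximum-parsimony search.

The search machinery follows the traditional cladistic protocol:
replicated random stepwise addition followed by tree
bisection–reconnection (TBR) branch swapping, collecting equally
parsimonious trees, collapsing branches whose minimum possible length is
zero, and pooling/deduplicating across replicates.  Constrained
searches (enforcing or forbidding the monophyly of a clade) support
hypothesis tests and Bremer (decay) indices; character resampling gives
bootstrap supports.

Internally trees are manipulated as unrooted binary adjacency maps and
scored with a bitmask Fitch engine vectorized over characters.  A TBR
neighborhood is evaluated without rescoring whole trees: cutting an edge
splits the tree into two fragments whose lengths are rooting-invariant,
and the length after reconnecting at edges ``g`` and ``f`` is
``L_A + L_B + w·[R_A(g) ∩ R_B(f) = ∅]`` where ``R`` are the per-edge
Fitch root sets of each fragment.  Results are reported as rooted trees,
rooted on the designated outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from cladix.matrix import CharacterMatrix
from cladix.parsimony import branch_min_changes, fitch_length, n_states
from cladix.tree import Node, Tree, strict_consensus

__all__ = [
    "Constraint",
    "FitchEngine",
    "SearchConfig",
    "SearchResult",
    "bootstrap_supports",
    "bremer_supports",
    "collapse_min_zero",
    "constrained_search",
    "exhaustive_search",
    "heuristic_search",
    "random_addition_tree",
    "tbr_search",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class Constraint:
    """Monophyly constraint on a taxon subset (rooted on the outgroup)."""

    mode: Literal["enforce_monophyly", "forbid_monophyly"]
    clade: frozenset[str]

    def __post_init__(self) -> None:
        if self.mode not in ("enforce_monophyly", "forbid_monophyly"):
            raise ValueError(f"unknown constraint mode {self.mode!r}")
        if len(self.clade) < 2:
            raise ValueError("a constraint clade needs at least 2 taxa")


@dataclass(frozen=True)
class SearchConfig:
    """Search protocol parameters.

    ``n_replicates`` random-addition + TBR replicates are run; each saves
    at most ``max_trees_per_replicate`` equally parsimonious trees, and
    at most ``hold_overall`` distinct trees are kept after pooling.  The
    seed drives every tie-break and is mandatory for reproducibility.
    """

    n_replicates: int = 50
    max_trees_per_replicate: int = 500
    hold_overall: int = 500
    seed: int = 0
    collapse: bool = True
    constraints: tuple[Constraint, ...] = ()
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_replicates, self.max_trees_per_replicate,
               self.hold_overall) < 1:
            raise ValueError("replicate and tree counts must be >= 1")


#: Desk-scale preset: quick, suitable for matrices of a few dozen taxa.
DESK_PRESET = SearchConfig(n_replicates=50, max_trees_per_replicate=500,
                           hold_overall=500)
#: Full traditional-search protocol preset (10,000 replicates holding
#: 10,000 trees each) for published-scale analyses.
PAPER_PRESET = SearchConfig(n_replicates=10_000,
                            max_trees_per_replicate=10_000,
                            hold_overall=10_000)


@dataclass
class SearchResult:
    best_length: int
    mpts: list[Tree]
    replicate_lengths: list[int]
    seed: int

    def consensus(self) -> Tree:
        return strict_consensus(self.mpts)


# ---------------------------------------------------------------------------
# bitmask Fitch engine


class FitchEngine:
    """Per-taxon bitmask state sets, vectorized over characters.

    ``masks[i, c]`` has bit ``s`` set when state ``s`` is attainable for
    taxon ``i`` at character ``c`` (missing/inapplicable = all states).
    ``weights`` multiplies per-character step counts (used by the
    bootstrap to avoid materializing resampled matrices).
    """

    def __init__(self, matrix: CharacterMatrix,
                 weights: np.ndarray | None = None):
        S = n_states(matrix)
        full = (1 << S) - 1
        self.n_state = S
        self.taxa = list(matrix.taxon_names)
        self.index = {t: i for i, t in enumerate(self.taxa)}
        m = np.zeros((matrix.n_taxa, matrix.n_characters), dtype=np.uint16)
        for i, t in enumerate(self.taxa):
            for c, cell in enumerate(matrix.row(t)):
                if cell.is_observed:
                    bits = 0
                    for s in cell.states:
                        bits |= 1 << s
                    m[i, c] = bits
                else:
                    m[i, c] = full
        self.masks = m
        self.weights = (np.ones(matrix.n_characters, dtype=np.int64)
                        if weights is None else np.asarray(weights, np.int64))

    def with_weights(self, weights: np.ndarray) -> "FitchEngine":
        clone = object.__new__(FitchEngine)
        clone.n_state = self.n_state
        clone.taxa = self.taxa
        clone.index = self.index
        clone.masks = self.masks
        clone.weights = np.asarray(weights, np.int64)
        return clone


def _merge(a: np.ndarray, b: np.ndarray, weights: np.ndarray,
           counter: list[int] | None) -> np.ndarray:
    inter = a & b
    disjoint = inter == 0
    if counter is not None:
        counter[0] += int(weights[disjoint].sum())
    return np.where(disjoint, a | b, inter)


# ---------------------------------------------------------------------------
# unrooted binary trees as adjacency maps
#
# Leaves are taxon indices 0..n-1; internal nodes get ids >= n.  An
# unrooted binary tree over n >= 3 taxa has n-2 internal nodes of degree 3.


def _utree_copy(nbrs: dict[int, list[int]]) -> dict[int, list[int]]:
    return {u: list(vs) for u, vs in nbrs.items()}


def _utree_edges(nbrs: dict[int, list[int]]) -> list[tuple[int, int]]:
    return [(u, v) for u, vs in nbrs.items() for v in vs if u < v]


def _utree_splits(nbrs: dict[int, list[int]], n_taxa: int
                  ) -> frozenset[frozenset[int]]:
    """Canonical fingerprint: non-trivial splits, each as the side not
    containing taxon 0."""
    splits: set[frozenset[int]] = set()
    for u, v in _utree_edges(nbrs):
        side = _reachable(nbrs, v, u)
        leaves = frozenset(x for x in side if x < n_taxa)
        if 0 in leaves:
            leaves = frozenset(range(n_taxa)) - leaves
        if 1 < len(leaves) < n_taxa - 1:
            splits.add(leaves)
    return frozenset(splits)


def _reachable(nbrs: dict[int, list[int]], start: int, blocked: int
               ) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in nbrs[x]:
            if y != blocked and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def _utree_to_tree(nbrs: dict[int, list[int]], taxa: Sequence[str],
                   outgroup: str) -> Tree:
    """Root on the outgroup's pendant edge: outgroup becomes sister to
    the rest of the taxa."""
    og = list(taxa).index(outgroup)
    if len(nbrs) == 1:  # degenerate single-leaf "tree"
        return Tree(Node(taxa[og]))

    def build(x: int, parent: int) -> Node:
        if x < len(taxa):
            return Node(taxa[x])
        node = Node()
        for y in nbrs[x]:
            if y != parent:
                node.add_child(build(y, x))
        return node

    root = Node()
    root.add_child(Node(taxa[og]))
    root.add_child(build(nbrs[og][0], og))
    return Tree(root)


def _tree_to_utree(tree: Tree, taxa: Sequence[str]
                   ) -> tuple[dict[int, list[int]], int]:
    """Rooted binary tree → unrooted adjacency map (root suppressed)."""
    index = {t: i for i, t in enumerate(taxa)}
    nbrs: dict[int, list[int]] = {}
    next_id = [len(taxa)]

    def add_edge(a: int, b: int) -> None:
        nbrs.setdefault(a, []).append(b)
        nbrs.setdefault(b, []).append(a)

    def walk(node: Node) -> int:
        if node.is_leaf:
            nbrs.setdefault(index[node.label], [])
            return index[node.label]
        if len(node.children) != 2:
            raise ValueError("search trees must be binary")
        me = next_id[0]
        next_id[0] += 1
        nbrs.setdefault(me, [])
        for ch in node.children:
            add_edge(me, walk(ch))
        return me

    root = tree.root
    if len(root.children) != 2:
        raise ValueError("search trees must be binary")
    a = walk(root.children[0])
    b = walk(root.children[1])
    add_edge(a, b)
    return nbrs, next_id[0]


# ---------------------------------------------------------------------------
# fragment scoring


def _fragment_arrays(nbrs: dict[int, list[int]], nodes: set[int],
                     engine: FitchEngine, n_taxa: int
                     ) -> tuple[int, list[tuple[int, int] | None], np.ndarray]:
    """Length, edge list and per-edge Fitch root sets of a fragment.

    The fragment must be a binary unrooted tree induced on ``nodes`` (a
    single leaf is allowed).  Edge ``None`` stands for the pendant
    attachment point of a single-leaf fragment.
    """
    leaves = sorted(x for x in nodes if x < n_taxa)
    handle = leaves[0]
    if len(nodes) == 1:
        return 0, [None], engine.masks[handle][None, :].copy()
    masks = engine.masks
    weights = engine.weights
    counter = [0]
    # rooted orientation away from the handle leaf
    parent: dict[int, int] = {handle: -1}
    order: list[int] = []
    stack = [handle]
    while stack:
        x = stack.pop()
        order.append(x)
        for y in nbrs[x]:
            if y in nodes and y != parent[x]:
                parent[y] = x
                stack.append(y)
    down: dict[int, np.ndarray] = {}
    for x in reversed(order):
        if x < n_taxa:
            down[x] = masks[x]
        else:
            kids = [y for y in nbrs[x] if y in nodes and y != parent[x]]
            down[x] = _merge(down[kids[0]], down[kids[1]], weights, counter)
    top = [y for y in nbrs[handle] if y in nodes][0]
    up: dict[int, np.ndarray] = {top: masks[handle]}
    for x in order:
        if x < n_taxa:
            continue
        kids = [y for y in nbrs[x] if y in nodes and y != parent[x]]
        a, b = kids
        up[a] = _merge(up[x], down[b], weights, None)
        up[b] = _merge(up[x], down[a], weights, None)
    # the root-edge merge closes the length count (rooting-invariant)
    root_sets = _merge(down[top], up[top], weights, counter)
    edges: list[tuple[int, int] | None] = [(handle, top)]
    rsets = [root_sets]
    for x in order:
        if x == handle or parent[x] == handle:
            continue
        edges.append((parent[x], x))
        rsets.append(_merge(down[x], up[x], weights, None))
    return counter[0], edges, np.stack(rsets)


def _tree_length(nbrs: dict[int, list[int]], engine: FitchEngine,
                 n_taxa: int) -> int:
    L, _, _ = _fragment_arrays(nbrs, set(nbrs), engine, n_taxa)
    return L


def _pair_lengths(ra: np.ndarray, rb: np.ndarray, weights: np.ndarray
                  ) -> np.ndarray:
    """(len(ra), len(rb)) matrix of weighted disjoint-merge counts."""
    disjoint = (ra[:, None, :] & rb[None, :, :]) == 0
    return disjoint @ weights


# ---------------------------------------------------------------------------
# TBR moves


def _split_fragment(nbrs: dict[int, list[int]], keep: set[int],
                    cut_end: int) -> tuple[dict[int, list[int]], int | None]:
    """Adjacency of one side of a cut edge, suppressing the degree-2
    cut endpoint; returns (fragment nbrs, freed internal node id)."""
    frag = {x: [y for y in nbrs[x] if y in keep] for x in keep}
    freed: int | None = None
    if len(frag[cut_end]) == 2:  # internal endpoint became degree 2
        a, b = frag[cut_end]
        frag[a] = [b if y == cut_end else y for y in frag[a]]
        frag[b] = [a if y == cut_end else y for y in frag[b]]
        del frag[cut_end]
        freed = cut_end
    return frag, freed


def _reattach(frag: dict[int, list[int]], edge: tuple[int, int] | None,
              new_node: int | None) -> tuple[dict[int, list[int]], int]:
    """Insert ``new_node`` into ``edge`` (or use the lone leaf directly)
    and return (updated fragment, attachment point)."""
    if edge is None:
        (leaf,) = frag.keys()
        return frag, leaf
    assert new_node is not None
    x, y = edge
    frag[x] = [new_node if z == y else z for z in frag[x]]
    frag[y] = [new_node if z == x else z for z in frag[y]]
    frag[new_node] = [x, y]
    return frag, new_node


def _apply_tbr(nbrs: dict[int, list[int]], cut: tuple[int, int],
               g: tuple[int, int] | None, f: tuple[int, int] | None,
               n_taxa: int) -> dict[int, list[int]]:
    u, v = cut
    side_b = _reachable(nbrs, v, u)
    side_a = set(nbrs) - side_b
    frag_a, freed_a = _split_fragment(nbrs, side_a, u)
    frag_b, freed_b = _split_fragment(nbrs, side_b, v)
    free = [x for x in (freed_a, freed_b, u, v)
            if x is not None and x not in frag_a and x not in frag_b]
    free = list(dict.fromkeys(free))
    frag_a, pa = _reattach(frag_a, g, free.pop() if g is not None else None)
    frag_b, pb = _reattach(frag_b, f, free.pop() if f is not None else None)
    merged = {**frag_a, **frag_b}
    merged[pa] = merged[pa] + [pb]
    merged[pb] = merged[pb] + [pa]
    return merged


def _tbr_scan(nbrs: dict[int, list[int]], engine: FitchEngine, n_taxa: int,
              best_cap: int, checker: "_ConstraintChecker | None" = None
              ) -> tuple[int, list[tuple[tuple[int, int],
                                         tuple[int, int] | None,
                                         tuple[int, int] | None]]]:
    """Scan the full TBR neighborhood; return the best neighbor length
    and up to ``best_cap`` moves achieving it.

    With a constraint checker, the best *feasible* tier is returned:
    candidate moves are examined in order of increasing length and
    infeasible ones discarded.
    """
    weights = engine.weights
    per_edge: list = []
    best_possible = np.iinfo(np.int64).max
    for u, v in _utree_edges(nbrs):
        side_b = _reachable(nbrs, v, u)
        side_a = set(nbrs) - side_b
        frag_a, _ = _split_fragment(nbrs, side_a, u)
        frag_b, _ = _split_fragment(nbrs, side_b, v)
        la, ea, ra = _fragment_arrays(frag_a, set(frag_a), engine, n_taxa)
        lb, eb, rb = _fragment_arrays(frag_b, set(frag_b), engine, n_taxa)
        lengths = la + lb + _pair_lengths(ra, rb, weights)
        per_edge.append(((u, v), ea, eb, lengths))
        best_possible = min(best_possible, int(lengths.min()))
    if checker is None:
        moves: list = []
        for cut, ea, eb, lengths in per_edge:
            for i, j in zip(*np.nonzero(lengths == best_possible)):
                if len(moves) >= best_cap:
                    return best_possible, moves
                moves.append((cut, ea[i], eb[j]))
        return best_possible, moves
    # constraint-aware: walk candidate lengths in ascending order
    tiers = sorted({int(x) for _, _, _, lengths in per_edge
                    for x in np.unique(lengths)})
    for tier in tiers:
        moves = []
        for cut, ea, eb, lengths in per_edge:
            for i, j in zip(*np.nonzero(lengths == tier)):
                mv = (cut, ea[i], eb[j])
                if checker.ok(_apply_tbr(nbrs, *mv, n_taxa)):
                    moves.append(mv)
                    if len(moves) >= best_cap:
                        return tier, moves
        if moves:
            return tier, moves
    return np.iinfo(np.int64).max, []


# ---------------------------------------------------------------------------
# constraints


def _split_present(nbrs: dict[int, list[int]], part: set[int],
                   added: set[int], n_taxa: int) -> bool:
    """Is there an edge separating exactly ``part`` from the other added
    leaves?"""
    for u, v in _utree_edges(nbrs):
        side = {x for x in _reachable(nbrs, v, u) if x < n_taxa}
        if side == part or added - side == part:
            return True
    return False


class _ConstraintChecker:
    """Monophyly constraints, evaluated on complete or partial trees.

    Clades are rooted on the outgroup (which therefore may not belong to
    a constraint clade); on partially built trees an enforced clade is
    violated as soon as its added members are separated, while a
    forbidden clade is only assessed once every taxon is in the tree
    (later insertions inside the clade could still break it).
    """

    def __init__(self, constraints: Sequence[Constraint],
                 taxa: Sequence[str], outgroup: str):
        index = {t: i for i, t in enumerate(taxa)}
        self.n_taxa = len(taxa)
        self.og = index[outgroup]
        self.items: list[tuple[str, frozenset[int]]] = []
        for c in constraints:
            unknown = sorted(set(c.clade) - set(taxa))
            if unknown:
                raise ValueError(f"constraint names unknown taxa: {unknown}")
            if not 2 <= len(c.clade) < len(taxa):
                raise ValueError("constraint clade size out of range")
            if outgroup in c.clade:
                raise ValueError(
                    "constraint clades may not contain the outgroup "
                    f"{outgroup!r} (clades are rooted on it)")
            self.items.append((c.mode, frozenset(index[t] for t in c.clade)))

    def __bool__(self) -> bool:
        return bool(self.items)

    def ok(self, nbrs: dict[int, list[int]]) -> bool:
        added = {x for x in nbrs if x < self.n_taxa}
        complete = len(added) == self.n_taxa
        for mode, clade in self.items:
            inside = clade & added
            outside = added - clade
            if mode == "enforce_monophyly":
                if len(inside) >= 2 and outside and not _split_present(
                        nbrs, inside, added, self.n_taxa):
                    return False
            else:
                if complete and _split_present(nbrs, set(clade), added,
                                               self.n_taxa):
                    return False
        return True


# ---------------------------------------------------------------------------
# stepwise addition


def _random_addition(engine: FitchEngine, rng: np.random.Generator,
                     checker: _ConstraintChecker | None,
                     taxon_subset: Sequence[int] | None = None
                     ) -> dict[int, list[int]]:
    n_all = len(engine.taxa)
    taxa = list(taxon_subset) if taxon_subset is not None else list(range(n_all))
    if len(taxa) < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    a, b, c = order[:3]
    hub = 2 * n_all  # internal ids above any taxon id
    nbrs = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    next_id = hub + 1
    for t in order[3:]:
        _, edges, rsets = _fragment_arrays(nbrs, set(nbrs), engine, n_all)
        costs = _pair_lengths(rsets, engine.masks[t][None, :],
                              engine.weights)[:, 0]
        ranked = np.argsort(costs, kind="stable")
        chosen = None
        best_cost = None
        candidates: list[int] = []
        for k in ranked:
            if best_cost is None:
                best_cost = costs[k]
            if costs[k] > best_cost and candidates:
                break
            edge = edges[k]
            if checker:
                trial = _utree_copy(nbrs)
                x, y = edge
                trial[x] = [next_id if z == y else z for z in trial[x]]
                trial[y] = [next_id if z == x else z for z in trial[y]]
                trial[next_id] = [x, y, t]
                trial[t] = [next_id]
                if not checker.ok(trial):
                    continue
            candidates.append(int(k))
            if costs[k] > best_cost:
                break
        if checker and not candidates:
            # relax to any feasible edge regardless of cost
            for k in ranked:
                edge = edges[k]
                trial = _utree_copy(nbrs)
                x, y = edge
                trial[x] = [next_id if z == y else z for z in trial[x]]
                trial[y] = [next_id if z == x else z for z in trial[y]]
                trial[next_id] = [x, y, t]
                trial[t] = [next_id]
                if checker.ok(trial):
                    candidates.append(int(k))
                    break
            if not candidates:
                raise ValueError(
                    "constraints cannot be satisfied during stepwise addition")
        pick = candidates[int(rng.integers(len(candidates)))] \
            if len(candidates) > 1 else candidates[0]
        x, y = edges[pick]
        nbrs[x] = [next_id if z == y else z for z in nbrs[x]]
        nbrs[y] = [next_id if z == x else z for z in nbrs[y]]
        nbrs[next_id] = [x, y, t]
        nbrs[t] = [next_id]
        next_id += 1
    return nbrs


def random_addition_tree(matrix: CharacterMatrix, order_seed: int,
                         outgroup: str | None = None) -> Tree:
    """Binary starting tree by seeded random-order stepwise addition.

    Each taxon is inserted at a branch minimizing total length at that
    step; ties are broken uniformly at random under the seed.
    """
    engine = FitchEngine(matrix)
    rng = np.random.default_rng(order_seed)
    nbrs = _random_addition(engine, rng, None)
    og = outgroup or matrix.taxon_names[0]
    return _utree_to_tree(nbrs, engine.taxa, og)


# ---------------------------------------------------------------------------
# TBR hill-climbing


def _swap_to_completion(start_nbrs: dict[int, list[int]],
                        engine: FitchEngine, n_taxa: int,
                        config: SearchConfig, rng: np.random.Generator,
                        checker: _ConstraintChecker | None
                        ) -> tuple[int, dict[frozenset, dict[int, list[int]]]]:
    """Hill-climb through TBR neighborhoods, swapping every saved tree."""
    cap = config.max_trees_per_replicate
    best_len = _tree_length(start_nbrs, engine, n_taxa)
    pool: dict[frozenset, dict[int, list[int]]] = {
        _utree_splits(start_nbrs, n_taxa): start_nbrs}
    queue = list(pool)
    while queue:
        key = queue.pop()
        if key not in pool:
            continue
        nbrs = pool[key]
        improved = True
        while improved:
            improved = False
            m, moves = _tbr_scan(nbrs, engine, n_taxa, best_cap=4 * cap,
                                 checker=checker)
            if not moves:
                break
            if m < best_len:
                order = rng.permutation(len(moves))
                nbrs = _apply_tbr(nbrs, *moves[int(order[0])], n_taxa)
                best_len = m
                pool = {_utree_splits(nbrs, n_taxa): nbrs}
                queue = []
                improved = True
            elif m == best_len:
                for mv in moves:
                    if len(pool) >= cap:
                        break
                    t2 = _apply_tbr(nbrs, *mv, n_taxa)
                    k2 = _utree_splits(t2, n_taxa)
                    if k2 not in pool:
                        pool[k2] = t2
                        queue.append(k2)
        key_now = _utree_splits(nbrs, n_taxa)
        if key_now not in pool and len(pool) < cap:
            pool[key_now] = nbrs
    return best_len, pool


def tbr_search(start: Tree, matrix: CharacterMatrix,
               config: SearchConfig | None = None) -> SearchResult:
    """TBR hill-climbing from a binary starting tree."""
    config = config or SearchConfig()
    engine = FitchEngine(matrix)
    og = config.outgroup or matrix.taxon_names[0]
    checker = _ConstraintChecker(config.constraints, engine.taxa, og) \
        if config.constraints else None
    nbrs, _ = _tree_to_utree(start, engine.taxa)
    rng = np.random.default_rng(config.seed)
    best_len, pool = _swap_to_completion(nbrs, engine, len(engine.taxa),
                                         config, rng, checker)
    trees = _finalize(pool.values(), best_len, engine, matrix, config, og)
    return SearchResult(best_length=best_len, mpts=trees,
                        replicate_lengths=[best_len], seed=config.seed)


def _finalize(forest: Iterable[dict[int, list[int]]], best_len: int,
              engine: FitchEngine, matrix: CharacterMatrix,
              config: SearchConfig, og: str) -> list[Tree]:
    """Root, optionally collapse, and deduplicate the pooled trees."""
    seen: dict[frozenset, Tree] = {}
    for nbrs in forest:
        t = _utree_to_tree(nbrs, engine.taxa, og)
        if config.collapse:
            t = collapse_min_zero(t, matrix)
        key = frozenset(t.clades())
        if key not in seen:
            seen[key] = t
        if len(seen) >= config.hold_overall:
            break
    return list(seen.values())


# ---------------------------------------------------------------------------
# collapsing


def collapse_min_zero(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Contract internal branches whose minimum possible length is zero.

    A branch's minimum length is the number of characters for which no
    most-parsimonious reconstruction leaves it change-free.  Contracting
    one such branch never changes tree length (each character keeps an
    optimal reconstruction with the branch change-free), but contracting
    several at once can, because different branches may need different
    reconstructions.  All min-zero branches are therefore contracted as
    a batch only when the batch provably preserves length; otherwise
    they are contracted one at a time in postorder, re-testing after
    each contraction.
    """
    base_len = fitch_length(tree, matrix).total_length

    def contract(t: Tree, node_ids: set[int]) -> Tree:
        for node in list(t.postorder()):
            if id(node) in node_ids and node.parent is not None \
                    and not node.is_leaf:
                parent = node.parent
                i = parent.children.index(node)
                parent.children[i:i + 1] = node.children
                for ch in node.children:
                    ch.parent = parent
        return t

    def copy_with_ids(t: Tree, ids: set[int]) -> tuple[Tree, set[int]]:
        clone = t.copy()
        mapped = {id(b) for a, b in zip(t.postorder(), clone.postorder())
                  if id(a) in ids}
        return clone, mapped

    out = tree.copy()
    while True:
        mins = branch_min_changes(out, matrix)
        zero = {id(n) for n in out.postorder()
                if not n.is_leaf and n.parent is not None
                and mins[id(n)] == 0}
        if not zero:
            return out
        clone, mapped = copy_with_ids(out, zero)
        batch = contract(clone, mapped)
        if fitch_length(batch, matrix).total_length == base_len:
            return batch
        # conservative path: one branch at a time, then re-test
        first = next(id(n) for n in out.postorder() if id(n) in zero)
        out = contract(out, {first})


# ---------------------------------------------------------------------------
# top-level searches


def heuristic_search(matrix: CharacterMatrix,
                     config: SearchConfig | None = None) -> SearchResult:
    """Replicated random addition + TBR; pool, collapse, deduplicate."""
    config = config or SearchConfig()
    engine = FitchEngine(matrix)
    n_taxa = len(engine.taxa)
    og = config.outgroup or matrix.taxon_names[0]
    checker = _ConstraintChecker(config.constraints, engine.taxa, og) \
        if config.constraints else None
    rng = np.random.default_rng(config.seed)
    overall_best: int | None = None
    forest: dict[frozenset, dict[int, list[int]]] = {}
    replicate_lengths: list[int] = []
    for _ in range(config.n_replicates):
        rep_rng = np.random.default_rng(rng.integers(2**31))
        start = _random_addition(engine, rep_rng, checker)
        best_len, pool = _swap_to_completion(start, engine, n_taxa,
                                             config, rep_rng, checker)
        replicate_lengths.append(best_len)
        if overall_best is None or best_len < overall_best:
            overall_best = best_len
            forest = {}
        if best_len == overall_best:
            for k, v in pool.items():
                if len(forest) < config.hold_overall and k not in forest:
                    forest[k] = v
    assert overall_best is not None
    trees = _finalize(forest.values(), overall_best, engine, matrix,
                      config, og)
    return SearchResult(best_length=overall_best, mpts=trees,
                        replicate_lengths=replicate_lengths,
                        seed=config.seed)


def constrained_search(matrix: CharacterMatrix,
                       config: SearchConfig) -> SearchResult:
    """Heuristic search restricted to constraint-satisfying trees."""
    if not config.constraints:
        raise ValueError("constrained_search requires at least one constraint")
    return heuristic_search(matrix, config)


def exhaustive_search(matrix: CharacterMatrix,
                      outgroup: str | None = None,
                      constraints: Sequence[Constraint] = ()
                      ) -> SearchResult:
    """Enumerate every unrooted binary topology (feasible for n ≤ ~9)."""
    engine = FitchEngine(matrix)
    n = len(engine.taxa)
    og = outgroup or matrix.taxon_names[0]
    checker = _ConstraintChecker(constraints, engine.taxa, og) \
        if constraints else None
    best: int | None = None
    pool: list[dict[int, list[int]]] = []
    for nbrs in _all_topologies(n):
        if checker and not checker.ok(nbrs):
            continue
        L = _tree_length(nbrs, engine, n)
        if best is None or L < best:
            best, pool = L, [nbrs]
        elif L == best:
            pool.append(nbrs)
    if best is None:
        raise ValueError("constraints admit no topology")
    cfg = SearchConfig(collapse=True, outgroup=og)
    trees = _finalize(pool, best, engine, matrix, cfg, og)
    return SearchResult(best_length=best, mpts=trees,
                        replicate_lengths=[best], seed=0)


def _all_topologies(n: int):
    """Yield all unrooted binary topologies on taxa 0..n-1 by recursive
    edge insertion ((2n-5)!! trees)."""
    base = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}

    def expand(nbrs: dict[int, list[int]], t: int, next_id: int):
        if t == n:
            yield nbrs
            return
        for x, y in _utree_edges(nbrs):
            new = _utree_copy(nbrs)
            new[x] = [next_id if z == y else z for z in new[x]]
            new[y] = [next_id if z == x else z for z in new[y]]
            new[next_id] = [x, y, t]
            new[t] = [next_id]
            yield from expand(new, t + 1, next_id + 1)

    if n < 3:
        raise ValueError("need at least 3 taxa")
    yield from expand(base, 3, n + 1)


# ---------------------------------------------------------------------------
# supports


def bremer_supports(matrix: CharacterMatrix, result: SearchResult,
                    config: SearchConfig | None = None
                    ) -> dict[frozenset[str], int]:
    """Decay index per strict-consensus clade: extra steps of the best
    tree in which the clade is not monophyletic.

    Clades containing all taxa but one are skipped: rooted on the
    outgroup they are present in every tree, so no reverse-constraint
    search can break them.
    """
    config = config or SearchConfig()
    consensus = result.consensus()
    n = len(consensus.leaf_names())
    out: dict[frozenset[str], int] = {}
    for clade in sorted(consensus.clades(), key=lambda c: (len(c), sorted(c))):
        if len(clade) >= n - 1:
            continue
        anti = Constraint("forbid_monophyly", clade)
        cfg = replace(config, constraints=(anti,))
        res = heuristic_search(matrix, cfg)
        out[clade] = res.best_length - result.best_length
    return out


def bootstrap_supports(matrix: CharacterMatrix,
                       config: SearchConfig | None = None,
                       n_pseudoreplicates: int = 100,
                       inner_replicates: int = 5
                       ) -> dict[frozenset[str], float]:
    """Clade frequencies over character-resampled pseudoreplicates.

    Characters are resampled with replacement to the original count; each
    pseudoreplicate runs a reduced heuristic search and contributes the
    clades of its strict consensus.
    """
    config = config or SearchConfig()
    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_pseudoreplicates):
        idx = rng.integers(matrix.n_characters, size=matrix.n_characters)
        weights = np.bincount(idx, minlength=matrix.n_characters)
        cfg = replace(config, n_replicates=inner_replicates,
                      seed=int(rng.integers(2**31)))
        res = _weighted_search(matrix, weights, cfg)
        for clade in res.consensus().clades():
            counts[clade] = counts.get(clade, 0) + 1
    return {c: k / n_pseudoreplicates for c, k in counts.items()}


def _weighted_search(matrix: CharacterMatrix, weights: np.ndarray,
                     config: SearchConfig) -> SearchResult:
    """Heuristic search under per-character weights (bootstrap internals).

    Collapsing is skipped: consensus clades of the saved binary trees are
    what the bootstrap tallies.
    """
    engine = FitchEngine(matrix).with_weights(weights)
    n_taxa = len(engine.taxa)
    og = config.outgroup or matrix.taxon_names[0]
    rng = np.random.default_rng(config.seed)
    overall_best: int | None = None
    forest: dict[frozenset, dict[int, list[int]]] = {}
    for _ in range(config.n_replicates):
        rep_rng = np.random.default_rng(rng.integers(2**31))
        start = _random_addition(engine, rep_rng, None)
        best_len, pool = _swap_to_completion(start, engine, n_taxa,
                                             config, rep_rng, None)
        if overall_best is None or best_len < overall_best:
            overall_best, forest = best_len, {}
        if best_len == overall_best:
            for k, v in pool.items():
                if len(forest) < config.hold_overall and k not in forest:
                    forest[k] = v
    trees = [_utree_to_tree(nbrs, engine.taxa, og)
             for nbrs in forest.values()]
    return SearchResult(best_length=int(overall_best), mpts=trees,
                        replicate_lengths=[], seed=config.seed)
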