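"""Ghost lineages, time calibration and stratigraphic congruence.

A tree is calibrated against first-appearance ages by minimum-age
dating: each leaf sits at its first-appearance age (Ma) and each
internal node at the maximum of its children's ages.  The ghost lineage
on a branch is the implied gap ``parent_age − child_age`` (myr); the
minimum implied gap (MIG) is the sum of ghosts over all branches.

For a fixed set of leaf ages, the best and worst achievable MIG over all
rooted binary topologies have closed forms, both realized by pectinate
(comb) trees:

* ``g_min = a_max − a_min`` — join taxa oldest-first, so the only gaps
  lie on the spine and telescope to the total age range;
* ``g_max = Σ_i (a_max − a_i)`` — join taxa youngest-first, so every
  internal node is an ancestor of the oldest taxon and is dragged up to
  its age.

These constructions are certified against exhaustive topology
enumeration in the test suite.  GER scales a tree's MIG between the two
(1 = best), and MSM* is ``g_min / MIG``.  Polytomies and age intervals
are handled by reporting the full range of each metric over binary
resolutions and age-endpoint choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np

from cladix.matrix import AgeTable
from cladix.tree import Node, Tree

__all__ = [
    "CalibratedTree",
    "StratMetrics",
    "binary_resolutions",
    "calibrate",
    "count_resolutions",
    "g_bounds",
    "ger",
    "metrics_under_uncertainty",
    "mig",
    "msm_star",
]


def _as_age_lookup(ages: AgeTable | Mapping[str, float],
                   which: Literal["oldest", "youngest"]) -> "dict[str, float]":
    if isinstance(ages, AgeTable):
        return {t: ages.point(t, which) for t in ages.taxa()}
    return dict(ages)


@dataclass
class CalibratedTree:
    """A tree with minimum-age node dates and per-branch ghost durations.

    ``node_age`` and ``ghost`` are keyed by ``id(node)`` on ``tree``;
    ghosts belong to the branch above each non-root node.  Ages are also
    mirrored into node annotations (``age``, ``ghost``).
    """

    tree: Tree
    node_age: dict[int, float]
    ghost: dict[int, float]

    def leaf_ages(self) -> list[float]:
        return [self.node_age[id(lf)] for lf in self.tree.leaves()]

    def mig(self) -> float:
        return sum(self.ghost.values())

    def ghost_of_clade(self, clade: frozenset[str]) -> float:
        """Ghost duration on the stem branch subtending a clade."""
        below = self.tree.clade_map()
        for node in self.tree.postorder():
            if node.parent is not None and below[id(node)] == clade:
                return self.ghost[id(node)]
        raise KeyError(f"no branch subtends clade {sorted(clade)}")


def calibrate(tree: Tree, ages: AgeTable | Mapping[str, float],
              which: Literal["oldest", "youngest"] = "oldest"
              ) -> CalibratedTree:
    """Minimum-age calibration: leaf age = chosen first-appearance
    endpoint; internal age = max over children's ages."""
    lookup = _as_age_lookup(ages, which)
    out = tree.copy()
    missing = sorted(lf.label for lf in out.leaves() if lf.label not in lookup)
    if missing:
        raise ValueError(f"taxa without ages: {missing}")
    node_age: dict[int, float] = {}
    for node in out.postorder():
        if node.is_leaf:
            node_age[id(node)] = float(lookup[node.label])
        else:
            node_age[id(node)] = max(node_age[id(c)] for c in node.children)
        node.annotations["age"] = node_age[id(node)]
    ghost: dict[int, float] = {}
    for node in out.postorder():
        if node.parent is not None:
            g = node_age[id(node.parent)] - node_age[id(node)]
            ghost[id(node)] = g
            node.annotations["ghost"] = g
    return CalibratedTree(tree=out, node_age=node_age, ghost=ghost)


def mig(ct: CalibratedTree) -> float:
    """Minimum implied gap: total ghost-lineage duration (myr)."""
    return ct.mig()


def g_bounds(leaf_ages: Iterable[float]) -> tuple[float, float]:
    """(g_min, g_max): extreme MIG over all rooted binary topologies."""
    a = sorted(leaf_ages)
    if len(a) < 3:
        raise ValueError("g_bounds needs at least 3 leaf ages")
    top = a[-1]
    return top - a[0], float(sum(top - x for x in a))


def ger(ct: CalibratedTree) -> float | None:
    """Gap excess ratio (g_max − MIG)/(g_max − g_min); ``None`` when all
    topologies imply the same gap (degenerate denominator)."""
    g_min, g_max = g_bounds(ct.leaf_ages())
    if g_max == g_min:
        return None
    return (g_max - ct.mig()) / (g_max - g_min)


def msm_star(ct: CalibratedTree) -> float | None:
    """Modified Manhattan stratigraphic measure g_min/MIG; ``None`` when
    MIG is zero (perfect congruence with zero range is undefined)."""
    g_min, _ = g_bounds(ct.leaf_ages())
    m = ct.mig()
    if m == 0:
        return None
    return g_min / m


# ---------------------------------------------------------------------------
# polytomy resolutions


def _rooted_shapes(items: Sequence) -> Iterator:
    """All rooted binary tree shapes (nested pairs) over the items."""
    if len(items) == 1:
        yield items[0]
        return
    rest = list(_rooted_shapes(items[:-1]))
    x = items[-1]

    def insert_everywhere(shape):
        yield (shape, x)
        if isinstance(shape, tuple):
            a, b = shape
            for s in insert_everywhere(a):
                yield (s, b)
            for s in insert_everywhere(b):
                yield (a, s)

    for shape in rest:
        yield from insert_everywhere(shape)


def _double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def count_resolutions(tree: Tree) -> int:
    """Number of distinct binary resolutions of all polytomies."""
    total = 1
    for node in tree.postorder():
        k = len(node.children)
        if k > 2:
            total *= _double_factorial(2 * k - 3)
    return total


def _copy_node(node: Node) -> Node:
    c = Node(node.label, node.length)
    for ch in node.children:
        c.add_child(_copy_node(ch))
    return c


def _pairing_from_shape(shape, subtrees: Sequence[Node]) -> Node:
    """Turn a nested-pair shape over indices into anonymous cherry nodes."""
    if not isinstance(shape, tuple):
        return _copy_node(subtrees[shape])
    node = Node()
    node.add_child(_pairing_from_shape(shape[0], subtrees))
    node.add_child(_pairing_from_shape(shape[1], subtrees))
    return node


def binary_resolutions(tree: Tree, limit: int | None = None,
                       rng: np.random.Generator | None = None
                       ) -> Iterator[Tree]:
    """Yield binary resolutions of every polytomy.

    Exhaustive in deterministic order when ``rng`` is None; with an rng,
    yields ``limit`` trees with every polytomy resolved by random
    successive pairing (a seeded sampling convention, flagged as sampled
    upstream).
    """
    import itertools

    def resolve_rand(node: Node) -> Node:
        if node.is_leaf:
            return Node(node.label, node.length)
        kids = [resolve_rand(ch) for ch in node.children]
        while len(kids) > 2:
            i, j = sorted(rng.choice(len(kids), size=2, replace=False))
            pair = Node()
            pair.add_child(kids[i])
            pair.add_child(kids[j])
            kids = [k for t, k in enumerate(kids) if t not in (i, j)]
            kids.append(pair)
        out = Node(node.label, node.length)
        for k in kids:
            out.add_child(k)
        return out

    if rng is not None:
        for _ in range(limit or 1):
            yield Tree(resolve_rand(tree.root))
        return

    def expand(node: Node) -> Iterator[Node]:
        if node.is_leaf:
            yield node
            return
        options = [list(expand(c)) for c in node.children]
        for combo in itertools.product(*options):
            if len(combo) <= 2:
                n = Node(node.label, node.length)
                for c in combo:
                    n.add_child(_copy_node(c))
                yield n
            else:
                for shape in _rooted_shapes(list(range(len(combo)))):
                    n = Node(node.label, node.length)
                    top = _pairing_from_shape(shape, combo)
                    for ch in top.children:
                        n.add_child(ch)
                    yield n

    count = 0
    for root in expand(tree.root):
        yield Tree(_copy_node(root))
        count += 1
        if limit is not None and count >= limit:
            return


# ---------------------------------------------------------------------------
# metrics under uncertainty


@dataclass
class StratMetrics:
    """Interval-valued congruence metrics; lo == hi for point inputs.

    ``None`` endpoints mark metrics undefined over the whole sweep.
    ``sampled`` flags bounds obtained from sampled (not exhaustive)
    polytomy resolutions, with ``n_evaluated`` combinations inspected.
    """

    mig: tuple[float, float]
    g_min: tuple[float, float]
    g_max: tuple[float, float]
    ger: tuple[float | None, float | None]
    msm_star: tuple[float | None, float | None]
    sampled: bool = False
    n_evaluated: int = 0

    def as_dict(self) -> dict:
        return {
            "mig": list(self.mig), "g_min": list(self.g_min),
            "g_max": list(self.g_max), "ger": list(self.ger),
            "msm_star": list(self.msm_star),
            "sampled": self.sampled, "n_evaluated": self.n_evaluated,
        }


def _age_assignments(ages: AgeTable, taxa: Sequence[str],
                     max_exhaustive: int, rng: np.random.Generator,
                     n_search: int) -> list[dict[str, float]]:
    """Endpoint assignments to sweep: exhaustive 2^k when the number of
    uncertain taxa is small, else a seeded endpoint sample."""
    uncertain = [t for t in taxa if ages.oldest(t) != ages.youngest(t)]
    base = {t: ages.oldest(t) for t in taxa}
    if not uncertain:
        return [base]
    if len(uncertain) <= max_exhaustive:
        out = []
        for bits in range(1 << len(uncertain)):
            a = dict(base)
            for i, t in enumerate(uncertain):
                a[t] = ages.youngest(t) if bits >> i & 1 else ages.oldest(t)
            out.append(a)
        return out
    # seeded coordinate search: random endpoint corners plus both extremes
    out = [dict(base),
           {t: ages.youngest(t) if t in uncertain else base[t] for t in taxa}]
    for _ in range(n_search):
        a = dict(base)
        for t in uncertain:
            if rng.integers(2):
                a[t] = ages.youngest(t)
        out.append(a)
    return out


def metrics_under_uncertainty(tree: Tree, ages: AgeTable,
                              max_resolutions: int = 10_000,
                              max_uncertain_exhaustive: int = 12,
                              n_samples: int = 200,
                              seed: int = 0) -> StratMetrics:
    """Range of MIG/GER/MSM* over binary polytomy resolutions × age
    endpoints.

    Resolutions are enumerated exhaustively when their count is at most
    ``max_resolutions``, otherwise ``n_samples`` seeded random
    resolutions are used and the result is flagged ``sampled``.
    """
    rng = np.random.default_rng(seed)
    taxa = sorted(tree.leaf_names())
    ages.validate_against(taxa)
    n_res = count_resolutions(tree)
    if n_res <= max_resolutions:
        resolutions = list(binary_resolutions(tree))
        sampled = False
    else:
        resolutions = list(binary_resolutions(tree, limit=n_samples, rng=rng))
        sampled = True
    assignments = _age_assignments(ages, taxa, max_uncertain_exhaustive,
                                   rng, n_samples)

    lo = {k: math.inf for k in ("mig", "g_min", "g_max")}
    hi = {k: -math.inf for k in ("mig", "g_min", "g_max")}
    ger_vals: list[float] = []
    msm_vals: list[float] = []
    n_eval = 0
    for assign in assignments:
        gmn, gmx = g_bounds([assign[t] for t in taxa])
        lo["g_min"] = min(lo["g_min"], gmn)
        hi["g_min"] = max(hi["g_min"], gmn)
        lo["g_max"] = min(lo["g_max"], gmx)
        hi["g_max"] = max(hi["g_max"], gmx)
        for res in resolutions:
            ct = calibrate(res, assign)
            m = ct.mig()
            lo["mig"] = min(lo["mig"], m)
            hi["mig"] = max(hi["mig"], m)
            if gmx > gmn:
                ger_vals.append((gmx - m) / (gmx - gmn))
            if m > 0:
                msm_vals.append(gmn / m)
            n_eval += 1

    def _interval(vals: list[float]) -> tuple[float | None, float | None]:
        if not vals:
            return (None, None)
        return (min(vals), max(vals))

    return StratMetrics(
        mig=(lo["mig"], hi["mig"]),
        g_min=(lo["g_min"], hi["g_min"]),
        g_max=(lo["g_max"], hi["g_max"]),
        ger=_interval(ger_vals),
        msm_star=_interval(msm_vals),
        sampled=sampled,
        n_evaluated=n_eval,
    )
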