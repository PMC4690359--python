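"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reusing the package's
algorithms: parsimony by explicit enumeration of ancestral assignments,
topology spaces by direct recursive construction, likelihoods by
summation over every ancestral state combination.  Slow but obviously
correct at small n.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterator, Sequence

# Trees are nested tuples: a leaf is a string label, an internal node is a
# tuple of subtrees (possibly more than two: polytomies).


def postorder(shape) -> Iterator:
    if isinstance(shape, tuple):
        for child in shape:
            yield from postorder(child)
    yield shape


def leaves_of(shape) -> list[str]:
    return [x for x in postorder(shape) if not isinstance(x, tuple)]


def shape_to_newick(shape) -> str:
    def fmt(s):
        if isinstance(s, tuple):
            return "(" + ",".join(fmt(c) for c in s) + ")"
        return s
    return fmt(shape) + ";"


def all_rooted_binary_shapes(labels: Sequence[str]) -> Iterator:
    """All rooted binary tree shapes over the labels ((2n-3)!! of them)."""
    if len(labels) == 1:
        yield labels[0]
        return
    first = labels[0]

    def insert(shape, leaf):
        yield (shape, leaf)
        if isinstance(shape, tuple):
            a, b = shape
            for s in insert(a, leaf):
                yield (s, b)
            for s in insert(b, leaf):
                yield (a, s)

    for smaller in all_rooted_binary_shapes(labels[:-1]):
        if len(labels) == 2:
            yield (smaller, labels[-1])
        else:
            yield from insert(smaller, labels[-1])


def all_unrooted_shapes(labels: Sequence[str]) -> Iterator:
    """Each unrooted topology once, as a rooted shape with the first
    label split off at the root: ((rest...), first)."""
    first, rest = labels[0], list(labels[1:])
    for shape in all_rooted_binary_shapes(rest):
        yield (shape, first)


# ---------------------------------------------------------------------------
# parsimony by enumeration


def sankoff_length(shape, states: dict[str, set[int] | None],
                   universe: Sequence[int]) -> int:
    """Minimum unordered changes over all ancestral assignments.

    ``states[leaf]`` is a set of attainable states (None = any state).
    Enumerates every assignment of universe states to internal nodes.
    """
    internals = [s for s in postorder(shape) if isinstance(s, tuple)]
    ids = {id(s): i for i, s in enumerate(internals)}
    best = math.inf
    for combo in itertools.product(universe, repeat=len(internals)):
        def node_states(s):
            if isinstance(s, tuple):
                return {combo[ids[id(s)]]}
            obs = states[s]
            return set(universe) if obs is None else obs

        cost = 0
        for s in internals:
            ps = combo[ids[id(s)]]
            for child in s:
                cs = node_states(child)
                if ps not in cs:
                    cost += 1
        if cost < best:
            best = cost
    return int(best)


def mpr_sets(shape, states: dict[str, set[int] | None],
             universe: Sequence[int]) -> dict[int, set[int]]:
    """States attainable at each internal node in at least one optimal
    assignment; keyed by the node's index in postorder over internals."""
    internals = [s for s in postorder(shape) if isinstance(s, tuple)]
    ids = {id(s): i for i, s in enumerate(internals)}
    best = math.inf
    sets: dict[int, set[int]] = {i: set() for i in range(len(internals))}
    for combo in itertools.product(universe, repeat=len(internals)):
        cost = 0
        for s in internals:
            ps = combo[ids[id(s)]]
            for child in s:
                if isinstance(child, tuple):
                    cs = {combo[ids[id(child)]]}
                else:
                    obs = states[child]
                    cs = set(universe) if obs is None else obs
                if ps not in cs:
                    cost += 1
        if cost < best:
            best = cost
            sets = {i: set() for i in range(len(internals))}
        if cost == best:
            for i in range(len(internals)):
                sets[i].add(combo[i])
    return sets


def optimal_assignments(shape, states, universe):
    """All minimum-cost internal assignments (list of tuples) plus the
    postorder-internal index map."""
    internals = [s for s in postorder(shape) if isinstance(s, tuple)]
    ids = {id(s): i for i, s in enumerate(internals)}
    best = math.inf
    combos = []
    for combo in itertools.product(universe, repeat=len(internals)):
        cost = 0
        for s in internals:
            ps = combo[ids[id(s)]]
            for child in s:
                if isinstance(child, tuple):
                    cs = {combo[ids[id(child)]]}
                else:
                    obs = states[child]
                    cs = set(universe) if obs is None else obs
                if ps not in cs:
                    cost += 1
        if cost < best:
            best, combos = cost, []
        if cost == best:
            combos.append(combo)
    return best, combos, ids


# ---------------------------------------------------------------------------
# stratigraphy by enumeration


def mig_of_shape(shape, ages: dict[str, float]) -> float:
    """Sum over branches of parent_age - child_age under minimum-age
    calibration, computed directly from the nested-tuple shape."""

    def age(s) -> float:
        if isinstance(s, tuple):
            return max(age(c) for c in s)
        return ages[s]

    total = 0.0
    for s in postorder(shape):
        if isinstance(s, tuple):
            a = age(s)
            for c in s:
                total += a - age(c)
    return total


def brute_g_bounds(ages: dict[str, float]) -> tuple[float, float]:
    labels = sorted(ages)
    migs = [mig_of_shape(s, ages) for s in all_rooted_binary_shapes(labels)]
    return min(migs), max(migs)


# ---------------------------------------------------------------------------
# Mk likelihood by enumeration


def mk_transition(k: int, alpha: float, t: float, i: int, j: int) -> float:
    e = math.exp(-k * alpha * t)
    if i == j:
        return 1.0 / k + (k - 1) / k * e
    return 1.0 / k - 1.0 / k * e


def brute_mk_likelihood(shape, lengths: dict[int, float],
                        leaf_states: dict[str, int], k: int,
                        alpha: float, prior: Sequence[float],
                        fixed: dict[int, int] | None = None) -> float:
    """Likelihood by summing over all internal-node state assignments.

    ``lengths`` maps id(subshape) -> branch length above it; ``fixed``
    optionally pins internal nodes (by postorder-internal index) to a
    state, for marginal checks.
    """
    internals = [s for s in postorder(shape) if isinstance(s, tuple)]
    ids = {id(s): i for i, s in enumerate(internals)}
    fixed = fixed or {}
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internals)):
        if any(combo[i] != v for i, v in fixed.items()):
            continue
        like = prior[combo[ids[id(shape)]]]
        for s in internals:
            ps = combo[ids[id(s)]]
            for child in s:
                cs = (combo[ids[id(child)]] if isinstance(child, tuple)
                      else leaf_states[child])
                like *= mk_transition(k, alpha, lengths[id(child)], ps, cs)
        total += like
    return total
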