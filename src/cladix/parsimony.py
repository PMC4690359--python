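"""Parsimony scoring, ensemble indices and MPR machinery.

All characters are unordered (non-additive): the cost of any state
change is 1.  Lengths are computed by uniform-cost dynamic programming
(Fitch generalized to polytomies, i.e. unit-cost Sankoff), which is
exact on multifurcating trees.  Missing and inapplicable cells behave as
"any state" and never add steps; polymorphic cells are satisfiable by
any member state at no cost.

Most-parsimonious-reconstruction (MPR) state sets are obtained from
inside (subtree) and outside (rest-of-tree) cost vectors: a state
belongs to a node's final set exactly when fixing the node to that state
still achieves the minimum total length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cladix.matrix import CharacterMatrix, StateSet
from cladix.tree import Tree

__all__ = [
    "CharacterChange",
    "MPRAnnotation",
    "ParsimonyScore",
    "char_bounds",
    "fitch_length",
    "mpr_state_sets",
    "unambiguous_changes",
]

_INF = np.int32(1 << 20)


# ---------------------------------------------------------------------------
# encoding helpers


def n_states(matrix: CharacterMatrix) -> int:
    """Size of the working state space (max observed code + 1, at least 2)."""
    top = 1
    for c in range(matrix.n_characters):
        for s in matrix.state_universe(c):
            top = max(top, s)
    return top + 1


def leaf_cost_vector(cell: StateSet, n_state: int) -> np.ndarray:
    """Unit-cost leaf vector: 0 on attainable states, +inf elsewhere."""
    v = np.full(n_state, _INF, dtype=np.int32)
    if cell.is_observed:
        v[list(cell.states)] = 0
    else:  # missing / inapplicable: any state at no cost
        v[:] = 0
    return v


def _leaf_costs(matrix: CharacterMatrix, taxon: str, S: int) -> np.ndarray:
    """(S, n_chars) leaf cost matrix for one taxon."""
    return np.stack(
        [leaf_cost_vector(c, S) for c in matrix.row(taxon)], axis=1)


def _child_contribution(cost: np.ndarray) -> np.ndarray:
    """min_t(cost[t] + [t != s]) for every parent state s, vectorized."""
    best = cost.min(axis=0)
    return np.minimum(cost, best[None, :] + 1)


def _down_costs(tree: Tree, matrix: CharacterMatrix
                ) -> tuple[dict[int, np.ndarray], int]:
    """Subtree (inside) cost vectors D[id(node)][s, char]."""
    missing = [lf.label for lf in tree.leaves()
               if lf.label not in matrix.taxon_names]
    if missing:
        raise ValueError(f"tree leaves absent from matrix: {sorted(missing)}")
    S = n_states(matrix)
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = _leaf_costs(matrix, node.label, S)
        else:
            acc = np.zeros_like(down[id(node.children[0])])
            for ch in node.children:
                acc = acc + _child_contribution(down[id(ch)])
            down[id(node)] = acc
    return down, S


def _up_costs(tree: Tree, down: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    """Outside cost vectors A[id(node)][s, char]: minimum cost of the tree
    outside the node's subtree given the node takes state ``s``, including
    the change cost on the node's parent branch."""
    root = tree.root
    up: dict[int, np.ndarray] = {id(root): np.zeros_like(down[id(root)])}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        contribs = {id(c): _child_contribution(down[id(c)])
                    for c in node.children}
        total = up[id(node)]
        for c in contribs.values():
            total = total + c
        for ch in node.children:
            b = total - contribs[id(ch)]  # cost with node = s_p, child removed
            up[id(ch)] = np.minimum(b, b.min(axis=0)[None, :] + 1)
    return up


# ---------------------------------------------------------------------------
# scores and bounds


@dataclass
class ParsimonyScore:
    """Tree length, per-character lengths/bounds and ensemble indices.

    ``ci``/``ri``/``rci`` use all characters; the ``*_informative``
    variants drop characters whose length cannot vary across topologies
    (``min_steps == max_steps``), matching the alternative convention
    some programs report.
    """

    total_length: int
    per_character_length: np.ndarray
    min_steps: np.ndarray
    max_steps: np.ndarray

    def _indices(self, mask: np.ndarray) -> tuple[float, float, float]:
        length = int(self.per_character_length[mask].sum())
        mn = int(self.min_steps[mask].sum())
        mx = int(self.max_steps[mask].sum())
        ci = mn / length if length > 0 else 1.0
        ri = (mx - length) / (mx - mn) if mx > mn else 1.0
        return ci, ri, ci * ri

    @property
    def ci(self) -> float:
        return self._indices(np.ones_like(self.min_steps, dtype=bool))[0]

    @property
    def ri(self) -> float:
        return self._indices(np.ones_like(self.min_steps, dtype=bool))[1]

    @property
    def rci(self) -> float:
        return self._indices(np.ones_like(self.min_steps, dtype=bool))[2]

    @property
    def ci_informative(self) -> float:
        return self._indices(self.min_steps != self.max_steps)[0]

    @property
    def ri_informative(self) -> float:
        return self._indices(self.min_steps != self.max_steps)[1]

    @property
    def rci_informative(self) -> float:
        return self._indices(self.min_steps != self.max_steps)[2]

    def as_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "ci": self.ci, "ri": self.ri, "rci": self.rci,
            "ci_informative": self.ci_informative,
            "ri_informative": self.ri_informative,
            "rci_informative": self.rci_informative,
        }


def char_bounds(matrix: CharacterMatrix,
                taxa: Sequence[str] | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-character minimum and maximum (star-tree) step counts.

    ``min_steps`` is the number of observed states minus one (floored at
    zero): every extra state requires at least one origin on any tree.
    ``max_steps`` is the parsimony length on the star tree: the number of
    scorable taxa minus the best achievable count of the single most
    frequent state, with polymorphic cells resolved to maximize that
    count.
    """
    names = list(taxa) if taxa is not None else matrix.taxon_names
    n_char = matrix.n_characters
    mins = np.zeros(n_char, dtype=np.int64)
    maxs = np.zeros(n_char, dtype=np.int64)
    for c in range(n_char):
        cells = [matrix.cell(t, c) for t in names]
        observed = [cell.states for cell in cells if cell.is_observed]
        universe: set[int] = set().union(*observed) if observed else set()
        mins[c] = max(0, len(universe) - 1)
        if observed:
            best = max(sum(1 for st in observed if s in st) for s in universe)
            maxs[c] = len(observed) - best
    return mins, maxs


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> ParsimonyScore:
    """Score a (possibly multifurcating) tree against a matrix."""
    down, _ = _down_costs(tree, matrix)
    per_char = down[id(tree.root)].min(axis=0).astype(np.int64)
    mins, maxs = char_bounds(matrix, [lf.label for lf in tree.leaves()])
    return ParsimonyScore(
        total_length=int(per_char.sum()),
        per_character_length=per_char,
        min_steps=mins,
        max_steps=maxs,
    )


# ---------------------------------------------------------------------------
# MPR state sets


@dataclass
class MPRAnnotation:
    """Per-node, per-character downpass and final (MPR) state sets.

    ``downpass[id(node)][c]`` collects the states minimizing the subtree
    cost; ``final[id(node)][c]`` collects the states attainable at the
    node in at least one most-parsimonious reconstruction.  Sets are
    restricted to each character's observed state universe (an
    all-missing character yields empty sets).
    """

    downpass: dict[int, list[frozenset[int]]]
    final: dict[int, list[frozenset[int]]]
    per_character_length: np.ndarray


def mpr_state_sets(tree: Tree, matrix: CharacterMatrix) -> MPRAnnotation:
    down, S = _down_costs(tree, matrix)
    up = _up_costs(tree, down)
    per_char = down[id(tree.root)].min(axis=0)
    universes = [matrix.state_universe(c) for c in range(matrix.n_characters)]
    uni_mask = np.zeros((S, matrix.n_characters), dtype=bool)
    for c, u in enumerate(universes):
        for s in u:
            uni_mask[s, c] = True

    downpass: dict[int, list[frozenset[int]]] = {}
    final: dict[int, list[frozenset[int]]] = {}
    for node in tree.postorder():
        d = down[id(node)]
        total = d + up[id(node)]
        d_opt = (d == d.min(axis=0)[None, :]) & uni_mask
        f_opt = (total == per_char[None, :]) & uni_mask
        downpass[id(node)] = [frozenset(np.nonzero(d_opt[:, c])[0].tolist())
                              for c in range(matrix.n_characters)]
        final[id(node)] = [frozenset(np.nonzero(f_opt[:, c])[0].tolist())
                           for c in range(matrix.n_characters)]
    return MPRAnnotation(downpass=downpass, final=final,
                         per_character_length=per_char.astype(np.int64))


def branch_min_changes(tree: Tree, matrix: CharacterMatrix
                       ) -> dict[int, int]:
    """Minimum number of changes (summed over characters) assignable to
    each branch over all most-parsimonious reconstructions.

    Keyed by ``id(child)``.  A branch can carry zero changes for one
    character exactly when some state, fixed at both endpoints, still
    achieves that character's optimum; the branch minimum is the count of
    characters for which no such state exists.
    """
    down, _ = _down_costs(tree, matrix)
    up = _up_costs(tree, down)
    per_char = down[id(tree.root)].min(axis=0)
    out: dict[int, int] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        p = node.parent
        # outside cost of the parent given parent state s, with this child's
        # subtree removed, plus this child's subtree cost at the same state:
        # achieving per_char means the branch can be change-free.
        contribs = [_child_contribution(down[id(c)]) for c in p.children
                    if c is not node]
        b = up[id(p)].copy()
        for c in contribs:
            b = b + c
        same_state = (b + down[id(node)]).min(axis=0)
        out[id(node)] = int((same_state != per_char).sum())
    return out


# ---------------------------------------------------------------------------
# unambiguous character changes


@dataclass(frozen=True)
class CharacterChange:
    """An unambiguously optimized state change on a branch.

    ``character_id`` is 1-based to match conventional character lists;
    ``clade`` identifies the branch by the leaf set of its child side.
    """

    character_id: int
    clade: frozenset[str]
    from_states: frozenset[int]
    to_state: int
    unambiguous: bool = True

    @property
    def notation(self) -> str:
        return f"{self.character_id}:{self.to_state}"


def _tree_unambiguous(tree: Tree, matrix: CharacterMatrix
                      ) -> dict[tuple[frozenset[str], int],
                                tuple[int, frozenset[int]]]:
    """(clade, char) → (derived state, parent final set) for branches where
    every MPR of this tree puts the derived state on the child and not the
    parent."""
    ann = mpr_state_sets(tree, matrix)
    below = tree.clade_map()
    out: dict[tuple[frozenset[str], int], tuple[int, frozenset[int]]] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        child_sets = ann.final[id(node)]
        parent_sets = ann.final[id(node.parent)]
        clade = below[id(node)]
        for c in range(matrix.n_characters):
            cs, ps = child_sets[c], parent_sets[c]
            if len(cs) == 1:
                (s,) = cs
                if s not in ps:
                    out[(clade, c)] = (s, ps)
    return out


def unambiguous_changes(trees: Sequence[Tree], matrix: CharacterMatrix
                        ) -> list[CharacterChange]:
    """Changes unambiguous across a set of equally parsimonious trees.

    A change ``c:s`` on a branch is reported iff, in every input tree
    containing that branch's clade, every most-parsimonious
    reconstruction assigns ``s`` to the child and not to the parent.
    """
    if not trees:
        return []
    lengths = [fitch_length(t, matrix).total_length for t in trees]
    if len(set(lengths)) != 1:
        raise ValueError(
            f"trees are not equally parsimonious: lengths {sorted(set(lengths))}")
    per_tree = [_tree_unambiguous(t, matrix) for t in trees]
    tree_clades = [t.clades(include_trivial=True) for t in trees]
    candidates = set().union(*(set(d) for d in per_tree))
    out: list[CharacterChange] = []
    for clade, c in sorted(candidates,
                           key=lambda kc: (sorted(kc[0]), kc[1])):
        verdicts = [d.get((clade, c)) for d, cl in zip(per_tree, tree_clades)
                    if clade in cl]
        if all(v is not None for v in verdicts):
            states = {v[0] for v in verdicts}
            if len(states) == 1:
                (s,) = states
                from_states = frozenset().union(*(v[1] for v in verdicts))
                out.append(CharacterChange(
                    character_id=c + 1, clade=clade,
                    from_states=from_states, to_state=s))
    return out


def changes_table(changes: Sequence[CharacterChange]) -> str:
    """TSV rendering: one row per branch, changes in ``char:state`` form."""
    by_clade: dict[frozenset[str], list[CharacterChange]] = {}
    for ch in changes:
        by_clade.setdefault(ch.clade, []).append(ch)
    lines = ["clade\tchanges"]
    for clade in sorted(by_clade, key=lambda c: (len(c), sorted(c))):
        items = sorted(by_clade[clade], key=lambda ch: ch.character_id)
        lines.append(",".join(sorted(clade)) + "\t"
                     + " ".join(ch.notation for ch in items))
    return "\n".join(lines) + "\n"
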