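"""Ancestral-area reconstruction on a fixed topology.

The geographic range of each terminal is a single state of a 6-state
unordered character (one state per continental area).  Two tracing
methods are provided:

* **parsimony** — the node vector puts uniform weight on the node's MPR
  final state set (equivocal nodes carry several areas);
* **likelihood** — marginal posteriors under the one-parameter symmetric
  Markov k-state (Mk) model with transition probabilities

  ``P(i→i, t) = 1/k + (k−1)/k · exp(−k·α·t)``
  ``P(i→j, t) = 1/k − 1/k · exp(−k·α·t)``  (i ≠ j),

  the single rate α estimated by maximum likelihood and a flat root
  prior (a "prior equals stationary distribution" alternative is the
  same vector under this model).

Branch lengths follow either the unit scheme (every branch 1) or the
ghost scheme (implied missing fossil record in myr, zeros replaced by
1), so that older taxa sit nearer the ancestral nodes and weigh more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from cladix.matrix import AREAS, AgeTable, AreaTable, build_area_character
from cladix.parsimony import mpr_state_sets
from cladix.stratigraphy import calibrate
from cladix.tree import Node, Tree

__all__ = [
    "AncestralReconstruction",
    "MkModel",
    "assign_branch_lengths",
    "fit_rate",
    "marginal_areas",
    "mk_loglik",
    "parsimony_areas",
]


# ---------------------------------------------------------------------------
# branch lengths


def assign_branch_lengths(tree: Tree,
                          scheme: Literal["unit", "ghost"] = "unit",
                          ages: AgeTable | Mapping[str, float] | None = None
                          ) -> Tree:
    """Unit lengths, or ghost-lineage durations with zeros replaced by 1.

    The ghost scheme calibrates with the *oldest* possible first
    appearances, then sets each branch to its implied gap in myr; a
    branch with no implied gap gets length 1 so the chain still mixes
    across it.
    """
    if scheme == "unit":
        out = tree.copy()
        for node in out.postorder():
            if node.parent is not None:
                node.length = 1.0
        out.root.length = None
        return out
    if scheme == "ghost":
        if ages is None:
            raise ValueError("ghost scheme requires an age table")
        ct = calibrate(tree, ages, "oldest")
        out = ct.tree
        for node in out.postorder():
            if node.parent is not None:
                g = ct.ghost[id(node)]
                node.length = g if g > 0 else 1.0
        out.root.length = None
        return out
    raise ValueError(f"unknown branch-length scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Mk model


@dataclass(frozen=True)
class MkModel:
    """Symmetric k-state Markov model with a single rate parameter."""

    k: int = len(AREAS)
    alpha: float = 1.0
    root_prior: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not self.root_prior:
            object.__setattr__(self, "root_prior",
                               tuple([1.0 / self.k] * self.k))
        if abs(sum(self.root_prior) - 1.0) > 1e-9:
            raise ValueError("root prior must sum to 1")

    def transition_matrix(self, t: float) -> np.ndarray:
        k = self.k
        e = math.exp(-k * self.alpha * t)
        off = (1.0 - e) / k
        p = np.full((k, k), off)
        np.fill_diagonal(p, 1.0 / k + (k - 1) / k * e)
        return p


def _leaf_vector(state: int, k: int) -> np.ndarray:
    v = np.zeros(k)
    v[state] = 1.0
    return v


def _check_lengths(tree: Tree) -> None:
    for node in tree.postorder():
        if node.parent is not None:
            if node.length is None or node.length <= 0:
                raise ValueError(
                    "all branch lengths must be positive for Mk pruning "
                    f"(offending node: {node.label or '<internal>'})")


def _down_likelihoods(tree: Tree, areas: AreaTable, model: MkModel
                      ) -> tuple[dict[int, np.ndarray], float]:
    """Felsenstein pruning: per-node conditional likelihoods, rescaled;
    returns (vectors keyed by id(node), accumulated log scale)."""
    k = model.k
    down: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = _leaf_vector(areas.state(node.label), k)
        else:
            v = np.ones(k)
            for ch in node.children:
                p = model.transition_matrix(ch.length)
                v = v * (p @ down[id(ch)])
            top = v.max()
            if top <= 0:
                raise ValueError("zero likelihood encountered")
            log_scale += math.log(top)
            down[id(node)] = v / top
    return down, log_scale


def mk_loglik(tree: Tree, areas: AreaTable,
              alpha: float | None = None,
              model: MkModel | None = None) -> float:
    """Log-likelihood of the area character on a tree with lengths."""
    if model is None:
        if alpha is None:
            raise ValueError("provide alpha or a model")
        model = MkModel(alpha=alpha)
    _check_lengths(tree)
    down, log_scale = _down_likelihoods(tree, areas, model)
    prior = np.asarray(model.root_prior)
    return log_scale + math.log(float(prior @ down[id(tree.root)]))


def fit_rate(tree: Tree, areas: AreaTable,
             bounds: tuple[float, float] = (1e-8, 1e3)) -> MkModel:
    """Maximum-likelihood rate by bounded 1-D search (flat root prior).

    The search runs on log(α) and is refined to an absolute log-scale
    tolerance of 1e-8.  Monomorphic data carry no rate information and
    are rejected (use the parsimony tracing instead).
    """
    observed = {areas.state(lf.label) for lf in tree.leaves()}
    if len(observed) < 2:
        raise ValueError(
            "all terminals share one area; the rate is unidentifiable — "
            "use parsimony_areas instead")
    _check_lengths(tree)

    def neg(log_a: float) -> float:
        return -mk_loglik(tree, areas, alpha=math.exp(log_a))

    res = minimize_scalar(neg, bounds=(math.log(bounds[0]),
                                       math.log(bounds[1])),
                          method="bounded",
                          options={"xatol": 1e-8})
    return MkModel(alpha=float(math.exp(res.x)))


# ---------------------------------------------------------------------------
# reconstructions


@dataclass
class AncestralReconstruction:
    """Per-node support vectors over the areas.

    ``values[id(node)]`` is a length-k vector summing to 1: uniform over
    the MPR set for parsimony tracing, marginal posteriors for
    likelihood tracing.  ``method`` records which.  Vectors are also
    mirrored into node annotations under ``areas``.
    """

    tree: Tree
    method: str
    values: dict[int, np.ndarray]
    area_names: tuple[str, ...] = AREAS

    def vector(self, node: Node) -> np.ndarray:
        return self.values[id(node)]

    def by_clade(self) -> dict[frozenset[str], np.ndarray]:
        below = self.tree.clade_map()
        return {below[id(n)]: self.values[id(n)]
                for n in self.tree.postorder() if not n.is_leaf}

    def best_areas(self, node: Node) -> list[str]:
        v = self.values[id(node)]
        top = v.max()
        return [self.area_names[i] for i in np.nonzero(v >= top - 1e-12)[0]]

    def table(self) -> str:
        """TSV: one row per internal node (identified by its clade)."""
        lines = ["clade\tmethod\t" + "\t".join(self.area_names) + "\tbest"]
        for clade, v in sorted(self.by_clade().items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            best = ",".join(self.area_names[i]
                            for i in np.nonzero(v >= v.max() - 1e-12)[0])
            lines.append(",".join(sorted(clade)) + f"\t{self.method}\t"
                         + "\t".join(f"{x:.3f}" for x in v) + "\t" + best)
        return "\n".join(lines) + "\n"


def parsimony_areas(tree: Tree, areas: AreaTable) -> AncestralReconstruction:
    """Uniform weight over each node's MPR final state set."""
    taxa = sorted(tree.leaf_names())
    column = build_area_character(areas, taxa)
    ann = mpr_state_sets(tree, column)
    k = len(AREAS)
    values: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        final = ann.final[id(node)][0]
        v = np.zeros(k)
        for s in final:
            v[s] = 1.0 / len(final)
        values[id(node)] = v
        node.annotations["areas"] = v
    return AncestralReconstruction(tree=tree, method="parsimony",
                                   values=values)


def marginal_areas(tree: Tree, areas: AreaTable,
                   model: MkModel | None = None) -> AncestralReconstruction:
    """Marginal posterior area probabilities at every node.

    Computed by the inside–outside two-pass: the outside vector of a
    node combines the root prior, transition along its stem, and the
    partial likelihoods of everything outside its subtree; the marginal
    is the normalized elementwise product with the inside vector.
    Requires branch lengths; fits the rate when no model is given.
    """
    if model is None:
        model = fit_rate(tree, areas)
    _check_lengths(tree)
    down, _ = _down_likelihoods(tree, areas, model)
    prior = np.asarray(model.root_prior)
    outside: dict[int, np.ndarray] = {id(tree.root): prior.copy()}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        contribs = {id(ch): model.transition_matrix(ch.length) @ down[id(ch)]
                    for ch in node.children}
        base = outside[id(node)]
        for ch in node.children:
            rest = base.copy()
            for other in node.children:
                if other is not ch:
                    rest = rest * contribs[id(other)]
            p = model.transition_matrix(ch.length)
            o = p.T @ rest
            s = o.sum()
            outside[id(ch)] = o / s if s > 0 else o
    values: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        v = outside[id(node)] * down[id(node)]
        total = v.sum()
        if total <= 0:
            raise ValueError("degenerate marginal vector")
        values[id(node)] = v / total
        node.annotations["areas"] = values[id(node)]
    return AncestralReconstruction(tree=tree, method="likelihood",
                                   values=values)
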