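"""Synthetic data with known ground truth.

Generates the full input suite of the analysis pipeline — a calibrated
tree, a discrete character matrix with missing/inapplicable/polymorphic
cells, first-appearance age intervals, and a single-state geographic
character — so that search, congruence and reconstruction code can be
tested end to end without any external files.

The tree process is pure-birth (Yule): the simplest process that yields
calibrated trees with ghost-lineage structure once first appearances
are drawn below the nodes.  Characters and the area character evolve
independently under the symmetric Mk model along the true branches.

Default :class:`SimConfig` values emulate the shape of a large
published-scale basal-dinosaur matrix: 65 taxa × 255 characters with up
to four states, a tree spanning on the order of 150 myr, roughly a third
of cells unscorable, and stage-level (±2.5 myr) age uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cladix.matrix import (AREAS, AgeTable, AreaTable, CharacterMatrix,
                           StateSet)
from cladix.stratigraphy import CalibratedTree
from cladix.tree import Node, Tree

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_areas",
    "simulate_characters",
    "simulate_dataset",
    "simulate_fads",
    "simulate_yule_tree",
    "yule_n_lineages_at",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Rates are per lineage per myr; ``alpha_*`` are Mk rates per myr of
    branch.  ``missing_frac``/``polymorphic_frac``/``inapplicable_frac``
    degrade cells i.i.d.; ``block_missing`` instead wipes a contiguous
    character range per affected taxon (whole anatomical regions absent,
    as in real fossil matrices).  ``age_noise`` half-widths the
    first-appearance interval, in myr.
    """

    n_taxa: int = 65
    n_characters: int = 255
    n_states: int = 4
    alpha_char: float = 0.0015
    alpha_area: float = 0.005
    birth_rate: float = 0.03
    missing_frac: float = 0.35
    polymorphic_frac: float = 0.005
    inapplicable_frac: float = 0.03
    age_noise: float = 2.5
    block_missing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.missing_frac + self.polymorphic_frac
                + self.inapplicable_frac) > 1:
            raise ValueError("degradation fractions must sum to at most 1")
        for name in ("alpha_char", "alpha_area", "birth_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")


@dataclass
class SimOutput:
    """Ground truth plus degraded observables for one simulated study."""

    config: SimConfig
    true_tree: CalibratedTree
    matrix: CharacterMatrix
    ages: AgeTable
    areas: AreaTable
    true_node_states: dict[int, np.ndarray]
    true_area_states: dict[int, int]


# ---------------------------------------------------------------------------
# tree process


def yule_n_lineages_at(t: float, birth_rate: float,
                       rng: np.random.Generator) -> int:
    """Lineage count of one pure-birth realization at time ``t``."""
    n, clock = 1, 0.0
    while True:
        clock += rng.exponential(1.0 / (birth_rate * n))
        if clock > t:
            return n
        n += 1


def simulate_yule_tree(config: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> CalibratedTree:
    """Pure-birth tree stopped at ``n_taxa`` lineages.

    Exponential waiting times between splits; after the last split one
    more waiting time elapses before the present so terminal branches
    have positive length.  Ages are in Ma before the present; branch
    lengths equal parent age − child age (myr).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lam = config.birth_rate
    root = Node()
    birth: dict[int, float] = {}
    t = 0.0
    active: list[Node] = []
    for _ in range(2):  # root splits at time zero
        ch = Node()
        root.add_child(ch)
        birth[id(ch)] = 0.0
        active.append(ch)
    split_time: dict[int, float] = {id(root): 0.0}
    while len(active) < config.n_taxa:
        t += rng.exponential(1.0 / (lam * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        split_time[id(node)] = t
        node.length = t - birth[id(node)]
        for _ in range(2):
            ch = Node()
            node.add_child(ch)
            birth[id(ch)] = t
            active.append(ch)
    t += rng.exponential(1.0 / (lam * len(active)))
    present = t
    for i, leaf in enumerate(active):
        leaf.label = f"t{i + 1}"
        leaf.length = present - birth[id(leaf)]
    tree = Tree(root)
    node_age: dict[int, float] = {}
    ghost: dict[int, float] = {}
    for node in tree.postorder():
        node_age[id(node)] = (0.0 if node.is_leaf
                              else present - split_time[id(node)])
        node.annotations["age"] = node_age[id(node)]
    for node in tree.postorder():
        if node.parent is not None:
            ghost[id(node)] = node_age[id(node.parent)] - node_age[id(node)]
    return CalibratedTree(tree=tree, node_age=node_age, ghost=ghost)


# ---------------------------------------------------------------------------
# character evolution


def _evolve_mk(ct: CalibratedTree, n_char: int, k: int, alpha: float,
               rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Per-node state vectors under the symmetric Mk model."""
    states: dict[int, np.ndarray] = {}
    root = ct.tree.root
    states[id(root)] = rng.integers(k, size=n_char)
    for node in root.preorder():
        for ch in node.children:
            t = ct.node_age[id(node)] - ct.node_age[id(ch)]
            e = np.exp(-k * alpha * t)
            p_stay = 1.0 / k + (k - 1) / k * e
            parent_states = states[id(node)]
            changed = rng.random(n_char) >= p_stay
            shift = rng.integers(1, k, size=n_char)
            child = np.where(changed, (parent_states + shift) % k,
                             parent_states)
            states[id(ch)] = child
    return states


def simulate_characters(ct: CalibratedTree, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[CharacterMatrix, dict[int, np.ndarray]]:
    """Mk-evolved matrix plus the true states at every node.

    Degradation replaces leaf cells i.i.d. by missing, inapplicable or
    polymorphic codings at the configured fractions (or wipes contiguous
    blocks per taxon in ``block_missing`` mode); the undegraded states
    stay available in the returned node-state map.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    k = config.n_states
    truth = _evolve_mk(ct, config.n_characters, k, config.alpha_char, rng)
    leaves = ct.tree.leaves()
    names = [lf.label for lf in leaves]
    rows: list[list[StateSet]] = []
    m, i, p = (config.missing_frac, config.inapplicable_frac,
               config.polymorphic_frac)
    for lf in leaves:
        cells: list[StateSet] = []
        true_states = truth[id(lf)]
        if config.block_missing:
            u = np.ones(config.n_characters)
            if rng.random() < 0.9:
                width = int(round(m * config.n_characters))
                start = int(rng.integers(max(1, config.n_characters - width + 1)))
                u[start:start + width] = 0.0
        else:
            u = rng.random(config.n_characters)
        for c in range(config.n_characters):
            s = int(true_states[c])
            if u[c] < m:
                cells.append(StateSet.missing())
            elif u[c] < m + i:
                cells.append(StateSet.inapplicable())
            elif u[c] < m + i + p and k > 1:
                other = (s + int(rng.integers(1, k))) % k
                cells.append(StateSet.observed({s, other}))
            else:
                cells.append(StateSet.observed({s}))
        rows.append(cells)
    return CharacterMatrix(names, rows), truth


# ---------------------------------------------------------------------------
# ages and areas


def simulate_fads(ct: CalibratedTree, config: SimConfig,
                  rng: np.random.Generator | None = None) -> AgeTable:
    """First-appearance intervals drawn below each leaf's parent node.

    The true first appearance is uniform on the subtending branch; the
    published-style interval is ± ``age_noise`` around it, truncated at
    the present.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    ages: dict[str, tuple[float, float]] = {}
    for lf in ct.tree.leaves():
        hi = ct.node_age[id(lf.parent)]
        lo = ct.node_age[id(lf)]
        fad = lo + rng.random() * (hi - lo)
        ages[lf.label] = (fad + config.age_noise,
                          max(0.0, fad - config.age_noise))
    return AgeTable(ages)


def simulate_areas(ct: CalibratedTree, config: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[AreaTable, dict[int, int]]:
    """Single-state geographic character evolved under Mk with k=6."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    states = _evolve_mk(ct, 1, len(AREAS), config.alpha_area, rng)
    table = AreaTable({lf.label: AREAS[int(states[id(lf)][0])]
                       for lf in ct.tree.leaves()})
    return table, {nid: int(v[0]) for nid, v in states.items()}


def simulate_dataset(config: SimConfig | None = None) -> SimOutput:
    """One complete synthetic study under a single seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    ct = simulate_yule_tree(config, rng)
    matrix, truth = simulate_characters(ct, config, rng)
    ages = simulate_fads(ct, config, rng)
    areas, area_truth = simulate_areas(ct, config, rng)
    return SimOutput(config=config, true_tree=ct, matrix=matrix,
                     ages=ages, areas=areas, true_node_states=truth,
                     true_area_states=area_truth)
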