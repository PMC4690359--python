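"""Shared fixtures and helpers for the suite."""

from __future__ import annotations

import numpy as np
import pytest

from cladix.matrix import CharacterMatrix, StateSet
from cladix.tree import Tree, parse_newick

import oracles


def shape_to_tree(shape) -> Tree:
    return parse_newick(oracles.shape_to_newick(shape))


def random_character(rng: np.random.Generator, labels,
                     n_state: int = 3, p_missing: float = 0.15,
                     p_poly: float = 0.1, p_inapp: float = 0.05):
    """One random character in both the package's and the oracle's form."""
    cells = {}
    oracle_states = {}
    for lb in labels:
        u = rng.random()
        if u < p_missing:
            cells[lb] = StateSet.missing()
            oracle_states[lb] = None
        elif u < p_missing + p_inapp:
            cells[lb] = StateSet.inapplicable()
            oracle_states[lb] = None
        elif u < p_missing + p_inapp + p_poly:
            pair = rng.choice(n_state, size=2, replace=False)
            cells[lb] = StateSet.observed(set(int(x) for x in pair))
            oracle_states[lb] = set(int(x) for x in pair)
        else:
            s = int(rng.integers(n_state))
            cells[lb] = StateSet.observed({s})
            oracle_states[lb] = {s}
    return cells, oracle_states


def build_matrix(labels, characters) -> CharacterMatrix:
    """characters: list of dicts label -> StateSet."""
    return CharacterMatrix(
        list(labels), [[ch[lb] for ch in characters] for lb in labels])


def canonical_splits(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted splits, each as the side without the
    alphabetically first leaf."""
    uni = tree.leaf_names()
    ref = min(uni)
    out = set()
    for c in tree.clades():
        if ref in c:
            c = uni - c
        if 1 < len(c) < len(uni) - 1:
            out.add(c)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
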