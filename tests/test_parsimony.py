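"""Parsimony scoring, bounds, MPR sets and unambiguous changes, checked
against explicit enumeration oracles."""

import numpy as np
import pytest

from cladix.matrix import CharacterMatrix, StateSet
from cladix.parsimony import (branch_min_changes, char_bounds, fitch_length,
                              mpr_state_sets, unambiguous_changes)
from cladix.tree import parse_newick

import oracles
from conftest import build_matrix, random_character, shape_to_tree


def _random_instance(rng, n_taxa=6, n_chars=5, polytomy=False, n_state=3):
    labels = [f"t{i}" for i in range(n_taxa)]
    if polytomy:
        # random shape with one polytomy: group some leaves under the root
        k = int(rng.integers(3, n_taxa))
        shape = (tuple(labels[:k]),) + tuple(labels[k:])
    else:
        shapes = list(oracles.all_rooted_binary_shapes(labels))
        shape = shapes[int(rng.integers(len(shapes)))]
    chars = [random_character(rng, labels, n_state=n_state)
             for _ in range(n_chars)]
    matrix = build_matrix(labels, [c[0] for c in chars])
    return shape, matrix, [c[1] for c in chars]


class TestFitchLength:
    def test_constant_character_is_free(self):
        m = build_matrix("ABCD", [{x: StateSet.observed({1}) for x in "ABCD"}])
        t = parse_newick("((A,B),(C,D));")
        assert fitch_length(t, m).total_length == 0

    def test_single_origin(self):
        m = build_matrix("ABCD", [
            {"A": StateSet.observed({0}), "B": StateSet.observed({0}),
             "C": StateSet.observed({1}), "D": StateSet.observed({1})}])
        assert fitch_length(parse_newick("((A,B),(C,D));"), m).total_length == 1

    def test_missing_leaf_row_rejected(self):
        m = build_matrix("ABC", [{x: StateSet.observed({0}) for x in "ABC"}])
        with pytest.raises(ValueError, match="D"):
            fitch_length(parse_newick("((A,B),(C,D));"), m)

    @pytest.mark.parametrize("polytomy", [False, True])
    def test_matches_enumeration_oracle(self, rng, polytomy):
        for _ in range(30):
            shape, matrix, ostates = _random_instance(rng, polytomy=polytomy)
            got = fitch_length(shape_to_tree(shape), matrix)
            for c, states in enumerate(ostates):
                uni = sorted(matrix.state_universe(c)) or [0]
                expected = oracles.sankoff_length(shape, states, uni)
                assert got.per_character_length[c] == expected

    def test_invariant_to_taxon_order_and_rerooting(self, rng):
        shape, matrix, _ = _random_instance(rng, n_taxa=7, n_chars=8)
        base = fitch_length(shape_to_tree(shape), matrix).total_length
        shuffled = CharacterMatrix(
            matrix.taxon_names[::-1],
            [matrix.row(t) for t in matrix.taxon_names[::-1]])
        assert fitch_length(shape_to_tree(shape), shuffled).total_length == base
        # reroot: swap nesting order of the same unrooted topology
        (left, right) = shape
        if isinstance(left, tuple) and len(left) == 2:
            rerooted = (left[0], (left[1], right))
            assert fitch_length(shape_to_tree(rerooted),
                                matrix).total_length == base

    def test_two_state_classic_fitch_agrees(self, rng):
        # binary characters, no missing data: classic Fitch hand count
        labels = list("ABCDEF")
        chars = []
        for _ in range(10):
            chars.append({lb: StateSet.observed({int(rng.integers(2))})
                          for lb in labels})
        m = build_matrix(labels, chars)
        shapes = list(oracles.all_rooted_binary_shapes(labels))
        shape = shapes[int(rng.integers(len(shapes)))]
        got = fitch_length(shape_to_tree(shape), m)
        for c in range(10):
            states = {lb: {next(iter(chars[c][lb].states))} for lb in labels}
            assert got.per_character_length[c] == oracles.sankoff_length(
                shape, states, [0, 1])


class TestBounds:
    def test_min_is_states_minus_one(self):
        m = build_matrix("ABCDE", [
            {"A": StateSet.observed({0}), "B": StateSet.observed({1}),
             "C": StateSet.observed({2}), "D": StateSet.missing(),
             "E": StateSet.observed({0})}])
        mins, _ = char_bounds(m)
        assert mins[0] == 2

    def test_max_is_star_tree_count(self):
        m = build_matrix("ABCDE", [
            {x: StateSet.observed({0}) for x in "ABC"}
            | {x: StateSet.observed({1}) for x in "DE"}])
        _, maxs = char_bounds(m)
        assert maxs[0] == 2

    def test_max_equals_star_tree_fitch(self, rng):
        for _ in range(20):
            labels = [f"t{i}" for i in range(6)]
            cells, _ = random_character(rng, labels, n_state=4)
            m = build_matrix(labels, [cells])
            star = parse_newick("(" + ",".join(labels) + ");")
            _, maxs = char_bounds(m)
            assert maxs[0] == fitch_length(star, m).total_length

    def test_ensemble_index_identities(self, rng):
        shape, matrix, _ = _random_instance(rng, n_taxa=7, n_chars=12)
        s = fitch_length(shape_to_tree(shape), matrix)
        assert 0 <= s.ci <= 1 and 0 <= s.ri <= 1
        assert s.rci == pytest.approx(s.ci * s.ri)
        assert (s.min_steps <= s.per_character_length).all()
        assert (s.per_character_length <= s.max_steps).all()
        assert s.total_length == s.per_character_length.sum()


class TestMPRSets:
    def test_cherry_is_ambiguous(self):
        m = build_matrix("AB", [{"A": StateSet.observed({0}),
                                 "B": StateSet.observed({1})}])
        t = parse_newick("(A,B);")
        ann = mpr_state_sets(t, m)
        assert ann.final[id(t.root)][0] == frozenset({0, 1})

    def test_constant_character_fixed_everywhere(self):
        m = build_matrix("ABCD", [{x: StateSet.observed({2}) for x in "ABCD"}])
        t = parse_newick("((A,B),(C,D));")
        ann = mpr_state_sets(t, m)
        for node in t.postorder():
            assert ann.final[id(node)][0] == frozenset({2})

    @pytest.mark.parametrize("polytomy", [False, True])
    def test_matches_enumeration(self, rng, polytomy):
        for _ in range(25):
            shape, matrix, ostates = _random_instance(
                rng, n_taxa=6, n_chars=4, polytomy=polytomy)
            tree = shape_to_tree(shape)
            ann = mpr_state_sets(tree, matrix)
            internals = [n for n in tree.postorder() if not n.is_leaf]
            for c, states in enumerate(ostates):
                uni = sorted(matrix.state_universe(c))
                if not uni:
                    continue
                expect = oracles.mpr_sets(shape, states, uni)
                for i, node in enumerate(internals):
                    assert ann.final[id(node)][c] == frozenset(expect[i]), (
                        f"char {c}, node {i}")


class TestBranchMinChanges:
    def test_matches_enumeration(self, rng):
        for _ in range(20):
            shape, matrix, ostates = _random_instance(rng, n_taxa=6,
                                                      n_chars=4)
            tree = shape_to_tree(shape)
            mins = branch_min_changes(tree, matrix)
            internals = [s for s in oracles.postorder(shape)
                         if isinstance(s, tuple)]
            ids = {id(s): i for i, s in enumerate(internals)}
            nodes = [n for n in tree.postorder()]
            shapes = [s for s in oracles.postorder(shape)]
            for node, sh in zip(nodes, shapes):
                if node.parent is None:
                    continue
                total = 0
                for c, states in enumerate(ostates):
                    uni = sorted(matrix.state_universe(c)) or [0]
                    best, combos, oids = oracles.optimal_assignments(
                        shape, states, uni)
                    per_branch = []
                    for combo in combos:
                        ps = combo[oids[id(
                            _parent_shape(shape, sh))]]
                        if isinstance(sh, tuple):
                            cs = {combo[oids[id(sh)]]}
                        else:
                            obs = states[sh]
                            cs = set(uni) if obs is None else obs
                        per_branch.append(0 if ps in cs else 1)
                    total += min(per_branch)
                assert mins[id(node)] == total


def _parent_shape(root, target):
    for s in oracles.postorder(root):
        if isinstance(s, tuple) and any(c is target for c in s):
            return s
    raise AssertionError


class TestUnambiguousChanges:
    def test_disjoint_singletons_reported(self):
        # outgroup-anchored derived state: parent fixed 0, child fixed 1
        m = build_matrix("ABCD", [
            {"A": StateSet.observed({0}), "B": StateSet.observed({0}),
             "C": StateSet.observed({1}), "D": StateSet.observed({1})}])
        t = parse_newick("(((C,D),B),A);")
        changes = unambiguous_changes([t], m)
        assert any(c.notation == "1:1" and c.clade == frozenset("CD")
                   for c in changes)

    def test_symmetric_split_has_no_unambiguous_change(self):
        # with a balanced 2+2 distribution the root is ambiguous, so the
        # single change can sit on either side
        m = build_matrix("ABCD", [
            {"A": StateSet.observed({0}), "B": StateSet.observed({0}),
             "C": StateSet.observed({1}), "D": StateSet.observed({1})}])
        t = parse_newick("((A,B),(C,D));")
        assert unambiguous_changes([t], m) == []

    def test_cherry_root_ambiguity_suppressed(self):
        m = build_matrix("AB", [{"A": StateSet.observed({0}),
                                 "B": StateSet.observed({1})}])
        t = parse_newick("(A,B);")
        assert unambiguous_changes([t], m) == []

    def test_unequal_lengths_rejected(self):
        m = build_matrix("ABCD", [
            {"A": StateSet.observed({0}), "B": StateSet.observed({0}),
             "C": StateSet.observed({1}), "D": StateSet.observed({1})}])
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        with pytest.raises(ValueError, match="not equally parsimonious"):
            unambiguous_changes([t1, t2], m)

    def test_matches_mpr_enumeration(self, rng):
        for _ in range(15):
            shape, matrix, ostates = _random_instance(rng, n_taxa=6,
                                                      n_chars=3)
            tree = shape_to_tree(shape)
            got = {(c.clade, c.character_id - 1, c.to_state)
                   for c in unambiguous_changes([tree], matrix)}
            expect = set()
            below = tree.clade_map()
            nodes = list(tree.postorder())
            shapes = list(oracles.postorder(shape))
            for c, states in enumerate(ostates):
                uni = sorted(matrix.state_universe(c))
                if not uni:
                    continue
                best, combos, oids = oracles.optimal_assignments(
                    shape, states, uni)
                for node, sh in zip(nodes, shapes):
                    if node.parent is None or node.is_leaf:
                        continue
                    parent = _parent_shape(shape, sh)
                    child_states = {combo[oids[id(sh)]] for combo in combos}
                    parent_states = {combo[oids[id(parent)]]
                                     for combo in combos}
                    if len(child_states) == 1:
                        (s,) = child_states
                        if s not in parent_states:
                            expect.add((below[id(node)], c, s))
            internal = {x for x in got if len(x[0]) > 1}
            assert internal == expect
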