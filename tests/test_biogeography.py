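"""Ancestral-area reconstruction: branch lengths, Mk likelihood,
rate fitting and marginal reconstructions."""

import itertools
import math

import numpy as np
import pytest

from cladix.biogeography import (MkModel, assign_branch_lengths, fit_rate,
                                 marginal_areas, mk_loglik, parsimony_areas)
from cladix.matrix import AREAS, AgeTable, AreaTable
from cladix.simulate import SimConfig, simulate_areas, simulate_yule_tree
from cladix.tree import parse_newick

import oracles

K = len(AREAS)


def _areas(mapping):
    return AreaTable({t: AREAS[s] for t, s in mapping.items()})


def _tree_with_lengths(newick):
    return parse_newick(newick)


def _oracle_setup(shape, lengths_by_leaf_path):
    """Build id(subshape) -> length map for the oracle."""
    lengths = {}
    for s in oracles.postorder(shape):
        lengths[id(s)] = lengths_by_leaf_path(s)
    return lengths


class TestBranchLengths:
    def test_unit_scheme(self):
        t = assign_branch_lengths(parse_newick("((A,B),(C,D));"), "unit")
        assert all(n.length == 1.0 for n in t.postorder()
                   if n.parent is not None)

    def test_ghost_scheme_zero_becomes_one(self):
        ages = AgeTable({"A": (100.0, 100.0), "B": (80.0, 80.0)})
        t = assign_branch_lengths(parse_newick("(A,B);"), "ghost", ages)
        got = {lf.label: lf.length for lf in t.leaves()}
        assert got == {"A": 1.0, "B": 20.0}

    def test_ghost_without_ages_rejected(self):
        with pytest.raises(ValueError, match="age"):
            assign_branch_lengths(parse_newick("(A,B);"), "ghost")

    def test_ghost_matches_calibration(self, rng):
        from cladix.stratigraphy import calibrate
        tree = parse_newick("(((A,B),C),(D,E));")
        base = {x: float(a) for x, a in zip("ABCDE",
                                            rng.uniform(10, 90, size=5))}
        ages = AgeTable({k: (v, v) for k, v in base.items()})
        t = assign_branch_lengths(tree, "ghost", ages)
        ct = calibrate(tree, base)
        for a, b in zip(ct.tree.postorder(), t.postorder()):
            if a.parent is None:
                continue
            g = ct.ghost[id(a)]
            assert b.length == (g if g > 0 else 1.0)


class TestParsimonyAreas:
    def test_uniform_background(self):
        areas = _areas({x: 0 for x in "ABCD"})
        t = parse_newick("((A,B),(C,D));")
        recon = parsimony_areas(t, areas)
        for node in t.postorder():
            v = recon.vector(node)
            assert v[0] == 1.0 and v.sum() == 1.0

    def test_outgroup_anchored_root(self):
        # two outgroup leaves and the basal ingroup member share an area:
        # the root must be reconstructed there unequivocally
        t = parse_newick("(O1,(O2,(B1,(X,Y))));")
        areas = _areas({"O1": 0, "O2": 0, "B1": 0, "X": 2, "Y": 3})
        recon = parsimony_areas(t, areas)
        assert recon.vector(t.root)[0] == 1.0

    def test_matches_mpr_enumeration(self, rng):
        labels = [f"t{i}" for i in range(6)]
        shapes = list(oracles.all_rooted_binary_shapes(labels))
        for _ in range(10):
            shape = shapes[int(rng.integers(len(shapes)))]
            assignment = {lb: int(rng.integers(4)) for lb in labels}
            from conftest import shape_to_tree
            tree = shape_to_tree(shape)
            recon = parsimony_areas(tree, _areas(assignment))
            universe = sorted(set(assignment.values()))
            expect = oracles.mpr_sets(
                shape, {lb: {s} for lb, s in assignment.items()}, universe)
            internals = [n for n in tree.postorder() if not n.is_leaf]
            for i, node in enumerate(internals):
                v = recon.vector(node)
                got = {s for s in range(K) if v[s] > 0}
                assert got == expect[i]
                if got:
                    assert v[sorted(got)[0]] == pytest.approx(1 / len(got))


class TestMkLoglik:
    def test_matches_brute_force_enumeration(self, rng):
        labels = list("ABCDE")
        shapes = list(oracles.all_rooted_binary_shapes(labels))
        for _ in range(5):
            shape = shapes[int(rng.integers(len(shapes)))]
            newick = oracles.shape_to_newick(shape)
            tree = parse_newick(newick)
            # assign random lengths to matching branches
            lens = {}
            for node, sh in zip(tree.postorder(),
                                oracles.postorder(shape)):
                if node.parent is not None:
                    node.length = float(rng.uniform(0.1, 3.0))
                    lens[id(sh)] = node.length
            states = {lb: int(rng.integers(K)) for lb in labels}
            alpha = float(rng.uniform(0.02, 0.5))
            got = mk_loglik(tree, _areas(states), alpha=alpha)
            expect = oracles.brute_mk_likelihood(
                shape, lens, states, K, alpha, [1 / K] * K)
            assert got == pytest.approx(math.log(expect), abs=1e-10)

    def test_saturation_limit(self):
        tree = assign_branch_lengths(parse_newick("((A,B),(C,D));"), "unit")
        areas = _areas({"A": 0, "B": 1, "C": 2, "D": 3})
        ll = mk_loglik(tree, areas, alpha=60.0)
        assert ll == pytest.approx(4 * math.log(1 / K), abs=1e-6)

    def test_identical_states_more_likely(self):
        same = _areas({"A": 2, "B": 2})
        diff = _areas({"A": 2, "B": 4})
        tree = assign_branch_lengths(parse_newick("(A,B);"), "unit")
        # (at saturating rates the two become equal to float precision)
        for alpha in (0.01, 0.2, 1.0):
            assert (mk_loglik(tree, same, alpha=alpha)
                    > mk_loglik(tree, diff, alpha=alpha))

    def test_nonpositive_length_rejected(self):
        tree = parse_newick("(A:1,B:0);")
        with pytest.raises(ValueError, match="positive"):
            mk_loglik(tree, _areas({"A": 0, "B": 1}), alpha=0.1)

    def test_polytomy_and_child_order_invariance(self, rng):
        t1 = parse_newick("((A:1,B:2,C:1):0.5,D:2);")
        t2 = parse_newick("(D:2,(C:1,A:1,B:2):0.5);")
        areas = _areas({"A": 0, "B": 0, "C": 1, "D": 5})
        for alpha in (0.05, 0.7):
            assert mk_loglik(t1, areas, alpha=alpha) == pytest.approx(
                mk_loglik(t2, areas, alpha=alpha), abs=1e-12)


class TestFitRate:
    def test_monomorphic_rejected(self):
        tree = assign_branch_lengths(parse_newick("((A,B),C);"), "unit")
        with pytest.raises(ValueError, match="parsimony"):
            fit_rate(tree, _areas({"A": 1, "B": 1, "C": 1}))

    def test_doubling_lengths_halves_alpha(self):
        ct = simulate_yule_tree(SimConfig(n_taxa=12, seed=4))
        areas, _ = simulate_areas(ct, SimConfig(n_taxa=12, alpha_area=0.01,
                                                seed=4))
        if len({areas.area(t) for t in areas.taxa()}) < 2:
            pytest.skip("degenerate draw")
        t1 = ct.tree.copy()
        m1 = fit_rate(t1, areas)
        t2 = ct.tree.copy()
        for n in t2.postorder():
            if n.parent is not None:
                n.length *= 2
        m2 = fit_rate(t2, areas)
        assert m2.alpha == pytest.approx(m1.alpha / 2, rel=1e-4)

    def test_optimum_beats_random_alphas(self, rng):
        ct = simulate_yule_tree(SimConfig(n_taxa=10, seed=9))
        areas, _ = simulate_areas(ct, SimConfig(n_taxa=10, alpha_area=0.02,
                                                seed=9))
        model = fit_rate(ct.tree, areas)
        best = mk_loglik(ct.tree, areas, model=model)
        for _ in range(10):
            alpha = float(10 ** rng.uniform(-4, 1))
            assert best >= mk_loglik(ct.tree, areas, alpha=alpha) - 1e-9


class TestMarginals:
    def test_vectors_sum_to_one(self):
        ct = simulate_yule_tree(SimConfig(n_taxa=10, seed=2))
        areas, _ = simulate_areas(ct, SimConfig(n_taxa=10, seed=2))
        recon = marginal_areas(ct.tree, areas, MkModel(alpha=0.01))
        for node in ct.tree.postorder():
            assert abs(recon.vector(node).sum() - 1.0) < 1e-10

    def test_matches_brute_force_conditionals(self, rng):
        labels = list("ABCDE")
        shapes = list(oracles.all_rooted_binary_shapes(labels))
        for _ in range(4):
            shape = shapes[int(rng.integers(len(shapes)))]
            tree = parse_newick(oracles.shape_to_newick(shape))
            lens = {}
            for node, sh in zip(tree.postorder(), oracles.postorder(shape)):
                if node.parent is not None:
                    node.length = float(rng.uniform(0.2, 2.0))
                    lens[id(sh)] = node.length
            states = {lb: int(rng.integers(K)) for lb in labels}
            alpha = float(rng.uniform(0.05, 0.4))
            recon = marginal_areas(tree, _areas(states), MkModel(alpha=alpha))
            internals_t = [n for n in tree.postorder() if not n.is_leaf]
            internals_s = [s for s in oracles.postorder(shape)
                           if isinstance(s, tuple)]
            ids = {id(s): i for i, s in enumerate(internals_s)}
            for node, sh in zip(internals_t, internals_s):
                total = oracles.brute_mk_likelihood(
                    shape, lens, states, K, alpha, [1 / K] * K)
                for s in range(K):
                    fixed = {ids[id(sh)]: s}
                    part = oracles.brute_mk_likelihood(
                        shape, lens, states, K, alpha, [1 / K] * K,
                        fixed=fixed)
                    assert recon.vector(node)[s] == pytest.approx(
                        part / total, abs=1e-10)

    def test_label_equivariance(self):
        tree = assign_branch_lengths(
            parse_newick("((A,B),(C,(D,E)));"), "unit")
        base = {"A": 0, "B": 1, "C": 1, "D": 3, "E": 3}
        perm = {0: 2, 1: 5, 3: 0, 2: 1, 4: 4, 5: 3}
        model = MkModel(alpha=0.13)
        r1 = marginal_areas(tree, _areas(base), model)
        r2 = marginal_areas(tree, _areas({t: perm[s]
                                          for t, s in base.items()}), model)
        for node in tree.postorder():
            v1, v2 = r1.vector(node), r2.vector(node)
            for s in range(K):
                assert v1[s] == pytest.approx(v2[perm[s]], abs=1e-12)

    def test_simulation_recovery_above_chance(self):
        # accuracy of the top-1 reconstructed area against the true
        # simulated ancestral states, at a moderate rate
        hits = total = 0
        for seed in range(30):
            cfg = SimConfig(n_taxa=12, seed=seed, alpha_area=0.004)
            ct = simulate_yule_tree(cfg)
            areas, truth = simulate_areas(ct, cfg)
            if len({areas.area(t) for t in areas.taxa()}) < 2:
                continue
            recon = marginal_areas(ct.tree, areas)
            for node in ct.tree.postorder():
                if node.is_leaf:
                    continue
                total += 1
                if np.argmax(recon.vector(node)) == truth[id(node)]:
                    hits += 1
        assert hits / total > 0.5
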