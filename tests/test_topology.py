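"""Percolation detection, chemical-distance backbones, state classification."""

import numpy as np
import pytest

from flexibcd import (BIGEL, FLUID, ONE_COMPONENT_GEL,
                      backbone_chemical_distance, classify_state,
                      detect_percolation)
from flexibcd.fixtures import chain, compact_blob, random_lattice_tree, ring, spanning_chain, star
from flexibcd.geometry import minimum_image_distance


def replica_tiling_spans(members, bonds, positions, L, axis):
    """Oracle: duplicate the box 2x along `axis` and test real spanning.

    The cluster percolates along the axis iff, in the doubled system, a
    particle connects to its own shifted copy (the two copies merge into
    one component containing both replicas of some particle).
    """
    members = np.asarray(members, dtype=np.int64)
    idx = {int(p): k for k, p in enumerate(members)}
    m = len(members)
    shift = np.zeros(3)
    shift[axis] = L
    pos2 = np.concatenate([positions[members], positions[members] + shift])
    dims = np.array([L, L, L])
    dims[axis] = 2 * L
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(2 * m))
    bond_lengths = {}
    for i, j in np.asarray(bonds, dtype=np.int64).reshape(-1, 2):
        if int(i) in idx and int(j) in idx:
            a, b = idx[int(i)], idx[int(j)]
            d = minimum_image_distance(positions[int(i)], positions[int(j)], L)
            bond_lengths[(a, b)] = d
    # connect every pair of copies at the bonded distance in the doubled box
    for (a, b), d in bond_lengths.items():
        for ca in (a, a + m):
            for cb in (b, b + m):
                delta = pos2[ca] - pos2[cb]
                delta -= dims * np.round(delta / dims)
                if np.linalg.norm(delta) <= d + 1e-9:
                    g.add_edge(ca, cb)
    for k in range(m):
        if nx.has_path(g, k, k + m):
            return True
    return False


class TestPercolation:
    def test_spanning_chain_spans_x_only(self):
        fix = spanning_chain(12.1)
        n = fix.particles.n
        spans = detect_percolation(np.arange(n), fix.bonds,
                                   fix.particles.positions, fix.particles.L)
        assert list(spans) == [True, False, False]

    def test_closed_ring_spans_nothing(self):
        fix = ring(14)
        spans = detect_percolation(np.arange(14), fix.bonds,
                                   fix.particles.positions, fix.particles.L)
        assert not spans.any()

    def test_open_chain_spans_nothing(self):
        fix = chain(10)
        spans = detect_percolation(np.arange(10), fix.bonds,
                                   fix.particles.positions, fix.particles.L)
        assert not spans.any()

    def test_size_prefilter_consistent(self):
        # clusters smaller than L / (1.1 sigma) can never span
        fix = chain(8, L=20.0)
        assert 8 <= 20.0 / 1.1
        spans = detect_percolation(np.arange(8), fix.bonds,
                                   fix.particles.positions, fix.particles.L)
        assert not spans.any()

    @pytest.mark.parametrize("fixture", [
        lambda: spanning_chain(12.1),
        lambda: ring(14),
        lambda: chain(10),
        lambda: star((5, 5, 3)),
        lambda: compact_blob(2.5),
        lambda: random_lattice_tree(40, seed=7),
    ])
    def test_matches_replica_tiling_oracle(self, fixture):
        fix = fixture()
        n = fix.particles.n
        spans = detect_percolation(np.arange(n), fix.bonds,
                                   fix.particles.positions, fix.particles.L)
        for axis in range(3):
            oracle = replica_tiling_spans(np.arange(n), fix.bonds,
                                          fix.particles.positions,
                                          fix.particles.L, axis)
            assert bool(spans[axis]) == oracle

    def test_monotone_under_bond_addition(self):
        """Adding edges never unsets a spanning flag."""
        fix = spanning_chain(12.1)
        n = fix.particles.n
        base = detect_percolation(np.arange(n), fix.bonds,
                                  fix.particles.positions, fix.particles.L)
        # add a chord
        extra = np.vstack([fix.bonds, [0, n // 2]])
        more = detect_percolation(np.arange(n), extra,
                                  fix.particles.positions, fix.particles.L)
        assert np.all(more >= base)


class TestBackbone:
    def test_path_graph(self):
        bonds = [(i, i + 1) for i in range(9)]
        res = backbone_chemical_distance(np.arange(10), bonds)
        assert res.chemical_distance == 9
        assert len(res.backbone) == 10
        assert len(res.dangling) == 0

    def test_three_armed_star(self):
        fix = star((5, 5, 3))
        n = fix.particles.n
        res = backbone_chemical_distance(np.arange(n), fix.bonds)
        assert res.chemical_distance == 10
        assert len(res.dangling) == 3  # the short arm dangles

    def test_l_at_most_mass_minus_one(self):
        for seed in range(5):
            fix = random_lattice_tree(30, seed=seed)
            res = backbone_chemical_distance(np.arange(30), fix.bonds)
            assert res.chemical_distance <= 29
            # equality iff the tree is a path
            is_path = all(
                sum(1 for b in fix.bonds.ravel() if b == node) <= 2
                for node in range(30))
            assert (res.chemical_distance == 29) == is_path

    def test_matches_exhaustive_eccentricity(self):
        """l equals the true graph diameter on trees (exhaustive oracle)."""
        import networkx as nx

        for seed in range(5):
            fix = random_lattice_tree(25, seed=100 + seed)
            g = nx.Graph(list(map(tuple, fix.bonds)))
            want = max(nx.eccentricity(g).values())
            res = backbone_chemical_distance(np.arange(25), fix.bonds)
            assert res.chemical_distance == want

    def test_relabeling_invariance(self):
        fix = star((4, 4, 2))
        n = fix.particles.n
        perm = np.random.default_rng(3).permutation(n)
        remapped = perm[fix.bonds]
        res1 = backbone_chemical_distance(np.arange(n), fix.bonds)
        res2 = backbone_chemical_distance(perm, remapped)
        assert res1.chemical_distance == res2.chemical_distance

    def test_single_particle_undefined(self):
        with pytest.raises(ValueError):
            backbone_chemical_distance([3], np.empty((0, 2)))


class TestClassifyState:
    def test_all_bigel(self):
        call = classify_state([(True, True)] * 10)
        assert call.verdict == BIGEL

    def test_one_component_gel_rule(self):
        reps = [(False, True)] * 6 + [(False, False)] * 4
        assert classify_state(reps).verdict == ONE_COMPONENT_GEL

    def test_fluid(self):
        assert classify_state([(False, False)] * 10).verdict == FLUID

    def test_bigel_precedence_at_exact_half(self):
        reps = [(True, True)] * 5 + [(False, True)] * 5
        assert classify_state(reps).verdict == BIGEL

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_state([])
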