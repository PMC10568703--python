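"""Cluster statistics: labeling, unwrapping, Rg, m_w, Z_c."""

import numpy as np
import networkx as nx
import pytest

from flexibcd import (average_bonded_neighbors, label_clusters,
                      mass_average_aggregation_number, radius_of_gyration,
                      size_histogram, unwrap_cluster)
from flexibcd.analysis import mass_average_from_histogram, snapshot_cluster_stats
from flexibcd.fixtures import chain, ring, star


class TestLabeling:
    def test_no_edges_all_singletons(self):
        lab = label_clusters(5, np.empty((0, 2)))
        assert lab.n_clusters == 5
        assert len(set(lab.labels)) == 5

    def test_chain_plus_isolate(self):
        lab = label_clusters(4, [(0, 1), (1, 2)])
        assert lab.n_clusters == 2
        assert set(lab.members(lab.labels[0])) == {0, 1, 2}
        assert set(lab.members(lab.labels[3])) == {3}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx_components(self, seed):
        """Partition identical to an independent graph-traversal oracle."""
        rng = np.random.default_rng(seed)
        n = 60
        edges = rng.integers(0, n, (40, 2))
        edges = edges[edges[:, 0] != edges[:, 1]]
        lab = label_clusters(n, edges)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(map(tuple, edges))
        want = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(map(int, lab.members(k))) for k in range(lab.n_clusters)}
        assert got == want


class TestUnwrap:
    def test_dimer_across_boundary(self):
        L = 10.0
        pos = np.array([[0.05, 5, 5], [L - 0.05, 5, 5]])
        coords, ok = unwrap_cluster([0, 1], [(0, 1)], pos, L)
        assert ok
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.1)

    def test_interior_chain_identity_up_to_shift(self):
        fix = chain(10)
        pos = fix.particles.positions
        coords, ok = unwrap_cluster(np.arange(10), fix.bonds, pos, fix.particles.L)
        assert ok
        np.testing.assert_allclose(coords - coords[0], pos - pos[0], atol=1e-9)

    def test_spanning_chain_flagged_inconsistent(self):
        from flexibcd.fixtures import spanning_chain

        fix = spanning_chain(12.1)
        n = fix.particles.n
        coords, ok = unwrap_cluster(np.arange(n), fix.bonds,
                                    fix.particles.positions, fix.particles.L)
        assert not ok

    def test_rg_invariant_to_unwrap_root(self):
        fix = star((4, 3, 2))
        pos = fix.particles.positions
        n = fix.particles.n
        rgs = []
        for root in (0, n - 1):
            order = np.roll(np.arange(n), root)
            coords, ok = unwrap_cluster(order, fix.bonds, pos, fix.particles.L)
            assert ok
            rgs.append(radius_of_gyration(coords))
        assert rgs[0] == pytest.approx(rgs[1], abs=1e-12)


class TestRadiusOfGyration:
    def test_dimer_at_contact(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(0.5)

    def test_collinear_trimer(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(np.sqrt(2 / 3))

    def test_single_particle(self):
        assert radius_of_gyration(np.array([[3.0, 1, 2]])) == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(20, 3))
        shifted = coords + np.array([17.0, -3.0, 42.0])
        assert radius_of_gyration(coords) == pytest.approx(
            radius_of_gyration(shifted), abs=1e-9)


class TestMassAverage:
    def test_all_monomers(self):
        assert mass_average_aggregation_number([1] * 7) == 1.0

    def test_mixed_masses(self):
        # (1 + 1 + 4 + 16) / (1 + 1 + 2 + 4)
        assert mass_average_aggregation_number([1, 1, 2, 4]) == pytest.approx(2.75)

    def test_single_spanning_cluster(self):
        assert mass_average_aggregation_number([321]) == 321.0

    def test_empty_species_is_missing(self):
        assert np.isnan(mass_average_aggregation_number([]))

    def test_histogram_path_agrees_with_raw_path(self):
        rng = np.random.default_rng(2)
        masses = rng.integers(1, 50, 500)
        sizes, counts = size_histogram(masses)
        assert mass_average_from_histogram(sizes, counts) == pytest.approx(
            mass_average_aggregation_number(masses))
        # mass conservation within the histogram
        assert (sizes * counts).sum() == masses.sum()

    def test_mw_at_least_number_average(self):
        rng = np.random.default_rng(3)
        masses = rng.integers(1, 30, 100)
        assert mass_average_aggregation_number(masses) >= masses.mean()
        assert mass_average_aggregation_number([4] * 9) == pytest.approx(4.0)


class TestBondedNeighbors:
    def test_all_monomers_zero(self):
        assert average_bonded_neighbors(10, np.empty((0, 2))) == 0.0

    def test_all_dimers(self):
        bonds = [(0, 1), (2, 3), (4, 5)]
        assert average_bonded_neighbors(6, bonds) == 1.0

    @pytest.mark.parametrize("n", [2, 5, 10, 33])
    def test_chain_closed_form(self, n):
        bonds = [(i, i + 1) for i in range(n - 1)]
        assert average_bonded_neighbors(n, bonds) == pytest.approx(2 * (n - 1) / n)

    def test_species_restriction(self):
        species = np.array([0, 0, 1, 1])
        bonds = [(0, 1)]
        assert average_bonded_neighbors(4, bonds, species, 0) == 1.0
        assert average_bonded_neighbors(4, bonds, species, 1) == 0.0


class TestSnapshotStats:
    def test_ring_statistics(self):
        fix = ring(12)
        snap = type("S", (), {"positions": fix.particles.positions,
                              "species": fix.particles.species,
                              "bonds": fix.bonds, "L": fix.particles.L})()
        stats = snapshot_cluster_stats(snap, 0)
        assert list(stats.masses) == [12]
        assert stats.z_c == pytest.approx(2.0)
        assert not stats.spanning.any()
        # Rg of a regular 12-ring equals its circumradius
        radius = 1.05 / (2 * np.sin(np.pi / 12))
        assert stats.rg[0] == pytest.approx(radius, rel=1e-6)
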