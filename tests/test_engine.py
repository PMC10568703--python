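"""Propagator contracts: bonding rules, gating, invariants, determinism."""

import numpy as np
import pytest

from flexibcd import (BoxSpec, EngineParams, ModelParams, ParticleSet,
                      SimulationState, build_initial_configuration,
                      run_simulation)
from flexibcd.geometry import minimum_image_distance
from flexibcd.particles import SPECIES_A, SPECIES_B


def two_particle_state(d, species, p_flex_A=1.0, L=10.0, seed=0):
    pos = np.array([[4.0, 5.0, 5.0], [4.0 + d, 5.0, 5.0]])
    ps = ParticleSet(pos, np.array(species, dtype=np.int8), L)
    params = ModelParams(c_A=0.5, p_flex_A=p_flex_A, seed=seed)
    return SimulationState.from_particles(ps, params)


class TestBondFormation:
    def test_same_species_within_range_bond(self):
        st = two_particle_state(1.05, [0, 0])
        assert len(st.bond_pairs()) == 1

    def test_unlike_species_never_bond(self):
        st = two_particle_state(1.05, [0, 1])
        assert len(st.bond_pairs()) == 0

    def test_outside_well_no_bond(self):
        st = two_particle_state(1.2, [0, 0])
        assert len(st.bond_pairs()) == 0

    def test_no_interspecies_edge_in_mixture_run(self):
        params = ModelParams(c_A=0.5, seed=1)
        box = BoxSpec.from_phi(0.25, 10.0)
        ps = build_initial_configuration(params, box)
        st = SimulationState.from_particles(ps, params)
        st.advance(200)
        bonds = st.bond_pairs()
        assert len(bonds) > 0
        assert np.all(st.species[bonds[:, 0]] == st.species[bonds[:, 1]])

    def test_bond_monotonicity(self):
        """The edge set never loses a bond across sweeps."""
        params = ModelParams(c_A=1.0, seed=2)
        box = BoxSpec.from_phi(0.2, 10.0)
        ps = build_initial_configuration(params, box)
        st = SimulationState.from_particles(ps, params)
        prev = set(map(tuple, st.bond_pairs()))
        for _ in range(10):
            st.advance(20)
            now = set(map(tuple, st.bond_pairs()))
            assert prev <= now
            prev = now


class TestInvariantsDuringRun:
    @pytest.mark.parametrize("p_flex_A", [0.0, 0.5, 1.0])
    def test_hard_core_and_bond_range_hold(self, p_flex_A):
        params = ModelParams(c_A=0.5, p_flex_A=p_flex_A, seed=3)
        box = BoxSpec.from_phi(0.3, 8.0)
        ps = build_initial_configuration(params, box)
        st = SimulationState.from_particles(ps, params)
        for _ in range(5):
            st.advance(40)
            snap = st.snapshot()
            assert snap.particles.min_pair_distance() >= 1.0 - 1e-9
            bonds = snap.bonds
            if len(bonds):
                d = minimum_image_distance(snap.positions[bonds[:, 0]],
                                           snap.positions[bonds[:, 1]], snap.L)
                assert d.max() <= 1.1 + 1e-9

    def test_bonded_dimer_stays_in_well(self):
        st = two_particle_state(1.0999, [0, 0], seed=4)
        for _ in range(20):
            st.advance(50)
            d = minimum_image_distance(st.pos[0], st.pos[1], st.L)
            assert 1.0 - 1e-12 <= d <= 1.1 + 1e-9

    def test_species_counts_conserved(self):
        params = ModelParams(c_A=0.3, seed=5)
        box = BoxSpec.from_phi(0.2, 10.0)
        ps = build_initial_configuration(params, box)
        st = SimulationState.from_particles(ps, params)
        na0, nb0 = ps.n_a, ps.n_b
        st.advance(100)
        assert (st.species == SPECIES_A).sum() == na0
        assert (st.species == SPECIES_B).sum() == nb0


class TestFlexibilityGate:
    def test_rigid_bonded_pair_never_moves_internally(self):
        st = two_particle_state(1.05, [0, 0], p_flex_A=0.0, seed=6)
        d0 = minimum_image_distance(st.pos[0], st.pos[1], st.L)
        st.advance(500)
        d1 = minimum_image_distance(st.pos[0], st.pos[1], st.L)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_unbonded_particles_ignore_the_gate(self):
        # p_flex_A = 0 but no bonds: particles must still diffuse
        params = ModelParams(c_A=1.0, p_flex_A=0.0, seed=7)
        pos = np.array([[2.0, 5, 5], [8.0, 5, 5]])
        ps = ParticleSet(pos, np.zeros(2, dtype=np.int8), 20.0)
        st = SimulationState.from_particles(ps, params)
        u0 = st.unwrapped_positions().copy()
        st.advance(200, bonding=False)
        assert np.abs(st.unwrapped_positions() - u0).max() > 0

    def test_gate_acceptance_fraction_matches_p_flex(self):
        """A bonded A monomer moves a fraction ~p_flex of attempts: the
        internal separation of an isolated rigid-ish dimer updates at the
        gated rate, measured against a fully flexible reference."""
        samples = {}
        for p_flex in (0.25, 1.0):
            moved = 0
            st = two_particle_state(1.05, [0, 0], p_flex_A=p_flex, seed=8)
            prev = st.pos.copy()
            for _ in range(600):
                st.advance(1, zimm=False)
                moved += int(np.any(np.abs(st.pos - prev) > 0))
                prev = st.pos.copy()
            samples[p_flex] = moved / 600
        # per sweep: 2 gated attempts; P(any accepted) scales with p_flex
        ratio = samples[0.25] / samples[1.0]
        p_any = lambda p: 1 - (1 - p * samples[1.0] / 2 / 1) ** 2  # noqa: E731
        assert samples[0.25] < samples[1.0]
        assert 0.15 < ratio < 0.55

    def test_deterministic_gate_cycle_matches_bernoulli_rate(self):
        """The one-move-in-every-1/p_flex schedule grants bonded monomers
        the same mean mobility as the Bernoulli gate."""
        rates = {}
        for gate in (False, True):
            moved = 0
            st = two_particle_state(1.05, [0, 0], p_flex_A=0.5, seed=9)
            prev = st.pos.copy()
            for _ in range(1500):
                st.advance(1, zimm=False, deterministic_gate=gate)
                moved += int(np.any(np.abs(st.pos - prev) > 0))
                prev = st.pos.copy()
            rates[gate] = moved / 1500
        assert rates[True] == pytest.approx(rates[False], rel=0.15)


class TestDeterminism:
    def test_identical_seed_identical_trajectory(self):
        states = []
        for _ in range(2):
            params = ModelParams(c_A=0.4, p_flex_A=0.3, seed=11)
            box = BoxSpec.from_phi(0.25, 8.0)
            ps = build_initial_configuration(params, box)
            st = SimulationState.from_particles(ps, params)
            st.advance(150)
            states.append(st)
        np.testing.assert_array_equal(states[0].pos, states[1].pos)
        np.testing.assert_array_equal(states[0].deg, states[1].deg)
        assert states[0].sweep == states[1].sweep

    def test_run_simulation_kinetics_bit_identical(self):
        params = ModelParams(c_A=0.5, seed=12)
        box = BoxSpec.from_phi(0.2, 8.0)
        engine = EngineParams(max_reduced_time=0.2, keep_snapshots=False)
        a = run_simulation(params, box, engine)
        b = run_simulation(params, box, engine)
        assert a.kinetics.equals(b.kinetics)

    def test_restart_round_trip(self, tmp_path):
        params = ModelParams(c_A=0.5, seed=13)
        box = BoxSpec.from_phi(0.2, 8.0)
        ps = build_initial_configuration(params, box)
        st = SimulationState.from_particles(ps, params)
        st.advance(50)
        path = tmp_path / "state.npz"
        st.save(path)
        st2 = SimulationState.load(path)
        st.advance(50)
        st2.advance(50)
        np.testing.assert_array_equal(st.pos, st2.pos)
        np.testing.assert_array_equal(st.adj, st2.adj)


class TestRunSimulation:
    def test_zero_attraction_control(self):
        """With bonding never triggered (single particle species spread out),
        m_w stays 1: no spurious aggregation."""
        params = ModelParams(c_A=1.0, seed=14)
        box = BoxSpec(L=20.0, N_tot=30)
        ps = build_initial_configuration(params, box)
        st = SimulationState.from_particles(ps, params, bond_initial=False)
        st.advance(100, bonding=False)
        assert st.mass_average_aggregation(SPECIES_A) == 1.0
        assert st.mean_bonded_neighbors(SPECIES_A) == 0.0

    def test_gel_time_recorded_for_gelling_system(self):
        # phi_tot = 0.3 single species: spanning cluster before t/t0 = 1
        params = ModelParams(c_A=1.0, seed=15)
        box = BoxSpec.from_phi(0.3, 10.0)
        engine = EngineParams(max_reduced_time=2.0, stop_on_percolation=True,
                              keep_snapshots=False)
        result = run_simulation(params, box, engine)
        assert result.state.percolates(SPECIES_A)
        assert result.gel_time_A < 1.0
        assert not result.truncated

    def test_kinetics_columns_present(self):
        params = ModelParams(c_A=0.5, seed=16)
        box = BoxSpec.from_phi(0.15, 8.0)
        engine = EngineParams(max_reduced_time=0.1)
        result = run_simulation(params, box, engine)
        for col in ("sweep", "t_reduced", "m_w_A", "m_w_B", "Zc_A", "Zc_B",
                    "perc_A", "perc_B"):
            assert col in result.kinetics.columns
        assert result.kinetics.sweep.is_monotonic_increasing
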