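import math

import numpy as np
import pytest
from scipy import stats

from dmdpep.dmd_engine import (SimulationState, Thermostat,
                               maxwell_boltzmann_velocity, next_pair_event)
from dmdpep.peptide_model import (MolecularSystem, Particle, PotentialTable,
                                  Sequence, StepPotential, build_chain,
                                  default_forcefield)
from dmdpep.synthetic_data import ToyModelSpec, make_toy_system


class FreeParticleSystem(MolecularSystem):
    """Test helper: N particles all interacting through one step potential."""

    def __init__(self, positions, velocities, masses, pot, bonds=()):
        table = PotentialTable(default_forcefield())
        particles = [
            Particle(i, "A", i + 1, "G", "backbone", m, pot.hard_core / 2,
                     0.0, np.asarray(x, float), np.asarray(v, float))
            for i, (x, v, m) in enumerate(zip(positions, velocities, masses))
        ]
        super().__init__(particles, list(bonds), table, set(),
                         forcefield=default_forcefield())
        self._pot = pot

    def pair_potential(self, i, j):
        if frozenset((i, j)) in self.exclusions:
            return None
        return self._pot

    def hbond_eligible(self, i, j):
        return False

    def copy(self):
        return self


def make_pair(pos1, pos2, v1, v2, pot, m=1.0):
    system = FreeParticleSystem([pos1, pos2], [v1, v2], [m, m], pot)
    return SimulationState(system, 0.0, initialize_velocities=False)


class TestNextPairEvent:
    def test_head_on_core_reflection_time(self):
        pot = StepPotential(1.0)
        sys = FreeParticleSystem([(0, 0, 0), (3, 0, 0)],
                                 [(1, 0, 0), (-1, 0, 0)], [1.0, 1.0], pot)
        ev = next_pair_event(sys.particles[0], sys.particles[1], pot)
        assert ev is not None
        assert ev.kind == "core_reflection"
        assert ev.time == pytest.approx(1.0, abs=1e-12)

    def test_receding_outside_all_steps_gives_none(self):
        pot = StepPotential(1.0, ((2.0, -1.0),))
        sys = FreeParticleSystem([(0, 0, 0), (3, 0, 0)],
                                 [(-1, 0, 0), (1, 0, 0)], [1.0, 1.0], pot)
        ev = next_pair_event(sys.particles[0], sys.particles[1], pot)
        assert ev is None

    def test_oblique_well_crossing_matches_numeric_scan(self):
        pot = StepPotential(1.0, ((3.0, -0.7),))
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([5.0, 1.3, -0.4])
        v1 = np.array([0.6, 0.1, 0.0])
        v2 = np.array([-0.8, -0.05, 0.12])
        sys = FreeParticleSystem([p1, p2], [v1, v2], [1.0, 1.0], pot)
        ev = next_pair_event(sys.particles[0], sys.particles[1], pot)
        # brute-force oracle: scan |r12(t)| on a fine grid for the crossing
        ts = np.linspace(0.0, 20.0, 2_000_001)
        rel = (p2 - p1)[None, :] + np.outer(ts, v2 - v1)
        d = np.linalg.norm(rel, axis=1)
        crossing = ts[np.nonzero(np.diff(d < 3.0))[0][0] + 1]
        assert ev is not None
        assert ev.time == pytest.approx(crossing, abs=1e-5)


class TestResolvePairEvent:
    def test_equal_mass_head_on_exchanges_velocities(self):
        pot = StepPotential(1.0)
        eng = make_pair((0, 0, 0), (3, 0, 0), (1, 0, 0), (-1, 0, 0), pot)
        eng.run_events(1)
        assert eng.vx[0] == pytest.approx(-1.0)
        assert eng.vx[1] == pytest.approx(1.0)

    def test_well_entry_accelerates_by_depth(self):
        eps = 1.0
        pot = StepPotential(1.0, ((2.0, -eps),))
        eng = make_pair((0, 0, 0), (3, 0, 0), (0.5, 0, 0), (-0.5, 0, 0), pot)
        mu = 0.5
        v_rel = 1.0
        eng.run_events(1)  # well entry at r = 2
        v_rel_after = eng.vx[0] - eng.vx[1]
        # ½ μ v'² = ½ μ v² + ε
        assert 0.5 * mu * v_rel_after ** 2 == pytest.approx(
            0.5 * mu * v_rel ** 2 + eps, rel=1e-12)

    def test_insufficient_exit_energy_bounces(self):
        eps = 5.0
        pot = StepPotential(1.0, ((2.0, -eps),))
        eng = make_pair((0, 0, 0), (1.5, 0, 0), (-0.2, 0, 0), (0.2, 0, 0), pot)
        k0, u0 = eng.total_energy()
        eng.run_events(1)  # exit attempt at r = 2: radial KE 0.04 < 5
        k1, u1 = eng.total_energy()
        assert eng.vx[0] == pytest.approx(0.2)
        assert eng.vx[1] == pytest.approx(-0.2)
        assert k1 + u1 == pytest.approx(k0 + u0, rel=1e-12)
        assert u1 == u0  # still inside the well

    def test_bound_pair_oscillation_period(self):
        # relative coordinate shuttles at constant speed between the core
        # and the well edge; each leg lasts (distance)/|v_rel|
        pot = StepPotential(1.0, ((2.0, -10.0),))
        eng = make_pair((0, 0, 0), (1.5, 0, 0), (0.1, 0, 0), (-0.1, 0, 0), pot)
        v_rel = 0.2
        legs = [(2.0 - 1.5) / v_rel]  # to the outer edge (bounce)
        legs.append((2.0 - 1.0) / v_rel)  # outer edge to core
        legs.append((2.0 - 1.0) / v_rel)  # core back to outer edge
        eng.run_events(3)
        assert eng.t == pytest.approx(sum(legs), rel=1e-12)


class TestHbondReaction:
    def _two_glycine_chains(self, d0, v, extra_residues=""):
        a = build_chain(Sequence("a", "G" + extra_residues, "A"))
        b = build_chain(Sequence("b", "G" + extra_residues, "B"))
        particles = []
        from dataclasses import replace

        for p in a.particles:
            particles.append(replace(p, id=len(particles)))
        off = len(particles)
        for p in b.particles:
            q = replace(p, id=len(particles),
                        position=p.position + np.array([d0, 0.0, 0.0]))
            particles.append(q)
        bonds = list(a.bonds) + [
            type(bb)(bb.i + off, bb.j + off, bb.d_min, bb.d_max)
            for bb in b.bonds]
        system = MolecularSystem(particles, bonds, a.potentials,
                                 forcefield=a.forcefield)
        system.particles[0].velocity = np.array([v, 0.0, 0.0])
        system.particles[off].velocity = np.array([-v, 0.0, 0.0])
        return system, off

    def test_formation_exchanges_exactly_eps_hb(self):
        ff = default_forcefield()
        system, off = self._two_glycine_chains(8.0, 0.05)
        eng = SimulationState(system, 0.0, initialize_velocities=False)
        k0, u0 = eng.total_energy()
        eng.run_events(1)  # inward crossing of the reaction radius
        k1, u1 = eng.total_energy()
        assert eng.hbond_count() == 1
        assert u1 - u0 == pytest.approx(-ff.eps_hbond, rel=1e-12)
        assert k1 - k0 == pytest.approx(ff.eps_hbond, rel=1e-12)

    def test_aux_condition_violation_gives_ordinary_entry(self):
        # the donor's backbone neighbour sits on the far side, putting the
        # auxiliary distance outside the allowed band: no reaction
        ff = default_forcefield()
        system, off = self._two_glycine_chains(12.0, 0.05,
                                               extra_residues="G")
        # chain A: G1 at x=0 (donor), G2 at x=3.8; acceptor chain placed at
        # x=12 approaching G1?  the first crossing happens for G2-B1; use
        # a direct check of the geometry filter instead for the pair G1-B1.
        eng = SimulationState(system, 0.0, initialize_velocities=False)
        pr = eng._find_pair(0, off)
        aux = eng._hbond_aux_particle(0, off)
        assert aux is not None
        # force the aux particle far away and test the gate
        eng.py[aux] += 50.0
        assert not eng._hbond_allowed(pr)
        eng.py[aux] -= 50.0
        assert eng._hbond_allowed(pr) == (
            eng._hb_aux[0] <= eng._distance(aux, off) <= eng._hb_aux[1])

    def test_short_sequence_separation_never_eligible(self, short_helix):
        ca = [p.id for p in short_helix.particles if p.role == "backbone"]
        assert not short_helix.hbond_eligible(ca[0], ca[1])
        assert not short_helix.hbond_eligible(ca[0], ca[2])
        assert short_helix.hbond_eligible(ca[0], ca[3])

    def test_bond_is_reversible(self):
        system, off = self._two_glycine_chains(8.0, 0.05)
        eng = SimulationState(system, 0.0, initialize_velocities=False)
        eng.run_events(1)
        assert eng.hbond_count() == 1
        e_before = sum(eng.total_energy())
        # after formation the pair has enough radial KE to break back out
        eng.run_events(2)  # core bounce, then escape attempt
        assert sum(eng.total_energy()) == pytest.approx(e_before, rel=1e-12)


class TestThermostat:
    def test_zero_temperature_gives_zero_velocity(self, rng):
        assert maxwell_boltzmann_velocity(10.0, 0.0, rng) == (0.0, 0.0, 0.0)

    def test_mean_kinetic_energy_is_three_halves_T(self, rng):
        m, T, n = 7.0, 0.8, 100_000
        ke = np.array([
            0.5 * m * sum(v * v for v in maxwell_boltzmann_velocity(m, T, rng))
            for v in range(n // 1000)
            for _ in [0]
        ])
        # vectorized draw for speed
        v = rng.normal(0.0, math.sqrt(T / m), size=(n, 3))
        ke = 0.5 * m * (v ** 2).sum(axis=1)
        assert ke.mean() == pytest.approx(1.5 * T, rel=0.02)

    def test_fixed_seed_reproducible(self):
        a = maxwell_boltzmann_velocity(5.0, 1.0, np.random.default_rng(42))
        b = maxwell_boltzmann_velocity(5.0, 1.0, np.random.default_rng(42))
        assert a == b

    def test_velocity_distribution_passes_ks(self):
        """Thermostatted dynamics should produce Maxwell-Boltzmann velocity
        components: KS test against N(0, sqrt(T/m)) at alpha = 0.01."""
        system, _ = make_toy_system(ToyModelSpec(kind="harmonic_like_chain",
                                                 n_particles=6))
        T, m = 0.7, 50.0
        eng = SimulationState(system, T, seed=11, thermostat=Thermostat(T, 0.5))
        eng.run(200, 200)  # equilibrate
        samples = []
        while len(samples) < 12_000:
            eng.run(5, 5)
            samples.extend(eng.vx)
            samples.extend(eng.vy)
        z = np.array(samples) / math.sqrt(T / m)
        _, p = stats.kstest(z, "norm")
        assert p > 0.01


class TestRun:
    def test_zero_duration_single_frame(self, short_helix):
        eng = SimulationState(short_helix, 0.5, seed=3)
        traj = eng.run(0.0, 100.0)
        assert traj.n_frames == 1
        np.testing.assert_allclose(traj.coords[0],
                                   short_helix.coordinates())

    def test_frame_count_contract(self, short_helix):
        eng = SimulationState(short_helix, 0.5, seed=3)
        traj = eng.run(1000.0, 300.0)
        assert traj.n_frames == int(1000.0 // 300.0) + 1

    def test_energy_conservation_1e4_events(self, short_helix):
        eng = SimulationState(short_helix, 0.6, seed=5)  # no thermostat
        k0, u0 = eng.total_energy()
        eng.run_events(10_000)
        k1, u1 = eng.total_energy()
        assert abs((k1 + u1) - (k0 + u0)) / abs(k0 + u0) < 1e-6
        # incremental accumulator agrees with recomputation
        assert eng.u_pot == pytest.approx(u1, abs=1e-9)

    def test_momentum_conservation(self, short_helix):
        eng = SimulationState(short_helix, 0.6, seed=5)

        def momentum():
            p = np.zeros(3)
            for i in range(eng.n):
                p += eng.mass[i] * np.array([eng.vx[i], eng.vy[i], eng.vz[i]])
            return p

        p0 = momentum()
        eng.run_events(5000)
        assert np.abs(momentum() - p0).max() < 1e-10

    def test_no_overlap_at_sampled_frames(self, short_helix):
        eng = SimulationState(short_helix, 0.7, seed=9,
                              thermostat=Thermostat(0.7, 0.2))
        traj = eng.run(3000, 100)  # check_overlaps runs at every frame
        coords = traj.coords
        radii = np.array([p.radius for p in short_helix.particles])
        for f in range(traj.n_frames):
            d = np.linalg.norm(coords[f][:, None] - coords[f][None], axis=-1)
            hc = radii[:, None] + radii[None, :]
            for pr in eng.pairs:
                assert d[pr.i, pr.j] >= pr.radii[0] - 1e-9

    def test_determinism_identical_seed_identical_bytes(self, short_helix):
        t1 = SimulationState(short_helix.copy(), 0.6, seed=17,
                             thermostat=Thermostat(0.6, 0.1)).run(2000, 100)
        t2 = SimulationState(short_helix.copy(), 0.6, seed=17,
                             thermostat=Thermostat(0.6, 0.1)).run(2000, 100)
        assert t1.coords.tobytes() == t2.coords.tobytes()
        assert t1.e_pot.tobytes() == t2.e_pot.tobytes()


class TestTotalEnergy:
    def test_zero_velocities_zero_kinetic(self):
        pot = StepPotential(1.0)
        eng = make_pair((0, 0, 0), (5, 0, 0), (0, 0, 0), (0, 0, 0), pot)
        k, _ = eng.total_energy()
        assert k == 0.0

    def test_beyond_all_steps_zero_potential(self):
        pot = StepPotential(1.0, ((2.0, -3.0),))
        eng = make_pair((0, 0, 0), (5, 0, 0), (0, 0, 0), (0, 0, 0), pot)
        _, u = eng.total_energy()
        assert u == 0.0

    def test_three_particle_hand_summed_shells(self):
        pot = StepPotential(1.0, ((2.0, -1.5), (4.0, -0.25)))
        sys = FreeParticleSystem(
            [(0, 0, 0), (1.5, 0, 0), (0, 3.0, 0)],
            [(0, 0, 0)] * 3, [1.0] * 3, pot)
        eng = SimulationState(sys, 0.0, initialize_velocities=False)
        # pair distances: (0,1)=1.5 -> -1.5; (0,2)=3.0 -> -0.25;
        # (1,2)=sqrt(1.5²+3²)=3.354 -> -0.25
        _, u = eng.total_energy()
        assert u == pytest.approx(-1.5 - 0.25 - 0.25)
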