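"""Synthetic inputs for exercising the pipeline without downloads.

Three kinds of stand-ins:

* bundled canonical sequences (human and rat IAPP, human insulin A/B chains)
  with checksums so fixture drift fails loudly;
* toy molecular systems with analytically known thermodynamics — a
  two-level system with Schottky closed forms, a tethered square-well dimer
  whose two-body partition function is a one-dimensional integral, and a
  bonded chain for integrator stress tests;
* trajectories with planted residue contacts and planted conformational
  clusters, for validating the analysis stages against construction.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .dmd_engine import Trajectory
from .peptide_model import (BondConstraint, MolecularSystem, Particle,
                            PotentialTable, Sequence, StepPotential,
                            default_forcefield)

# Canonical mature peptide sequences (UniProt: P10997 hIAPP, P12969 rIAPP,
# P01308 insulin chains).  hIAPP and rIAPP differ at exactly 6 positions.
HIAPP = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"
RIAPP = "KCNTATCATQRLANFLVRSSNNLGPVLPPTNVGSNTY"
INSULIN_A = "GIVEQCCTSICSLYQLENYCN"
INSULIN_B = "FVNQHLCGSHLVEALYLVCGERGFFYTPKT"

_FIXTURE_MD5 = {
    "hIAPP": "393ab0c4bf75b60064c16df06199d065",
    "rIAPP": "48d3c3c650dd9205bc037f7134e73206",
    "insulin_A": "182e5c05a96d229a344ab465e38ef86d",
    "insulin_B": "f2397348127b309897ef2f62999b3383",
}


class FixtureError(RuntimeError):
    pass


def fixture_sequences(verify: bool = True) -> dict[str, Sequence]:
    """The bundled peptide sequence fixtures, checksummed against drift."""
    raw = {"hIAPP": HIAPP, "rIAPP": RIAPP,
           "insulin_A": INSULIN_A, "insulin_B": INSULIN_B}
    if verify:
        for name, s in raw.items():
            got = hashlib.md5(s.encode()).hexdigest()
            if got != _FIXTURE_MD5[name]:
                raise FixtureError(
                    f"fixture {name} drifted: md5 {got} != {_FIXTURE_MD5[name]}")
        n_diff = sum(a != b for a, b in zip(HIAPP, RIAPP))
        if n_diff != 6:
            raise FixtureError(
                f"hIAPP/rIAPP fixtures differ at {n_diff} positions, not 6")
    chains = {"hIAPP": "A", "rIAPP": "A", "insulin_A": "A", "insulin_B": "B"}
    return {name: Sequence(name, s, chains[name]) for name, s in raw.items()}


@dataclass(frozen=True)
class ToyModelSpec:
    """Specification of one analytic toy model."""

    kind: str  # "two_level" | "square_well_dimer" | "harmonic_like_chain"
    delta_e: float = 1.0  # two-level gap, kcal/mol
    g0: int = 1
    g1: int = 1
    epsilon: float = 3.0  # square-well depth, kcal/mol
    r_core: float = 2.5  # Å
    r_well: float = 4.0  # Å
    r_tether: float = 10.0  # Å
    n_particles: int = 8  # harmonic-like chain length
    bond_length: float = 3.8  # Å
    mass: float = 50.0  # amu
    seed: int = 0


class TwoLevelModel:
    """Two energy levels 0 and ΔE with degeneracies g0, g1 (Schottky).

    Samples states directly (no engine); all thermodynamic references are
    closed forms.
    """

    def __init__(self, spec: ToyModelSpec):
        self.delta_e = spec.delta_e
        self.g0 = spec.g0
        self.g1 = spec.g1

    def occupancy(self, T: float) -> float:
        """Equilibrium population of the upper level."""
        w1 = self.g1 * math.exp(-self.delta_e / T)
        return w1 / (self.g0 + w1)

    def mean_energy(self, T: float) -> float:
        return self.delta_e * self.occupancy(T)

    def cv(self, T: float) -> float:
        """Schottky specific heat (ΔE/T)² g0 g1 e^{ΔE/T} / (g0 + g1 e^{ΔE/T})²
        — written via the upper-level weight for numerical symmetry."""
        x = self.delta_e / T
        w1 = self.g1 * math.exp(-x)
        z = self.g0 + w1
        return x * x * self.g0 * w1 / (z * z)

    def peak_temperature(self) -> float:
        """Temperature of the Cv maximum, located numerically from the
        closed form."""
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda T: -self.cv(T),
                              bounds=(1e-3 * self.delta_e, 10 * self.delta_e),
                              method="bounded",
                              options={"xatol": 1e-10})
        return float(res.x)

    def sample(self, T: float, n: int, rng: np.random.Generator) -> np.ndarray:
        """Direct Boltzmann sampling of per-sample energies at T."""
        p1 = self.occupancy(T)
        upper = rng.random(n) < p1
        return np.where(upper, self.delta_e, 0.0)


class SquareWellDimerModel:
    """Two tethered particles with a single square well.

    The relative coordinate is confined to r ∈ (r_core, r_tether) with
    energy −ε inside (r_core, r_well) and 0 outside, so every canonical
    average reduces to one-dimensional integrals over r² dr.
    """

    def __init__(self, spec: ToyModelSpec):
        self.eps = spec.epsilon
        self.rc = spec.r_core
        self.rw = spec.r_well
        self.rt = spec.r_tether
        self._v_well = (self.rw ** 3 - self.rc ** 3) / 3.0
        self._v_out = (self.rt ** 3 - self.rw ** 3) / 3.0

    def _weights(self, T: float) -> tuple[float, float]:
        return self._v_well * math.exp(self.eps / T), self._v_out

    def p_bound(self, T: float) -> float:
        w_in, w_out = self._weights(T)
        return w_in / (w_in + w_out)

    def mean_energy(self, T: float) -> float:
        return -self.eps * self.p_bound(T)

    def cv(self, T: float) -> float:
        p = self.p_bound(T)
        return (self.eps / T) ** 2 * p * (1.0 - p)

    def mean_energy_quadrature(self, T: float) -> float:
        """Brute-force check of the closed form by numerical integration."""

        def u(r):
            return -self.eps if r < self.rw else 0.0

        z, _ = quad(lambda r: r * r * math.exp(-u(r) / T), self.rc, self.rt,
                    points=[self.rw], limit=200)
        ez, _ = quad(lambda r: u(r) * r * r * math.exp(-u(r) / T),
                     self.rc, self.rt, points=[self.rw], limit=200)
        return ez / z


def make_toy_system(spec: ToyModelSpec):
    """Build a toy system and its analytic reference.

    Returns ``(system_or_None, model)``: ``two_level`` has no molecular
    system (its sampler bypasses the engine); the other kinds return a
    :class:`MolecularSystem` ready for the integrator.
    """
    if spec.kind == "two_level":
        return None, TwoLevelModel(spec)
    if spec.kind == "square_well_dimer":
        table = PotentialTable(default_forcefield())
        pot = StepPotential(spec.r_core, ((spec.r_well, -spec.epsilon),))
        mid = spec.r_core + 0.5 * (spec.r_well - spec.r_core)
        particles = [
            Particle(0, "A", 1, "G", "backbone", spec.mass, spec.r_core / 2,
                     0.0, np.zeros(3), np.zeros(3)),
            Particle(1, "B", 1, "G", "backbone", spec.mass, spec.r_core / 2,
                     0.0, np.array([mid + 0.4, 0.0, 0.0]), np.zeros(3)),
        ]
        bonds = [BondConstraint(0, 1, 1.0, spec.r_tether)]
        system = _DimerSystem(particles, bonds, table, pot, spec)
        return system, SquareWellDimerModel(spec)
    if spec.kind == "harmonic_like_chain":
        table = PotentialTable(default_forcefield())
        rng = np.random.default_rng(spec.seed)
        particles = []
        for i in range(spec.n_particles):
            pos = np.array([spec.bond_length * i, 0.0, 0.0])
            particles.append(Particle(i, "A", i + 1, "G", "backbone",
                                      spec.mass, 1.5, 0.0, pos, np.zeros(3)))
        bonds = [BondConstraint(i, i + 1, 0.9 * spec.bond_length,
                                1.1 * spec.bond_length)
                 for i in range(spec.n_particles - 1)]
        system = MolecularSystem(particles, bonds, table, set(),
                                 forcefield=default_forcefield())
        return system, None
    raise ValueError(f"unknown toy model kind {spec.kind!r}")


class _DimerSystem(MolecularSystem):
    """Square-well dimer: a tethered pair whose well coexists with the bond."""

    def __init__(self, particles, bonds, table, pot, spec):
        super().__init__(particles, bonds, table, set(),
                         forcefield=default_forcefield())
        self._pot = pot
        # the bond is the tether; keep the nonbonded well active too
        self.exclusions.clear()

    def pair_potential(self, i, j):
        return self._pot

    def hbond_eligible(self, i, j):
        return False

    def copy(self):
        import copy as _copy

        from dataclasses import replace

        parts = [replace(p, position=p.position.copy(),
                         velocity=p.velocity.copy()) for p in self.particles]
        return _DimerSystem(parts, list(self.bonds), self.potentials,
                            self._pot, None)


def planted_trajectory(n_frames: int,
                       contact_plan: dict[tuple[int, int], float] | None = None,
                       cluster_plan: list[int] | None = None,
                       seed: int = 0,
                       n_residues: tuple[int, int] = (10, 10),
                       sample_interval: float = 1000.0,
                       window_fraction: float = 0.5,
                       energies: np.ndarray | None = None) -> Trajectory:
    """A synthetic two-chain bead trajectory with planted structure.

    ``contact_plan`` maps 1-based residue pairs (chain A, chain B) to target
    contact frequencies, realised exactly (to one frame) over the retained
    window by placing the chain-B bead at 4 Å or 8 Å from its chain-A
    partner on a deterministic schedule.  ``cluster_plan`` lists group
    sizes; each group's frames share one rigid template (plus a random
    rotation/translation and ~0.02 Å jitter), so RMSD-based clustering must
    recover the partition exactly.
    """
    contact_plan = contact_plan or {}
    rng = np.random.default_rng(seed)
    na, nb = n_residues
    for (i, j), f in contact_plan.items():
        if not (1 <= i <= na and 1 <= j <= nb):
            raise ValueError(f"contact plan pair {(i, j)} out of range")
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"contact frequency {f} outside [0, 1]")
    table = PotentialTable(default_forcefield())
    particles = []
    for i in range(na):
        particles.append(Particle(i, "A", i + 1, "G", "backbone", 50.0, 1.0,
                                  0.0, np.array([20.0 * i, 0.0, 0.0]),
                                  np.zeros(3)))
    for j in range(nb):
        particles.append(Particle(na + j, "B", j + 1, "G", "backbone", 50.0,
                                  1.0, 0.0, np.array([20.0 * j, 50.0, 0.0]),
                                  np.zeros(3)))
    system = MolecularSystem(particles, [], table, set(),
                             forcefield=default_forcefield())
    base = system.coordinates()
    n = len(particles)

    n_window = int(round(n_frames * window_fraction))
    window_start = n_frames - n_window

    if cluster_plan is not None:
        if sum(cluster_plan) != n_frames:
            raise ValueError("cluster plan sizes must sum to n_frames")
        templates = [base + rng.normal(scale=3.0, size=(n, 3))
                     for _ in cluster_plan]
        group_of = np.concatenate([np.full(sz, g)
                                   for g, sz in enumerate(cluster_plan)])
    else:
        templates, group_of = None, None

    from scipy.spatial.transform import Rotation

    coords = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        if templates is not None:
            x = templates[group_of[f]].copy()
            x += rng.normal(scale=0.005, size=(n, 3))
            R = Rotation.random(rng=rng).as_matrix()
            x = x @ R.T + rng.uniform(-30, 30, size=3)
        else:
            x = base.copy()
        if f >= window_start:
            widx = f - window_start
            for (i, j), freq in contact_plan.items():
                on = math.floor((widx + 1) * freq) - math.floor(widx * freq) >= 1
                a = i - 1
                b = na + j - 1
                offset = 4.0 if on else 8.0
                x[b] = x[a] + (x[b] - x[a]) / np.linalg.norm(x[b] - x[a]) * offset
        coords[f] = x
    times = sample_interval * np.arange(n_frames)
    if energies is None:
        e_pot = rng.normal(size=n_frames)
    else:
        e_pot = np.asarray(energies, dtype=float)
    e_kin = np.full(n_frames, 1.5 * n)
    return Trajectory(times, coords, e_pot, e_kin, sample_interval, system)
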