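"""Coarse-grained peptide models with discretized step-function potentials.

Peptides are represented at two beads per residue: a backbone bead on the
Cα position and a sidechain bead at the approximate sidechain centroid
(glycine carries no sidechain bead).  All non-bonded interactions are
piecewise-constant in distance (:class:`StepPotential`), which is what an
event-driven integrator requires: dynamics consist of ballistic flight
between instantaneous energy exchanges at the step radii.

Continuous physical potentials (a hydrophobicity-scaled van der Waals well
with a desolvation shoulder, plus Debye-Hückel screened electrostatics for
charged sidechains) are converted to step form by shell averaging
(:func:`discretize_potential`).

Units: lengths in Å, energies in kcal/mol, masses in amu, charges in
elementary charges, k_B = 1 so temperature is in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Sequence as TypingSequence

import numpy as np
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Backbone bead: N-Cα-C=O united group.
BACKBONE_MASS = 56.0
BACKBONE_RADIUS = 2.0

#: Ideal α-helix Cα-trace parameters: rise per residue and twist.
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3

#: Extended-chain Cα-Cα spacing.
EXTENDED_SPACING = 3.8

#: Cα-sidechain bead distance.
CA_SC_DISTANCE = 2.4

COULOMB_CONSTANT = 332.06  # kcal·Å/(mol·e²)
DIELECTRIC = 80.0


class ModelError(ValueError):
    """Raised for invalid model construction inputs."""


@dataclass(frozen=True)
class Sequence:
    """A peptide sequence with a label and chain identifier."""

    id: str
    residues: str
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ModelError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in AMINO_ACIDS:
                raise ModelError(
                    f"sequence {self.id!r}: unknown residue code {aa!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Particle:
    """One coarse-grained bead."""

    id: int
    chain_id: str
    residue_index: int  # 1-based
    residue_name: str  # one-letter code
    role: str  # "backbone" | "sidechain"
    mass: float
    radius: float
    charge: float
    position: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ModelError(f"particle {self.id}: mass must be > 0")
        if self.radius <= 0:
            raise ModelError(f"particle {self.id}: radius must be > 0")
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ModelError(f"particle {self.id}: non-finite coordinates")

    @property
    def type_key(self) -> str:
        return "BB" if self.role == "backbone" else f"SC:{self.residue_name}"


@dataclass(frozen=True)
class StepPotential:
    """Piecewise-constant pair potential.

    ``steps`` is an ordered tuple of ``(outer_radius, energy)``: the energy is
    ``steps[k][1]`` for separations in ``(prev_radius, steps[k][0])`` with
    ``prev_radius = hard_core`` for the first step, and exactly 0 beyond the
    outermost radius.  An empty ``steps`` tuple is a pure hard sphere.
    """

    hard_core: float
    steps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.hard_core <= 0:
            raise ModelError("hard_core must be > 0")
        prev = self.hard_core
        for r, e in self.steps:
            if r <= prev:
                raise ModelError(
                    f"step radii must be strictly increasing and > hard core "
                    f"(got {r} after {prev})"
                )
            if not math.isfinite(e):
                raise ModelError("step energies must be finite")
            prev = r

    @property
    def radii(self) -> tuple[float, ...]:
        """All discontinuity radii: hard core followed by the step radii."""
        return (self.hard_core,) + tuple(r for r, _ in self.steps)

    @property
    def shell_energies(self) -> tuple[float, ...]:
        """Energy of shell k (between radii k and k+1); last entry is the
        zero energy beyond the outermost radius."""
        return tuple(e for _, e in self.steps) + (0.0,)

    def energy(self, r: float) -> float:
        if r <= self.hard_core:
            return math.inf
        for outer, e in self.steps:
            if r < outer:
                return e
        return 0.0

    def shell_index(self, r: float) -> int:
        """Index of the shell containing separation ``r`` (> hard core)."""
        if r <= self.hard_core:
            raise ModelError(f"separation {r} inside hard core {self.hard_core}")
        for k, (outer, _) in enumerate(self.steps):
            if r < outer:
                return k
        return len(self.steps)


@dataclass(frozen=True)
class BondConstraint:
    """Infinite square well keeping a particle pair within [d_min, d_max]."""

    i: int
    j: int
    d_min: float
    d_max: float

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ModelError(
                f"bond ({self.i},{self.j}): need 0 < d_min < d_max, "
                f"got [{self.d_min}, {self.d_max}]"
            )


@dataclass(frozen=True)
class ElectrostaticParams:
    """Debye-Hückel screening parameters."""

    debye_length: float = 10.0
    cutoff: float = 30.0
    dielectric: float = DIELECTRIC
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if not self.cutoff > self.debye_length > 0:
            raise ModelError("require cutoff > debye_length > 0")


@dataclass(frozen=True)
class ResidueParams:
    name3: str
    sc_mass: float
    sc_radius: float
    charge: float
    hydropathy: float


@dataclass(frozen=True)
class ForceFieldParams:
    """All tunable interaction parameters of the coarse model."""

    residues: dict[str, ResidueParams]
    electrostatics: ElectrostaticParams = ElectrostaticParams()
    n_steps: int = 4  # shells for the short-range well
    n_tail_steps: int = 4  # extra shells for the electrostatic tail
    eps_background: float = 0.2  # uniform sidechain attraction, kcal/mol
    eps_hydrophobic: float = 1.2  # max hydrophobic pair well depth, kcal/mol
    desolvation_scale: float = 0.06  # kcal/mol per unit of negative hydropathy
    well_offset: float = 0.5  # well minimum at hard core + offset, Å
    well_width: float = 1.0  # Gaussian well width, Å
    well_range: float = 3.0  # short-range well extent beyond hard core, Å
    eps_hbond: float = 2.0  # hydrogen-bond well depth, kcal/mol
    hbond_radius: float = 6.5  # reaction radius between backbone beads, Å
    hbond_aux_range: tuple[float, float] = (4.5, 8.0)
    hbond_min_sequence_separation: int = 3
    max_hbonds_per_bead: int = 2
    eps_backbone: float = 0.1  # shallow backbone-backbone well, kcal/mol
    disulfide_range: tuple[float, float] = (3.4, 4.6)  # SC-SC bead level, Å

    def residue(self, aa: str) -> ResidueParams:
        return self.residues[aa]

    def desolvation(self, aa: str) -> float:
        return self.desolvation_scale * max(0.0, -self.residues[aa].hydropathy)


def load_forcefield(name: str = "forcefield_v1.tsv", **overrides) -> ForceFieldParams:
    """Load the bundled plain-text bead parameter table."""
    table: dict[str, ResidueParams] = {}
    text = resources.files("dmdpep.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, name3, mass, radius, charge, kd = line.split("\t")
        table[aa] = ResidueParams(name3, float(mass), float(radius),
                                  float(charge), float(kd))
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ModelError(f"forcefield table missing residues: {sorted(missing)}")
    return ForceFieldParams(residues=table, **overrides)


_DEFAULT_FF: ForceFieldParams | None = None


def default_forcefield() -> ForceFieldParams:
    global _DEFAULT_FF
    if _DEFAULT_FF is None:
        _DEFAULT_FF = load_forcefield()
    return _DEFAULT_FF


def screened_coulomb(q1: float, q2: float, r: float,
                     params: ElectrostaticParams | None = None) -> float:
    """Debye-Hückel screened Coulomb energy in kcal/mol.

    ``k q1 q2 exp(-r/λ_D) / (ε_r r)`` for ``r < cutoff``, exactly 0 beyond.
    """
    if params is None:
        params = ElectrostaticParams()
    if r <= 0:
        raise ModelError(f"separation must be positive, got {r}")
    if r >= params.cutoff:
        return 0.0
    return (params.coulomb_constant * q1 * q2
            * math.exp(-r / params.debye_length) / (params.dielectric * r))


def discretize_potential(continuous_energy: Callable[[float], float],
                         hard_core: float, r_max: float,
                         n_steps: int) -> StepPotential:
    """Convert a continuous radial energy to a step potential.

    The interval ``[hard_core, r_max]`` is partitioned into ``n_steps``
    equal-width shells; each step energy is the radial mean of the continuous
    function over its shell, and the energy beyond ``r_max`` is exactly 0.
    """
    if n_steps < 1:
        raise ModelError(f"n_steps must be >= 1, got {n_steps}")
    if r_max <= hard_core:
        raise ModelError(f"r_max ({r_max}) must exceed hard_core ({hard_core})")
    edges = np.linspace(hard_core, r_max, n_steps + 1)
    steps = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        integral, _ = quad(continuous_energy, lo, hi, limit=200)
        steps.append((float(hi), float(integral / (hi - lo))))
    return StepPotential(hard_core=float(hard_core), steps=tuple(steps))


class PotentialTable:
    """Lazy per-bead-type-pair step potentials under one forcefield."""

    def __init__(self, ff: ForceFieldParams):
        self.ff = ff
        self._cache: dict[frozenset, StepPotential] = {}
        self._hbond_cache: StepPotential | None = None

    def _bead_props(self, key: str) -> tuple[float, float, float]:
        """(radius, charge, hydropathy) for a bead type key."""
        if key == "BB" or key == "TOY":
            return BACKBONE_RADIUS, 0.0, 0.0
        aa = key.split(":")[1]
        rp = self.ff.residue(aa)
        return rp.sc_radius, rp.charge, rp.hydropathy

    def get(self, key_a: str, key_b: str) -> StepPotential:
        cache_key = frozenset((key_a, key_b))
        pot = self._cache.get(cache_key)
        if pot is None:
            pot = self._build(key_a, key_b)
            self._cache[cache_key] = pot
        return pot

    def hbond_potential(self) -> StepPotential:
        """The bonded backbone pair potential after a hydrogen-bond reaction."""
        if self._hbond_cache is None:
            hc = 2 * BACKBONE_RADIUS
            self._hbond_cache = StepPotential(
                hard_core=hc, steps=((self.ff.hbond_radius, -self.ff.eps_hbond),))
        return self._hbond_cache

    def _build(self, key_a: str, key_b: str) -> StepPotential:
        ff = self.ff
        ra, qa, ha = self._bead_props(key_a)
        rb, qb, hb = self._bead_props(key_b)
        hc = ra + rb
        if key_a == "BB" and key_b == "BB":
            # Shallow well out to the hydrogen-bond reaction radius so that
            # every eligible backbone pair generates an event there.
            return StepPotential(hc, ((ff.hbond_radius, -ff.eps_backbone),))
        if key_a == "BB" or key_b == "BB" or key_a == "TOY" or key_b == "TOY":
            return StepPotential(hc)  # hard sphere only
        # sidechain-sidechain: hydrophobic well + desolvation shoulder
        aa_a, aa_b = key_a.split(":")[1], key_b.split(":")[1]
        frac_a = (ha + 4.5) / 9.0
        frac_b = (hb + 4.5) / 9.0
        amp = (-(ff.eps_background + ff.eps_hydrophobic * frac_a * frac_b)
               + ff.desolvation(aa_a) + ff.desolvation(aa_b))
        r0 = hc + ff.well_offset
        w = ff.well_width
        charged = qa != 0 and qb != 0
        es = ff.electrostatics

        def u_short(r: float) -> float:
            u = amp * math.exp(-((r - r0) / w) ** 2)
            if charged:
                u += screened_coulomb(qa, qb, r, es)
            return u

        short = discretize_potential(u_short, hc, hc + ff.well_range, ff.n_steps)
        if not charged:
            return short
        tail = discretize_potential(
            lambda r: screened_coulomb(qa, qb, r, es),
            hc + ff.well_range, es.cutoff, ff.n_tail_steps)
        return StepPotential(hc, short.steps + tail.steps)


@dataclass
class MolecularSystem:
    """Particles, bonded constraints and pair-potential assignments."""

    particles: list[Particle]
    bonds: list[BondConstraint]
    potentials: PotentialTable
    exclusions: set[frozenset] = field(default_factory=set)
    box: float | None = None  # reflecting cubic box edge, Å
    forcefield: ForceFieldParams | None = None

    def __post_init__(self) -> None:
        for b in self.bonds:
            self.exclusions.add(frozenset((b.i, b.j)))
        if self.forcefield is None:
            self.forcefield = self.potentials.ff

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for p in self.particles:
            if p.chain_id not in seen:
                seen.append(p.chain_id)
        return seen

    def residues_of_chain(self, chain_id: str) -> list[int]:
        out: list[int] = []
        for p in self.particles:
            if p.chain_id == chain_id and p.residue_index not in out:
                out.append(p.residue_index)
        return out

    def coordinates(self) -> np.ndarray:
        return np.array([p.position for p in self.particles])

    def set_coordinates(self, coords: np.ndarray) -> None:
        for p, x in zip(self.particles, coords):
            p.position = np.array(x, dtype=float)

    def pair_potential(self, i: int, j: int) -> StepPotential | None:
        if frozenset((i, j)) in self.exclusions:
            return None
        return self.potentials.get(self.particles[i].type_key,
                                   self.particles[j].type_key)

    def copy(self) -> "MolecularSystem":
        parts = [replace(p, position=p.position.copy(),
                         velocity=p.velocity.copy()) for p in self.particles]
        return MolecularSystem(parts, list(self.bonds), self.potentials,
                               set(self.exclusions), self.box, self.forcefield)

    def hbond_eligible(self, i: int, j: int) -> bool:
        pi, pj = self.particles[i], self.particles[j]
        if pi.role != "backbone" or pj.role != "backbone":
            return False
        if pi.chain_id != pj.chain_id:
            return True
        sep = abs(pi.residue_index - pj.residue_index)
        return sep >= (self.forcefield.hbond_min_sequence_separation
                       if self.forcefield else 3)


def _helix_ca(i: int) -> np.ndarray:
    theta = math.radians(HELIX_TWIST_DEG) * i
    return np.array([HELIX_RADIUS * math.cos(theta),
                     HELIX_RADIUS * math.sin(theta),
                     HELIX_RISE * i])


def build_chain(seq: Sequence, start_conformation: str = "helix",
                forcefield: ForceFieldParams | None = None,
                potentials: PotentialTable | None = None) -> MolecularSystem:
    """Build a single coarse-grained chain in an ideal starting conformation.

    ``helix`` places backbone beads on an ideal α-helix (1.5 Å rise, 100°
    twist per residue); ``extended`` places them on a straight line at 3.8 Å
    spacing.  Sidechain beads point away from the backbone.
    """
    if start_conformation not in ("helix", "extended"):
        raise ModelError(f"unknown start conformation {start_conformation!r}")
    ff = forcefield or default_forcefield()
    table = potentials or PotentialTable(ff)
    particles: list[Particle] = []
    bonds: list[BondConstraint] = []
    ca_ids: list[int] = []
    sc_ids: dict[int, int] = {}

    for idx, aa in enumerate(seq.residues):
        rp = ff.residue(aa)
        if start_conformation == "helix":
            ca = _helix_ca(idx)
            radial = np.array([ca[0], ca[1], 0.0])
            nrm = np.linalg.norm(radial)
            direction = radial / nrm
            sc = ca + CA_SC_DISTANCE * direction
        else:
            ca = np.array([EXTENDED_SPACING * idx, 0.0, 0.0])
            side = 1.0 if idx % 2 == 0 else -1.0
            sc = ca + np.array([0.0, side * CA_SC_DISTANCE, 0.0])
        pid = len(particles)
        particles.append(Particle(pid, seq.chain_id, idx + 1, aa, "backbone",
                                  BACKBONE_MASS, BACKBONE_RADIUS, 0.0,
                                  ca, np.zeros(3)))
        ca_ids.append(pid)
        if aa != "G":
            sid = len(particles)
            particles.append(Particle(sid, seq.chain_id, idx + 1, aa,
                                      "sidechain", rp.sc_mass, rp.sc_radius,
                                      rp.charge, sc, np.zeros(3)))
            sc_ids[idx] = sid
            bonds.append(BondConstraint(pid, sid, CA_SC_DISTANCE - 0.15,
                                        CA_SC_DISTANCE + 0.15))

    for idx in range(len(seq) - 1):
        bonds.append(BondConstraint(ca_ids[idx], ca_ids[idx + 1], 3.6, 4.0))
    for idx in range(len(seq) - 2):
        bonds.append(BondConstraint(ca_ids[idx], ca_ids[idx + 2], 4.2, 7.61))

    exclusions: set[frozenset] = set()
    for b in bonds:
        exclusions.add(frozenset((b.i, b.j)))
    # 1-3 pairs through the shared backbone bead
    for idx, sid in sc_ids.items():
        for nb in (idx - 1, idx + 1):
            if 0 <= nb < len(seq):
                exclusions.add(frozenset((sid, ca_ids[nb])))
    return MolecularSystem(particles, bonds, table, exclusions,
                           forcefield=ff)


def add_disulfide(system: MolecularSystem, res_a: tuple[str, int],
                  res_b: tuple[str, int]) -> None:
    """Cross-link two cysteines by a sidechain-sidechain bond constraint."""
    ff = system.forcefield or default_forcefield()

    def find(chain: str, resi: int) -> int:
        for p in system.particles:
            if (p.chain_id == chain and p.residue_index == resi
                    and p.role == "sidechain"):
                if p.residue_name != "C":
                    raise ModelError(
                        f"residue {chain}:{resi} is {p.residue_name}, not C")
                return p.id
        raise ModelError(f"no sidechain bead for residue {chain}:{resi}")

    i, j = find(*res_a), find(*res_b)
    lo, hi = ff.disulfide_range
    bond = BondConstraint(i, j, lo, hi)
    system.bonds.append(bond)
    system.exclusions.add(frozenset((i, j)))


def _min_pair_gap(system: MolecularSystem, offset: int) -> float:
    """Smallest (distance - summed hard core) over inter-chain pairs split
    at particle index ``offset``."""
    coords = system.coordinates()
    radii = np.array([p.radius for p in system.particles])
    a, b = coords[:offset], coords[offset:]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    hc = radii[:offset, None] + radii[None, offset:]
    return float(np.min(d - hc))


def assemble_system(chains: TypingSequence[MolecularSystem],
                    placement: str = "proximal_parallel",
                    separation: float = 10.0,
                    rng_seed: int = 0,
                    max_retries: int = 100) -> MolecularSystem:
    """Merge chains into one system, placing copies along the x axis.

    ``proximal_parallel`` keeps every chain in its built orientation and
    offsets centres of mass by ``separation`` along x; ``random_orientation``
    additionally applies a seeded random rotation about each chain's centre
    of mass, retrying (with fresh rotations) until no inter-chain hard-core
    overlap remains.
    """
    if not chains:
        raise ModelError("no chains to assemble")
    if placement not in ("proximal_parallel", "random_orientation"):
        raise ModelError(f"unknown placement {placement!r}")
    if len(chains) == 1:
        return chains[0].copy()
    rng = np.random.default_rng(rng_seed)
    table = chains[0].potentials
    ff = chains[0].forcefield

    for attempt in range(max_retries):
        particles: list[Particle] = []
        bonds: list[BondConstraint] = []
        exclusions: set[frozenset] = set()
        seen_chain_ids: set[str] = set()
        ok = True
        for ci, chain in enumerate(chains):
            offset = len(particles)
            coords = chain.coordinates()
            masses = np.array([p.mass for p in chain.particles])
            com = np.average(coords, axis=0, weights=masses)
            local = coords - com
            if placement == "random_orientation":
                local = Rotation.random(rng=rng).apply(local)
            placed = local + np.array([ci * separation, 0.0, 0.0])
            cid = chain.particles[0].chain_id
            while cid in seen_chain_ids:
                cid = cid + "'"
            seen_chain_ids.add(cid)
            for p, x in zip(chain.particles, placed):
                particles.append(replace(p, id=len(particles), chain_id=cid,
                                         position=np.array(x),
                                         velocity=p.velocity.copy()))
            for b in chain.bonds:
                bonds.append(BondConstraint(b.i + offset, b.j + offset,
                                            b.d_min, b.d_max))
            for pair in chain.exclusions:
                i, j = tuple(pair)
                exclusions.add(frozenset((i + offset, j + offset)))
            if ci > 0:
                merged = MolecularSystem(particles, [], table, set(),
                                         forcefield=ff)
                if _min_pair_gap(merged, offset) < 0.0:
                    ok = False
                    break
        if ok:
            return MolecularSystem(particles, bonds, table, exclusions,
                                   forcefield=ff)
        if placement == "proximal_parallel":
            break  # deterministic placement cannot be retried
    raise ModelError(
        f"could not place chains without hard-core overlap after "
        f"{max_retries} attempts at separation {separation} Å")
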