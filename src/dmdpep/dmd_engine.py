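"""Exact event-driven integration of step-potential systems.

Between events every particle moves ballistically; at an event the radial
velocity components of the participating pair change so that linear momentum
is conserved exactly and total energy (kinetic + step potential) is conserved
exactly across well boundaries.  A pair that lacks the radial kinetic energy
to climb an energy step is reflected elastically ("bounce").

The integrator keeps a priority queue of predicted events with lazy
invalidation: every particle carries a collision counter, and an event
scheduled with stale counters is discarded when popped.  Hydrogen bonds are
engine-level reaction events between backbone beads: at the reaction radius
an eligible pair can switch to a deeper "bonded" pair potential, with the
kinetic energy adjusted to conserve total energy; the mirror-image crossing
breaks the bond.  Temperature is controlled by an Andersen thermostat
(random ghost collisions that redraw one particle's velocity from the
Maxwell-Boltzmann distribution).

Reduced units: k_B = 1, lengths in Å, energies in kcal/mol, masses in amu;
one time unit corresponds nominally to 50 fs.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .peptide_model import MolecularSystem, StepPotential

#: Nominal physical duration of one DMD time unit.
FEMTOSECONDS_PER_TIME_UNIT = 50.0

# event kinds
CORE_REFLECTION = "core_reflection"
WELL_ENTRY = "well_entry"
WELL_EXIT_ATTEMPT = "well_exit_attempt"
BOND_BOUNDARY = "bond_boundary"
HBOND_REACTION = "hbond_reaction"
THERMOSTAT_GHOST = "thermostat_ghost"
WALL_REFLECTION = "wall_reflection"

_GEOM_TOL = 1e-7


class EngineError(RuntimeError):
    """Integrator-level failure (overlap, inconsistent geometry)."""


@dataclass(frozen=True)
class Event:
    """A predicted discontinuity crossing."""

    time: float
    kind: str
    i: int
    j: int  # -1 for single-particle events
    boundary: int  # index into the pair's boundary radii
    outward: bool
    count_i: int
    count_j: int


@dataclass
class Thermostat:
    """Andersen thermostat: ghost collisions per particle per time unit."""

    target_T: float
    ghost_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.ghost_rate <= 0:
            raise ValueError("ghost_rate must be > 0 when enabled")


@dataclass
class Trajectory:
    """Sampled frames of a run: times, coordinates and energies."""

    times: np.ndarray
    coords: np.ndarray  # (n_frames, n_particles, 3)
    e_pot: np.ndarray
    e_kin: np.ndarray
    sample_interval: float
    system: MolecularSystem
    run_id: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(np.concatenate([self.times, other.times]),
                          np.concatenate([self.coords, other.coords]),
                          np.concatenate([self.e_pot, other.e_pot]),
                          np.concatenate([self.e_kin, other.e_kin]),
                          self.sample_interval, self.system, self.run_id)


def crossing_time(rel_pos, rel_vel, r_inner: float | None,
                  r_outer: float | None) -> tuple[float, bool] | None:
    """Earliest positive time at which ballistic relative motion reaches the
    inner or outer boundary radius.  Returns ``(t, outward)`` or ``None``.
    """
    rx, ry, rz = rel_pos
    vx, vy, vz = rel_vel
    a = vx * vx + vy * vy + vz * vz
    if a == 0.0:
        return None
    b = rx * vx + ry * vy + rz * vz
    r2 = rx * rx + ry * ry + rz * rz
    best_t = math.inf
    outward = False
    if r_inner is not None and b < 0.0:
        c = r2 - r_inner * r_inner
        disc = b * b - a * c
        if disc > 0.0:
            t = (-b - math.sqrt(disc)) / a
            if 0.0 <= t < best_t:
                best_t, outward = t, False
    if r_outer is not None:
        c = r2 - r_outer * r_outer
        disc = b * b - a * c
        if disc > 0.0:
            t = (-b + math.sqrt(disc)) / a
            if 0.0 <= t < best_t:
                best_t, outward = t, True
    if math.isinf(best_t):
        return None
    return best_t, outward


def next_pair_event(p1, p2, pot: StepPotential) -> Event | None:
    """Predict the next boundary crossing for an isolated particle pair.

    Standalone form of the engine's internal prediction, for two particles
    currently between discontinuities of ``pot``.
    """
    rel = p1.position - p2.position
    vel = p1.velocity - p2.velocity
    r = float(np.linalg.norm(rel))
    shell = pot.shell_index(r)
    radii = pot.radii
    r_in = radii[shell]
    r_out = radii[shell + 1] if shell + 1 < len(radii) else None
    hit = crossing_time(tuple(rel), tuple(vel), r_in, r_out)
    if hit is None:
        return None
    t, outward = hit
    boundary = shell + 1 if outward else shell
    if boundary == 0:
        kind = CORE_REFLECTION
    elif outward:
        kind = WELL_EXIT_ATTEMPT
    else:
        kind = WELL_ENTRY
    return Event(t, kind, p1.id, p2.id, boundary, outward, 0, 0)


class _Pair:
    """Interacting pair bookkeeping.

    ``radii`` are the boundary radii in increasing order; shell ``s`` lies
    between ``radii[s]`` and ``radii[s+1]``.  Without an outer wall there is
    one more shell than the index of the last boundary (the zero-energy
    region beyond it); with an outer wall (bond constraint) the outermost
    boundary reflects.  ``energies[s]`` is the potential energy of shell s.
    """

    __slots__ = ("i", "j", "radii", "energies", "is_bond", "outer_wall",
                 "hb_eligible", "bonded_energies", "hbonded", "shell", "mu",
                 "idx")

    def __init__(self, idx, i, j, radii, energies, is_bond, outer_wall,
                 hb_eligible, bonded_energies, mu):
        self.idx = idx
        self.i = i
        self.j = j
        self.radii = radii
        self.energies = energies
        self.is_bond = is_bond
        self.outer_wall = outer_wall
        self.hb_eligible = hb_eligible
        self.bonded_energies = bonded_energies
        self.hbonded = False
        self.shell = 0
        self.mu = mu

    def current_energies(self):
        return self.bonded_energies if self.hbonded else self.energies

    @property
    def n_shells(self) -> int:
        return len(self.radii) - 1 if self.outer_wall else len(self.radii)


class SimulationState:
    """Event-driven integrator state for one :class:`MolecularSystem`.

    Holds positions/velocities as flat Python lists (the event loop is
    scalar-heavy), the pending-event heap, per-particle collision counters,
    and the potential-energy accumulator.
    """

    def __init__(self, system: MolecularSystem, temperature: float,
                 seed: int = 0, thermostat: Thermostat | None = None,
                 initialize_velocities: bool = True):
        self.system = system
        self.T = temperature
        self.rng = np.random.default_rng(seed)
        self.thermostat = thermostat
        n = system.n_particles
        self.n = n
        coords = system.coordinates()
        self.px = [float(c[0]) for c in coords]
        self.py = [float(c[1]) for c in coords]
        self.pz = [float(c[2]) for c in coords]
        self.mass = [p.mass for p in system.particles]
        self.radius = [p.radius for p in system.particles]
        if initialize_velocities and temperature > 0:
            sig = [math.sqrt(temperature / m) for m in self.mass]
            v = self.rng.normal(size=(n, 3))
            self.vx = [sig[i] * v[i, 0] for i in range(n)]
            self.vy = [sig[i] * v[i, 1] for i in range(n)]
            self.vz = [sig[i] * v[i, 2] for i in range(n)]
        else:
            self.vx = [float(p.velocity[0]) for p in system.particles]
            self.vy = [float(p.velocity[1]) for p in system.particles]
            self.vz = [float(p.velocity[2]) for p in system.particles]
        self.t = 0.0
        self.counters = [0] * n
        self.heap: list = []
        self._seq = 0
        self.n_events = 0
        self.event_log: deque = deque(maxlen=50)
        self.hbond_partners: list[list[int]] = [[] for _ in range(n)]
        ff = system.forcefield
        self._hb_max = ff.max_hbonds_per_bead if ff else 2
        self._hb_aux = ff.hbond_aux_range if ff else (4.5, 8.0)
        if system.box is not None:
            for i in range(n):
                r = self.radius[i]
                for x in (self.px[i], self.py[i], self.pz[i]):
                    if not r - _GEOM_TOL <= x <= system.box - r + _GEOM_TOL:
                        raise EngineError(
                            f"particle {i} outside the reflecting box "
                            f"[0, {system.box}] at coordinate {x:.3f}")
        self._build_pairs()
        self._init_shells()
        self.u_pot = self._potential_from_shells()
        self._schedule_all()
        if self.thermostat is not None:
            self._schedule_ghost()

    # -- construction -----------------------------------------------------

    def _build_pairs(self) -> None:
        sysm = self.system
        self.pairs: list[_Pair] = []
        self.neighbors: list[list[int]] = [[] for _ in range(self.n)]
        hb_pot = sysm.potentials.hbond_potential()
        hb_energies = hb_pot.shell_energies
        bonded = {}
        for b in sysm.bonds:
            bonded[frozenset((b.i, b.j))] = b
        for i in range(self.n):
            for j in range(i + 1, self.n):
                key = frozenset((i, j))
                mu = self.mass[i] * self.mass[j] / (self.mass[i] + self.mass[j])
                if key in bonded:
                    b = bonded[key]
                    pot = sysm.pair_potential(i, j)
                    if pot is None:
                        pr = _Pair(len(self.pairs), i, j,
                                   (b.d_min, b.d_max), (0.0,), True, True,
                                   False, None, mu)
                    else:
                        # bond walls combined with interior energy steps
                        radii = [max(pot.hard_core, b.d_min)]
                        radii += [r for r, _ in pot.steps
                                  if radii[0] < r < b.d_max]
                        radii.append(b.d_max)
                        energies = tuple(
                            pot.energy(0.5 * (lo + hi))
                            for lo, hi in zip(radii[:-1], radii[1:]))
                        pr = _Pair(len(self.pairs), i, j, tuple(radii),
                                   energies, True, True, False, None, mu)
                    self.pairs.append(pr)
                elif key in sysm.exclusions:
                    continue
                else:
                    pot = sysm.pair_potential(i, j)
                    if pot is None:
                        continue
                    hb = sysm.hbond_eligible(i, j)
                    pr = _Pair(len(self.pairs), i, j, pot.radii,
                               pot.shell_energies, False, False, hb,
                               hb_energies if hb else None, mu)
                    self.pairs.append(pr)
                self.neighbors[i].append(self.pairs[-1].idx)
                self.neighbors[j].append(self.pairs[-1].idx)

    def _init_shells(self) -> None:
        for pr in self.pairs:
            r = self._distance(pr.i, pr.j)
            if r <= pr.radii[0]:
                what = "bond wall" if pr.is_bond else "hard core"
                raise EngineError(
                    f"pair ({pr.i},{pr.j}) inside {what}: r = {r:.4f} <= "
                    f"{pr.radii[0]:.4f}")
            if pr.outer_wall and r >= pr.radii[-1] + _GEOM_TOL:
                raise EngineError(
                    f"bond ({pr.i},{pr.j}) outside outer wall "
                    f"{pr.radii[-1]:.4f}: r = {r:.4f}")
            s = 0
            while s + 1 < len(pr.radii) and r >= pr.radii[s + 1]:
                s += 1
            if pr.outer_wall:
                s = min(s, pr.n_shells - 1)
            pr.shell = s

    # -- geometry helpers -------------------------------------------------

    def _distance(self, i: int, j: int) -> float:
        dx = self.px[i] - self.px[j]
        dy = self.py[i] - self.py[j]
        dz = self.pz[i] - self.pz[j]
        return math.sqrt(dx * dx + dy * dy + dz * dz)

    def _advance_all(self, t_new: float) -> None:
        dt = t_new - self.t
        if dt == 0.0:
            return
        px, py, pz, vx, vy, vz = self.px, self.py, self.pz, self.vx, self.vy, self.vz
        for i in range(self.n):
            px[i] += vx[i] * dt
            py[i] += vy[i] * dt
            pz[i] += vz[i] * dt
        self.t = t_new

    # -- scheduling -------------------------------------------------------

    def _push(self, t: float, kind: str, i: int, j: int, boundary: int,
              outward: bool) -> None:
        self._seq += 1
        ci = self.counters[i]
        cj = self.counters[j] if j >= 0 else 0
        heapq.heappush(self.heap, (t, self._seq, kind, i, j, boundary,
                                   outward, ci, cj))

    def _predict_pair(self, pr: _Pair) -> None:
        i, j = pr.i, pr.j
        rel = (self.px[i] - self.px[j], self.py[i] - self.py[j],
               self.pz[i] - self.pz[j])
        vel = (self.vx[i] - self.vx[j], self.vy[i] - self.vy[j],
               self.vz[i] - self.vz[j])
        s = pr.shell
        radii = pr.radii
        r_in = radii[s]
        r_out = radii[s + 1] if s + 1 < len(radii) else None
        hit = crossing_time(rel, vel, r_in, r_out)
        if hit is None:
            return
        t, outward = hit
        boundary = s + 1 if outward else s
        if pr.is_bond and (boundary == 0 or boundary == len(radii) - 1):
            kind = BOND_BOUNDARY
        elif boundary == 0:
            kind = CORE_REFLECTION
        elif outward:
            kind = WELL_EXIT_ATTEMPT
        else:
            kind = WELL_ENTRY
        self._push(self.t + t, kind, i, j, boundary, outward)

    def _predict_walls(self, i: int) -> None:
        L = self.system.box
        if L is None:
            return
        best = math.inf
        for x, v, r in ((self.px[i], self.vx[i], self.radius[i]),
                        (self.py[i], self.vy[i], self.radius[i]),
                        (self.pz[i], self.vz[i], self.radius[i])):
            if v > 0:
                t = (L - r - x) / v
            elif v < 0:
                t = (r - x) / v
            else:
                continue
            if 0.0 <= t < best:
                best = t
        if math.isfinite(best):
            self._push(self.t + best, WALL_REFLECTION, i, -1, 0, False)

    def _schedule_particle(self, i: int) -> None:
        for idx in self.neighbors[i]:
            self._predict_pair(self.pairs[idx])
        self._predict_walls(i)

    def _schedule_all(self) -> None:
        for pr in self.pairs:
            self._predict_pair(pr)
        if self.system.box is not None:
            for i in range(self.n):
                self._predict_walls(i)

    def _schedule_ghost(self) -> None:
        rate = self.thermostat.ghost_rate * self.n
        dt = float(self.rng.exponential(1.0 / rate))
        self._seq += 1
        heapq.heappush(self.heap, (self.t + dt, self._seq, THERMOSTAT_GHOST,
                                   -1, -1, 0, False, 0, 0))

    # -- event resolution -------------------------------------------------

    def _project_to_radius(self, i: int, j: int, R: float) -> None:
        """Place the pair exactly at separation R along its current axis,
        preserving the centre of mass (floating-point drift guard)."""
        dx = self.px[i] - self.px[j]
        dy = self.py[i] - self.py[j]
        dz = self.pz[i] - self.pz[j]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            raise EngineError(f"coincident particles {i}, {j}")
        if abs(r - R) > 1e-3 * max(1.0, R):
            raise EngineError(
                f"particles {i},{j} not at discontinuity radius {R:.4f} "
                f"(r = {r:.6f})")
        mi, mj = self.mass[i], self.mass[j]
        wi = mj / (mi + mj)
        wj = mi / (mi + mj)
        scale = R / r - 1.0
        self.px[i] += wi * scale * dx
        self.py[i] += wi * scale * dy
        self.pz[i] += wi * scale * dz
        self.px[j] -= wj * scale * dx
        self.py[j] -= wj * scale * dy
        self.pz[j] -= wj * scale * dz

    def _apply_radial_impulse(self, pr: _Pair, delta_u: float,
                              force_bounce: bool = False) -> bool:
        """Change the pair's radial velocity at the current separation.

        Crossing an energy step of height ``delta_u`` keeps the tangential
        components and rescales the radial relative speed so that kinetic +
        potential energy is conserved; if the radial kinetic energy cannot
        pay ``delta_u`` (or ``force_bounce``), the radial components are
        elastically reflected.  Returns True when the step was crossed.
        """
        i, j = pr.i, pr.j
        dx = self.px[i] - self.px[j]
        dy = self.py[i] - self.py[j]
        dz = self.pz[i] - self.pz[j]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        ux, uy, uz = dx / r, dy / r, dz / r
        dvx = self.vx[i] - self.vx[j]
        dvy = self.vy[i] - self.vy[j]
        dvz = self.vz[i] - self.vz[j]
        vr = dvx * ux + dvy * uy + dvz * uz
        mu = pr.mu
        crossed = False
        if force_bounce or (delta_u > 0.0 and vr * vr < 2.0 * delta_u / mu):
            vr_new = -vr
        else:
            vr_new = math.copysign(math.sqrt(vr * vr - 2.0 * delta_u / mu), vr)
            crossed = True
        jimp = mu * (vr_new - vr)
        mi, mj = self.mass[i], self.mass[j]
        self.vx[i] += jimp / mi * ux
        self.vy[i] += jimp / mi * uy
        self.vz[i] += jimp / mi * uz
        self.vx[j] -= jimp / mj * ux
        self.vy[j] -= jimp / mj * uy
        self.vz[j] -= jimp / mj * uz
        return crossed

    def _find_pair(self, i: int, j: int) -> _Pair:
        for idx in self.neighbors[i]:
            pr = self.pairs[idx]
            if pr.i == i and pr.j == j or pr.i == j and pr.j == i:
                return pr
        raise EngineError(f"no interacting pair ({i},{j})")

    def _hbond_allowed(self, pr: _Pair) -> bool:
        i, j = pr.i, pr.j
        if (len(self.hbond_partners[i]) >= self._hb_max
                or len(self.hbond_partners[j]) >= self._hb_max):
            return False
        aux = self._hbond_aux_particle(i, j)
        if aux is None:
            return True
        d = self._distance(aux, j)
        lo, hi = self._hb_aux
        return lo <= d <= hi

    def _hbond_aux_particle(self, i: int, j: int) -> int | None:
        """Backbone neighbour of the lower-index bead, used as the auxiliary
        distance probe of the reaction geometry."""
        parts = self.system.particles
        pi = parts[i]
        for cand in range(self.n):
            pc = parts[cand]
            if (pc.chain_id == pi.chain_id and pc.role == "backbone"
                    and pc.residue_index == pi.residue_index + 1
                    and cand != j):
                return cand
        return None

    def _resolve_pair(self, pr: _Pair, boundary: int, outward: bool) -> str:
        radii = pr.radii
        R = radii[boundary]
        self._project_to_radius(pr.i, pr.j, R)
        if boundary == 0 or (pr.outer_wall and boundary == len(radii) - 1):
            self._apply_radial_impulse(pr, 0.0, force_bounce=True)
            return BOND_BOUNDARY if pr.is_bond else CORE_REFLECTION
        energies = pr.current_energies()
        target = boundary if outward else boundary - 1
        current = pr.shell
        kind = WELL_EXIT_ATTEMPT if outward else WELL_ENTRY
        # hydrogen-bond reaction at the outermost boundary of an eligible pair
        if pr.hb_eligible and boundary == len(radii) - 1:
            if not pr.hbonded and not outward and self._hbond_allowed(pr):
                # formation: switch to the bonded potential on entry
                delta_u = pr.bonded_energies[target] - energies[current]
                self._apply_radial_impulse(pr, delta_u)
                pr.hbonded = True
                self.hbond_partners[pr.i].append(pr.j)
                self.hbond_partners[pr.j].append(pr.i)
                pr.shell = target
                self.u_pot += delta_u
                return HBOND_REACTION
            if pr.hbonded and outward:
                # breaking attempt: pay the bonded well depth to escape
                delta_u = pr.energies[target] - energies[current]
                crossed = self._apply_radial_impulse(pr, delta_u)
                if crossed:
                    pr.hbonded = False
                    self.hbond_partners[pr.i].remove(pr.j)
                    self.hbond_partners[pr.j].remove(pr.i)
                    pr.shell = target
                    self.u_pot += delta_u
                    return HBOND_REACTION
                return WELL_EXIT_ATTEMPT
        delta_u = energies[target] - energies[current]
        crossed = self._apply_radial_impulse(pr, delta_u)
        if crossed:
            pr.shell = target
            self.u_pot += delta_u
        return kind

    def hbond_count(self) -> int:
        return sum(1 for pr in self.pairs if pr.hbonded)

    # -- energies ---------------------------------------------------------

    def kinetic_energy(self) -> float:
        return 0.5 * sum(m * (vx * vx + vy * vy + vz * vz)
                         for m, vx, vy, vz in zip(self.mass, self.vx,
                                                  self.vy, self.vz))

    def _potential_from_shells(self) -> float:
        return sum(pr.current_energies()[pr.shell] for pr in self.pairs)

    def total_energy(self) -> tuple[float, float]:
        """(kinetic, potential), the potential recomputed from pair shells."""
        return self.kinetic_energy(), self._potential_from_shells()

    def check_overlaps(self) -> None:
        for pr in self.pairs:
            r = self._distance(pr.i, pr.j)
            if r < pr.radii[0] - 1e-9:
                tail = list(self.event_log)
                raise EngineError(
                    f"hard-core overlap at t={self.t:.3f}: particles "
                    f"{pr.i},{pr.j} at r={r:.6f} < {pr.radii[0]:.6f}; "
                    f"recent events: {tail}")

    # -- thermostat -------------------------------------------------------

    def thermostat_kick(self, i: int) -> None:
        """Redraw particle i's velocity from Maxwell-Boltzmann at target_T."""
        T = self.thermostat.target_T
        v = maxwell_boltzmann_velocity(self.mass[i], T, self.rng)
        self.vx[i], self.vy[i], self.vz[i] = v
        self.counters[i] += 1
        self._schedule_particle(i)

    def set_temperature(self, T_new: float) -> None:
        """Swap to a new temperature, rescaling velocities by sqrt(T'/T)."""
        if T_new <= 0:
            raise ValueError("temperature must be positive")
        scale = math.sqrt(T_new / self.T)
        for i in range(self.n):
            self.vx[i] *= scale
            self.vy[i] *= scale
            self.vz[i] *= scale
            self.counters[i] += 1
        self.T = T_new
        if self.thermostat is not None:
            self.thermostat.target_T = T_new
        self.heap.clear()
        self._schedule_all()
        if self.thermostat is not None:
            self._schedule_ghost()

    # -- main loop --------------------------------------------------------

    def _execute(self, entry) -> None:
        t, _, kind, i, j, boundary, outward, ci, cj = entry
        if kind == THERMOSTAT_GHOST:
            self._advance_all(t)
            u = int(self.rng.integers(self.n))
            self.thermostat_kick(u)
            self._schedule_ghost()
            self.n_events += 1
            self.event_log.append((t, kind, u))
            return
        if self.counters[i] != ci or (j >= 0 and self.counters[j] != cj):
            return  # stale
        self._advance_all(t)
        if kind == WALL_REFLECTION:
            L = self.system.box
            r = self.radius[i]
            for attr_p, attr_v in (("px", "vx"), ("py", "vy"), ("pz", "vz")):
                x = getattr(self, attr_p)[i]
                v = getattr(self, attr_v)[i]
                if (v > 0 and x >= L - r - _GEOM_TOL) or (v < 0 and x <= r + _GEOM_TOL):
                    getattr(self, attr_v)[i] = -v
            self.counters[i] += 1
            self._schedule_particle(i)
        else:
            pr = self._find_pair(i, j)
            kind = self._resolve_pair(pr, boundary, outward)
            self.counters[i] += 1
            self.counters[j] += 1
            done = set()
            for p in (i, j):
                for idx in self.neighbors[p]:
                    if idx not in done:
                        done.add(idx)
                        self._predict_pair(self.pairs[idx])
                self._predict_walls(p)
        self.n_events += 1
        self.event_log.append((t, kind, i, j))

    def run(self, duration: float,
            sample_interval: float = 1000.0) -> Trajectory:
        """Advance the system, returning frames every ``sample_interval``.

        The trajectory includes the state at the start of the call, so the
        frame count is ``floor(duration / sample_interval) + 1``.
        """
        if duration < 0:
            raise ValueError("duration must be >= 0")
        t_end = self.t + duration
        n_frames = int(math.floor(duration / sample_interval + 1e-9)) + 1
        sample_times = [self.t + k * sample_interval for k in range(n_frames)]
        times, coords, e_pot, e_kin = [], [], [], []
        for ts in sample_times:
            while self.heap and self.heap[0][0] <= ts:
                self._execute(heapq.heappop(self.heap))
            self._advance_all(ts)
            self.check_overlaps()
            times.append(self.t)
            coords.append(np.array([self.px, self.py, self.pz]).T)
            e_pot.append(self.u_pot)
            e_kin.append(self.kinetic_energy())
        self._advance_all(t_end)
        return Trajectory(np.array(times), np.array(coords), np.array(e_pot),
                          np.array(e_kin), sample_interval, self.system)

    def run_events(self, n_events: int) -> None:
        """Advance by exactly ``n_events`` executed events (no sampling)."""
        target = self.n_events + n_events
        while self.n_events < target:
            if not self.heap:
                raise EngineError("event queue exhausted")
            self._execute(heapq.heappop(self.heap))


def maxwell_boltzmann_velocity(mass: float, T: float,
                               rng: np.random.Generator) -> tuple:
    """One velocity drawn from Maxwell-Boltzmann at temperature T (k_B = 1)."""
    if T < 0:
        raise ValueError("temperature must be >= 0")
    if T == 0:
        return (0.0, 0.0, 0.0)
    sig = math.sqrt(T / mass)
    v = rng.normal(0.0, sig, size=3)
    return (float(v[0]), float(v[1]), float(v[2]))


def resolve_pair_event(state: SimulationState, ev: Event) -> None:
    """Resolve a predicted pair event on the engine state (standalone form)."""
    pr = state._find_pair(ev.i, ev.j)
    state._resolve_pair(pr, ev.boundary, ev.outward)


def run(state: SimulationState, duration: float,
        thermostat: Thermostat | None = None,
        sample_interval: float = 1000.0) -> Trajectory:
    """Functional wrapper over :meth:`SimulationState.run`."""
    if thermostat is not None and state.thermostat is None:
        state.thermostat = thermostat
        state._schedule_ghost()
    return state.run(duration, sample_interval)


def total_energy(state: SimulationState) -> tuple[float, float]:
    return state.total_energy()
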