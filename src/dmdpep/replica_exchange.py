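"""Temperature replica exchange over the event-driven engine.

Replicas of the same system run at a ladder of temperatures; periodically,
neighbouring temperature pairs attempt a Metropolis swap of their
temperatures.  Configurations never move between replicas — only the
temperature labels do — so each replica trajectory is continuous.  Swaps
alternate between even and odd neighbour pairs each round.  On an accepted
swap the two engines' thermostat targets are exchanged and velocities are
rescaled by sqrt(T_new / T_old).

The per-temperature (demultiplexed) potential-energy samples returned by
:func:`run_rex` feed directly into WHAM (:mod:`dmdpep.thermo_analysis`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dmd_engine import SimulationState, Thermostat, Trajectory
from .peptide_model import MolecularSystem

#: The default production ladder: 8 replicas evenly spanning [0.5, 0.675].
DEFAULT_T_MIN = 0.5
DEFAULT_T_MAX = 0.675
DEFAULT_N_REPLICAS = 8
#: Target neighbour-pair exchange acceptance window.
DEFAULT_ACCEPTANCE_WINDOW = (0.3, 0.7)


@dataclass
class ReplicaLadder:
    """Temperature set with exchange schedule and acceptance counters."""

    temperatures: list[float]
    exchange_period: float = 1000.0
    attempts: list[int] = field(default_factory=list)
    accepts: list[int] = field(default_factory=list)
    tuned: bool = False
    tuning_converged: bool = True
    predicted_acceptance: list[float] | None = None

    def __post_init__(self) -> None:
        ts = self.temperatures
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("temperatures must be strictly increasing")
        if not self.attempts:
            self.attempts = [0] * (len(ts) - 1)
            self.accepts = [0] * (len(ts) - 1)

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)

    def acceptance_ratios(self) -> list[float]:
        return [a / n if n else math.nan
                for a, n in zip(self.accepts, self.attempts)]

    @classmethod
    def even(cls, t_min: float = DEFAULT_T_MIN, t_max: float = DEFAULT_T_MAX,
             n_replicas: int = DEFAULT_N_REPLICAS,
             exchange_period: float = 1000.0) -> "ReplicaLadder":
        ts = list(np.linspace(t_min, t_max, n_replicas))
        return cls(ts, exchange_period)


def exchange_probability(E_i: float, E_j: float, T_i: float, T_j: float) -> float:
    """Metropolis probability for swapping temperatures T_i < T_j between
    configurations with potential energies E_i, E_j."""
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    delta = (1.0 / T_i - 1.0 / T_j) * (E_i - E_j)
    return min(1.0, math.exp(delta)) if delta < 0 else 1.0


def propose_exchange(E_i: float, E_j: float, T_i: float, T_j: float,
                     u: float) -> bool:
    """Accept the swap iff ``u < min(1, exp[(1/T_i - 1/T_j)(E_i - E_j)])``."""
    return u < exchange_probability(E_i, E_j, T_i, T_j)


@dataclass
class RexResult:
    """Outcome of a replica-exchange run."""

    ladder: ReplicaLadder
    trajectories: list[Trajectory]  # one per replica (continuous configs)
    energy_samples: dict[float, list[float]]  # temperature -> E_pot samples
    sample_times: dict[float, list[float]]
    exchange_log: list[tuple[int, int, float, bool]]  # (round, pair, delta, ok)
    replica_temperature_history: list[list[float]]


def run_rex(system: MolecularSystem, ladder: ReplicaLadder, duration: float,
            seed: int = 0, sample_interval: float = 100.0,
            ghost_rate: float = 0.1) -> RexResult:
    """Replica-exchange run of ``duration`` time units.

    ``duration`` must be a multiple of the ladder's exchange period.  Returns
    per-replica trajectories, acceptance statistics and by-temperature
    energy samples.
    """
    period = ladder.exchange_period
    n_rounds = int(round(duration / period))
    if abs(n_rounds * period - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("duration must be a multiple of exchange_period")
    n_rep = ladder.n_replicas
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_rep + 1)
    swap_rng = np.random.default_rng(child_seeds[-1])
    engines = []
    for k in range(n_rep):
        T = ladder.temperatures[k]
        eng = SimulationState(system.copy(), T,
                              seed=child_seeds[k],
                              thermostat=Thermostat(T, ghost_rate))
        engines.append(eng)
    # replica_temp[k]: index into ladder.temperatures currently held by replica k
    replica_temp = list(range(n_rep))
    energy_samples: dict[float, list[float]] = {T: [] for T in ladder.temperatures}
    sample_times: dict[float, list[float]] = {T: [] for T in ladder.temperatures}
    trajs: list[Trajectory | None] = [None] * n_rep
    exchange_log: list[tuple[int, int, float, bool]] = []
    temp_history: list[list[float]] = []

    for rnd in range(n_rounds):
        temp_history.append([ladder.temperatures[replica_temp[k]]
                             for k in range(n_rep)])
        for k, eng in enumerate(engines):
            part = eng.run(period, sample_interval)
            T = ladder.temperatures[replica_temp[k]]
            # skip the duplicated first frame on continuation rounds
            lo = 1 if rnd > 0 else 0
            energy_samples[T].extend(part.e_pot[lo:].tolist())
            sample_times[T].extend(part.times[lo:].tolist())
            trajs[k] = part if trajs[k] is None else trajs[k].concat(
                Trajectory(part.times[1:], part.coords[1:], part.e_pot[1:],
                           part.e_kin[1:], sample_interval, part.system))
        # alternate even/odd neighbour pairs
        start = rnd % 2
        for pair in range(start, n_rep - 1, 2):
            # replicas currently holding ladder slots `pair` and `pair+1`
            k_lo = replica_temp.index(pair)
            k_hi = replica_temp.index(pair + 1)
            T_lo = ladder.temperatures[pair]
            T_hi = ladder.temperatures[pair + 1]
            _, E_lo = engines[k_lo].total_energy()
            _, E_hi = engines[k_hi].total_energy()
            u = float(swap_rng.random())
            accept = propose_exchange(E_lo, E_hi, T_lo, T_hi, u)
            ladder.attempts[pair] += 1
            delta = (1.0 / T_lo - 1.0 / T_hi) * (E_lo - E_hi)
            exchange_log.append((rnd, pair, delta, accept))
            if accept:
                ladder.accepts[pair] += 1
                replica_temp[k_lo], replica_temp[k_hi] = pair + 1, pair
                engines[k_lo].set_temperature(T_hi)
                engines[k_hi].set_temperature(T_lo)
    temp_history.append([ladder.temperatures[replica_temp[k]]
                         for k in range(n_rep)])
    return RexResult(ladder, [t for t in trajs if t is not None],
                     energy_samples, sample_times, exchange_log, temp_history)


def _predicted_acceptance(mu_i: float, sig_i: float, mu_j: float,
                          sig_j: float, T_i: float, T_j: float,
                          n_quad: int = 129) -> float:
    """Acceptance E[min(1, e^{Δβ ΔE})] for Gaussian energy distributions."""
    dbeta = 1.0 / T_i - 1.0 / T_j
    mu_d = mu_i - mu_j
    sig_d = math.hypot(sig_i, sig_j)
    if sig_d == 0.0:
        return min(1.0, math.exp(dbeta * mu_d))
    xs = np.linspace(mu_d - 8 * sig_d, mu_d + 8 * sig_d, n_quad)
    pdf = np.exp(-0.5 * ((xs - mu_d) / sig_d) ** 2) / (sig_d * math.sqrt(2 * math.pi))
    acc = np.exp(np.minimum(dbeta * xs, 0.0))  # min(1, e^{Δβ ΔE})
    return float(np.trapezoid(pdf * acc, xs))


def _engine_sampler(system: MolecularSystem, pilot_duration: float,
                    sample_interval: float, ghost_rate: float, seed_seq):
    """Default pilot sampler: a thermostatted engine run at one temperature."""

    def sampler(T: float, seed) -> np.ndarray:
        eng = SimulationState(system.copy(), T, seed=seed,
                              thermostat=Thermostat(T, ghost_rate))
        traj = eng.run(pilot_duration, sample_interval)
        half = len(traj.e_pot) // 2
        return traj.e_pot[half:]

    return sampler


def tune_ladder(system: MolecularSystem | None,
                t_min: float = DEFAULT_T_MIN,
                t_max: float = DEFAULT_T_MAX,
                n_replicas: int = DEFAULT_N_REPLICAS,
                target_window: tuple[float, float] = DEFAULT_ACCEPTANCE_WINDOW,
                pilot_duration: float = 5000.0,
                exchange_period: float = 1000.0,
                sample_interval: float = 100.0,
                ghost_rate: float = 0.1,
                seed: int = 0,
                sampler=None,
                max_iter: int = 30) -> ReplicaLadder:
    """Adjust interior ladder temperatures toward the acceptance window.

    Starting from even spacing, short pilot runs estimate the mean and
    standard deviation of the potential energy at each temperature; a
    Gaussian model predicts the neighbour-pair acceptance, and the interior
    temperatures are re-spaced (geometric interpolation on the cumulative
    -log acceptance) until every pair's predicted acceptance lies inside the
    window or the iteration cap is reached.  End temperatures stay fixed.
    """
    if not t_min < t_max:
        raise ValueError("t_min must be < t_max")
    if n_replicas < 2:
        raise ValueError("n_replicas must be >= 2")
    lo, hi = target_window
    ladder = ReplicaLadder.even(t_min, t_max, n_replicas, exchange_period)
    ss = np.random.SeedSequence(seed)
    if sampler is None:
        sampler = _engine_sampler(system, pilot_duration, sample_interval,
                                  ghost_rate, ss)
    # pilot statistics at the even ladder, interpolated in T afterwards
    pilot_T = list(ladder.temperatures)
    seeds = ss.spawn(len(pilot_T))
    mus, sigs = [], []
    for T, sd in zip(pilot_T, seeds):
        samples = np.asarray(sampler(T, sd), dtype=float)
        mus.append(float(np.mean(samples)))
        sigs.append(float(np.std(samples)))

    def stats(T: float) -> tuple[float, float]:
        return (float(np.interp(T, pilot_T, mus)),
                float(np.interp(T, pilot_T, sigs)))

    temps = list(ladder.temperatures)

    def acceptances(ts):
        acc = []
        for a, b in zip(ts, ts[1:]):
            mu_a, sig_a = stats(a)
            mu_b, sig_b = stats(b)
            acc.append(_predicted_acceptance(mu_a, sig_a, mu_b, sig_b, a, b))
        return acc

    converged = False
    acc = acceptances(temps)
    for _ in range(max_iter):
        if all(lo <= p <= hi for p in acc):
            converged = True
            break
        if n_replicas == 2:
            break  # endpoints fixed: nothing to tune
        # re-space interior temperatures on the cumulative -log acceptance
        d = [-math.log(min(max(p, 1e-12), 1.0 - 1e-12)) for p in acc]
        cum = np.concatenate([[0.0], np.cumsum(d)])
        total = cum[-1]
        targets = np.linspace(0.0, total, n_replicas)
        new_temps = np.interp(targets, cum, temps)
        # damp the update: the predicted acceptance responds nonlinearly
        new_temps = 0.5 * (np.asarray(temps) + new_temps)
        new_temps[0], new_temps[-1] = t_min, t_max
        for k in range(1, n_replicas):
            if new_temps[k] <= new_temps[k - 1]:
                new_temps[k] = new_temps[k - 1] + 1e-6
        shift = max(abs(a - b) for a, b in zip(new_temps, temps))
        temps = list(new_temps)
        acc = acceptances(temps)
        if shift < 1e-10:
            break
    if not converged and all(p >= lo for p in acc):
        # the window is unreachable from above with fixed end temperatures
        # (every pair already exceeds the upper edge): the equalized ladder
        # is the best achievable and sampling is not harmed
        converged = all(p > hi for p in acc)
    tuned = ReplicaLadder(temps, exchange_period)
    tuned.tuned = True
    tuned.tuning_converged = converged
    tuned.predicted_acceptance = acc
    return tuned
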