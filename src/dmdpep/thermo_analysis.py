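"""WHAM combination of multi-temperature samples and derived thermodynamics.

The weighted histogram analysis method (WHAM) self-consistently combines
potential-energy histograms collected at several temperatures into one
density-of-states estimate Ω(E), from which canonical averages — mean
energy, specific heat Cv(T) = (⟨E²⟩ − ⟨E⟩²)/T², and reweighted structural
observables — follow at any temperature.  k_B = 1 throughout, so reduced
temperatures carry units of kcal/mol; the conversion to Kelvin uses the
scale factor 5.03 × 10² K per reduced unit.

Transition detection locates Cv peaks and assigns each to the auxiliary
observable (inter-molecular contact count, RMSD, helix content, ...) whose
steepest temperature change lies nearest — the standard way of telling a
dissociation peak from an unfolding peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp

#: Kelvin per reduced temperature unit.
KELVIN_PER_REDUCED = 5.03e2


class WhamError(RuntimeError):
    pass


def reduced_to_kelvin(T: float | np.ndarray) -> float | np.ndarray:
    """Convert reduced temperature (kcal/mol, k_B = 1) to Kelvin."""
    if np.any(np.asarray(T) < 0):
        raise ValueError("temperature must be >= 0")
    return T * KELVIN_PER_REDUCED


def apply_burnin(samples: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Drop the leading ``fraction`` of a sample series (equilibration)."""
    samples = np.asarray(samples)
    start = int(math.floor(len(samples) * fraction))
    return samples[start:]


@dataclass
class EnergyHistogramSet:
    """Per-temperature energy histograms on one common set of bins."""

    temperatures: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray  # (n_temperatures, n_bins)
    samples: list[np.ndarray] = field(default_factory=list)

    @property
    def n_samples(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_samples(cls, samples_by_T: dict[float, np.ndarray],
                     bin_width: float | None = None,
                     max_distinct_for_discrete: int = 64) -> "EnergyHistogramSet":
        """Histogram samples on shared bins.

        The bin width defaults to the Freedman-Diaconis rule on the pooled
        samples; when the pooled energies take few distinct values (discrete
        toy models), each distinct value gets its own bin.
        """
        temps = np.array(sorted(samples_by_T))
        series = [np.asarray(samples_by_T[T], dtype=float) for T in temps]
        for T, s in zip(temps, series):
            if len(s) < 1:
                raise WhamError(f"temperature {T}: no retained samples")
        pooled = np.concatenate(series)
        distinct = np.unique(pooled)
        if bin_width is None and len(distinct) <= max_distinct_for_discrete:
            centers = distinct
            if len(distinct) > 1:
                gaps = np.diff(distinct)
                edges = np.concatenate([[distinct[0] - gaps[0] / 2],
                                        distinct[:-1] + gaps / 2,
                                        [distinct[-1] + gaps[-1] / 2]])
            else:
                edges = np.array([distinct[0] - 0.5, distinct[0] + 0.5])
        else:
            if bin_width is None:
                q75, q25 = np.percentile(pooled, [75, 25])
                iqr = q75 - q25
                bin_width = 2 * iqr / len(pooled) ** (1 / 3)
                if bin_width <= 0:
                    bin_width = max(1e-8, (pooled.max() - pooled.min()) / 50
                                    or 1e-8)
            lo = pooled.min() - bin_width / 2
            hi = pooled.max() + bin_width / 2
            n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
            edges = lo + bin_width * np.arange(n_bins + 1)
            centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.array([np.histogram(s, bins=edges)[0] for s in series],
                          dtype=float)
        return cls(temps, np.asarray(centers, dtype=float), counts,
                   samples=series)


@dataclass
class WhamSolution:
    """Converged WHAM output: free energies and density of states."""

    temperatures: np.ndarray
    f: np.ndarray  # dimensionless free energies, f[0] anchored to 0
    bin_centers: np.ndarray
    log_omega: np.ndarray  # log density of states per bin (up to a constant)
    n_samples: np.ndarray
    tolerance: float
    iterations: int
    residual: float

    @property
    def omega(self) -> np.ndarray:
        return np.exp(self.log_omega - self.log_omega.max())


def solve_wham(h: EnergyHistogramSet, tol: float = 1e-7,
               max_iter: int = 100_000) -> WhamSolution:
    """Fixed-point iteration of the WHAM equations.

    Iterates ``Ω(E) = Σ_k n_k(E) / Σ_k N_k exp(f_k − β_k E)`` and
    ``exp(−f_k) = Σ_E Ω(E) exp(−β_k E)`` until ``max |Δf_k| < tol``.
    """
    temps = h.temperatures
    betas = 1.0 / temps
    counts = h.counts
    N = h.n_samples
    total = counts.sum(axis=0)
    occupied = total > 0
    if len(temps) > 1:
        _check_overlap(h)
    log_total = np.where(occupied, np.log(np.where(occupied, total, 1.0)),
                         -np.inf)
    logN = np.log(N)
    E = h.bin_centers
    f = np.zeros(len(temps))
    residual = math.inf
    for it in range(1, max_iter + 1):
        # log Σ_k N_k exp(f_k − β_k E_m)
        log_denom = logsumexp(logN[:, None] + f[:, None]
                              - betas[:, None] * E[None, :], axis=0)
        log_omega = log_total - log_denom
        f_new = -logsumexp(log_omega[None, :] - betas[:, None] * E[None, :],
                           axis=1)
        f_new = f_new - f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            return WhamSolution(temps, f, E, log_omega, N, tol, it, residual)
    raise WhamError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(residual {residual:.3e} > tol {tol:.1e})")


def _check_overlap(h: EnergyHistogramSet) -> None:
    """Adjacent temperatures must populate at least one common bin."""
    for k in range(len(h.temperatures) - 1):
        a, b = h.counts[k] > 0, h.counts[k + 1] > 0
        if not np.any(a & b):
            lo = h.bin_centers[a].max() if a.any() else math.nan
            hi = h.bin_centers[b].min() if b.any() else math.nan
            raise WhamError(
                f"histograms at T={h.temperatures[k]:.4g} and "
                f"T={h.temperatures[k + 1]:.4g} do not overlap "
                f"(gap between E≈{lo:.4g} and E≈{hi:.4g})")


@dataclass
class ThermoCurve:
    """Cv(T) and optional reweighted observables on a temperature grid."""

    T: np.ndarray
    cv: np.ndarray
    mean_energy: np.ndarray
    observables: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def T_kelvin(self) -> np.ndarray:
        return reduced_to_kelvin(self.T)

    def to_frame(self):
        import pandas as pd

        data = {"T_reduced": self.T, "T_kelvin": self.T_kelvin,
                "Cv": self.cv, "mean_energy": self.mean_energy}
        for name, vals in self.observables.items():
            data[name] = vals
        return pd.DataFrame(data)


def _canonical_moments(w: WhamSolution, T: float) -> tuple[float, float]:
    if T <= 0:
        raise ValueError("grid temperatures must be positive")
    E = w.bin_centers
    logw = w.log_omega - E / T
    logZ = logsumexp(logw)
    p = np.exp(logw - logZ)
    e1 = float(np.dot(p, E))
    e2 = float(np.dot(p, E * E))
    return e1, e2


def specific_heat(w: WhamSolution, T_grid: np.ndarray) -> ThermoCurve:
    """Cv(T) = (⟨E²⟩ − ⟨E⟩²)/T² from the density of states."""
    T_grid = np.asarray(T_grid, dtype=float)
    cv = np.empty_like(T_grid)
    me = np.empty_like(T_grid)
    for k, T in enumerate(T_grid):
        e1, e2 = _canonical_moments(w, T)
        cv[k] = max(0.0, (e2 - e1 * e1)) / T ** 2
        me[k] = e1
    return ThermoCurve(T_grid, cv, me)


def reweight_observable(samples_by_T: dict[float, tuple[np.ndarray, np.ndarray]],
                        w: WhamSolution,
                        T_grid: np.ndarray) -> np.ndarray:
    """WHAM-weighted canonical average of an observable at each grid T.

    ``samples_by_T[T] = (E, O)``: per-sample potential energies and
    observable values from the run at temperature T (the same retained
    samples WHAM consumed).
    """
    T_grid = np.asarray(T_grid, dtype=float)
    betas_k = 1.0 / w.temperatures
    logN = np.log(w.n_samples)
    E_all, O_all = [], []
    for T in sorted(samples_by_T):
        E, O = samples_by_T[T]
        E = np.asarray(E, dtype=float)
        O = np.asarray(O, dtype=float)
        if len(E) != len(O) or np.any(~np.isfinite(O)):
            raise ValueError(f"temperature {T}: every sample needs both "
                             "an energy and an observable value")
        E_all.append(E)
        O_all.append(O)
    E_all = np.concatenate(E_all)
    O_all = np.concatenate(O_all)
    # log denominator of each sample's unbiased weight
    log_denom = logsumexp(logN[:, None] + w.f[:, None]
                          - betas_k[:, None] * E_all[None, :], axis=0)
    out = np.empty_like(T_grid)
    for k, T in enumerate(T_grid):
        logw_s = -E_all / T - log_denom
        logZ = logsumexp(logw_s)
        p = np.exp(logw_s - logZ)
        out[k] = float(np.dot(p, O_all))
    return out


def find_transitions(curve: ThermoCurve,
                     min_prominence: float | None = None) -> list[float]:
    """Temperatures of Cv local maxima above the prominence threshold.

    The default threshold is 5% of the curve's dynamic range.  An empty
    list means no cooperative transition in the scanned range.
    """
    if len(curve.T) < 5:
        raise ValueError("need at least 5 grid points")
    cv = curve.cv
    rng = float(cv.max() - cv.min())
    if rng == 0.0:
        return []
    if min_prominence is None:
        min_prominence = 0.05 * rng
    idx, _ = find_peaks(cv, prominence=min_prominence)
    return [float(curve.T[i]) for i in sorted(idx)]


def assign_transitions(peaks: list[float],
                       observable_curves: dict[str, tuple[np.ndarray, np.ndarray]],
                       flat_rtol: float = 1e-9) -> list[tuple[float, str]]:
    """Label each Cv peak with the observable changing most steeply there.

    ``observable_curves[name] = (T_grid, values)``.  For every observable the
    temperature of maximal |d⟨O⟩/dT| is found; each peak gets the label of
    the nearest such temperature.  Observables that are flat over the grid
    are excluded; with no usable observable a peak is labelled
    ``"unassigned"``.
    """
    if not observable_curves:
        raise ValueError("no observable curves provided")
    steepest: dict[str, float] = {}
    for name, (T, vals) in observable_curves.items():
        T = np.asarray(T, dtype=float)
        vals = np.asarray(vals, dtype=float)
        scale = max(abs(float(vals.max())), abs(float(vals.min())), 1.0)
        if float(vals.max() - vals.min()) <= flat_rtol * scale:
            continue  # flat: carries no transition signature
        slope = np.abs(np.gradient(vals, T))
        steepest[name] = float(T[int(np.argmax(slope))])
    labelled = []
    for p in peaks:
        if not steepest:
            labelled.append((p, "unassigned"))
            continue
        name = min(steepest, key=lambda n: abs(steepest[n] - p))
        labelled.append((p, name))
    return labelled
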