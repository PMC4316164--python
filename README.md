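# dmdpep

Coarse-grained **discrete molecular dynamics (DMD)** of peptides, with
temperature **replica exchange**, **WHAM** thermodynamics and structural
analysis (contact-frequency maps, RMSD clustering, secondary-structure
content).

## The scientific problem

Islet amyloid polypeptide (IAPP/amylin, 37 residues) aggregates in human
type-II diabetes, while the rat variant — differing at only six positions —
does not.  Studying the folding, dimerization and hetero-association of
such peptides (e.g. with insulin, whose monomer is an A-chain of 21 and a
B-chain of 30 residues) requires long equilibrium simulations of
multi-chain systems.  DMD makes that tractable: all pair interactions are
**step functions of distance**, so the dynamics consist of exact ballistic
flight between instantaneous "collisions" at the potential discontinuities
— no force integration, no timestep error.

`dmdpep` implements this methodology end to end at a two-beads-per-residue
resolution (backbone Cα bead + sidechain bead), for researchers who want a
fully inspectable, desk-scale pipeline whose every stage is validated
against analytic toy models:

* **peptide_model** — chains from sequence (ideal helix or extended start),
  hydrophobicity-scaled pair wells with a desolvation shoulder,
  Debye–Hückel screened electrostatics (λ_D = 10 Å, 30 Å cutoff),
  discretized into step potentials by shell averaging;
* **dmd_engine** — event-driven integrator (priority queue with lazy
  invalidation) conserving energy and momentum exactly per event;
  reaction-style hydrogen bonding between backbone beads; Andersen
  thermostat; reduced units with k_B = 1 (1 time unit ≡ 50 fs; multiply
  reduced temperature by 5.03 × 10² for Kelvin);
* **replica_exchange** — Metropolis temperature swaps
  p = min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]) on a ladder of 8 replicas
  spanning T = 0.5–0.675 by default, with automatic ladder tuning toward a
  0.3–0.7 acceptance window;
* **thermo_analysis** — WHAM density of states, specific heat
  C_v(T) = (⟨E²⟩ − ⟨E⟩²)/T², observable reweighting, C_v-peak detection
  and assignment to dissociation vs unfolding;
* **structure_analysis** — 5 Å any-bead contact frequencies over the
  latter half of each run, Kabsch RMSD, the low-energy-quarter →
  sliding-window → 50-cluster hierarchical clustering protocol with
  minimum-summed-RMSD centroids;
* **synthetic_data** — bundled hIAPP/rIAPP/insulin sequences, toy systems
  with closed-form thermodynamics (two-level/Schottky, tethered square-well
  dimer), and trajectories with planted contacts/clusters.

## Worked example

Replica exchange on the tethered square-well dimer (well depth
ε = 3 kcal/mol), then WHAM:

```python
import numpy as np
from dmdpep import (ToyModelSpec, make_toy_system, tune_ladder, run_rex,
                    EnergyHistogramSet, solve_wham, specific_heat,
                    find_transitions)
from dmdpep.thermo_analysis import apply_burnin

system, model = make_toy_system(ToyModelSpec(kind="square_well_dimer"))
ladder = tune_ladder(system, 0.5, 0.675, 8, target_window=(0.3, 0.7),
                     pilot_duration=5000.0, seed=1)
ladder.exchange_period = 500.0
result = run_rex(system.copy(), ladder, 200_000.0, seed=1,
                 sample_interval=20.0)
print("acceptance per neighbour pair:",
      [round(r, 2) for r in ladder.acceptance_ratios()])

by_t = {T: apply_burnin(np.asarray(s)) for T, s in result.energy_samples.items()}
sol = solve_wham(EnergyHistogramSet.from_samples(by_t))
curve = specific_heat(sol, np.linspace(0.5, 0.675, 36))
print("Cv at ladder ends: %.2f .. %.2f" % (curve.cv[0], curve.cv[-1]))
print("analytic Cv:       %.2f .. %.2f" % (model.cv(0.5), model.cv(0.675)))
```

prints (seed 1, ~7 s):

```
acceptance per neighbour pair: [1.0, 0.96, 0.99, 0.97, 0.98, 0.99, 0.99]
Cv at ladder ends: 1.42 .. 2.78
analytic Cv:       1.57 .. 2.98
```

Every neighbour-pair swap acceptance sits far above the 0.3 lower edge of
the target window (a two-particle system has tiny energy fluctuations, so
neighbouring temperatures overlap almost completely), and the WHAM specific
heat tracks the closed-form two-state fluctuation curve of the dimer to
within the sampling noise of bound/unbound dwell times.

A peptide run from the bundled fixtures, via the CLI:

```bash
dmdpep fixtures --write-fasta fixtures.fasta
dmdpep run --fasta fixtures.fasta --temperature 0.6 --duration 10000 \
           --seed 1 --outdir run1
dmdpep contacts --trajectory run1/trajectory.pdb --chains A B
```

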