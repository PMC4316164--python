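# Methods

## Model

`dmdpep` represents a peptide at two beads per residue: a backbone bead at
the Cα position (mass 56 amu — the N–Cα–C′=O united group — radius 2.0 Å)
and a sidechain bead at the approximate sidechain centroid (per-residue
mass, radius and charge from the bundled table
`src/dmdpep/data/forcefield_v1.tsv`; glycine has no sidechain bead).  This
resolution was chosen so that every part of the methodology — event-driven
integration, replica exchange, WHAM, contact/cluster analysis — can be
exercised end to end on a single CPU in minutes while keeping residue-level
structure (helicity, contacts, interfaces) meaningful.  It is deliberately
not an atomistic force field, and no claim is made that its transition
temperatures or hotspot residues match any particular experimental system;
the quantities the package validates quantitatively are the ones with
independent references (analytic toy models, protocol constants,
construction-planted structure).

### Units

Reduced units throughout: lengths in Å, energies in kcal/mol, masses in
amu, k_B = 1, so temperature carries units of kcal/mol.  One DMD time unit
is nominally 50 fs, and reduced temperatures convert to Kelvin by the scale
factor 5.03 × 10² (so T = 0.575 ≈ 290 K, T = 0.6 ≈ 300 K).  These two
constants are protocol conventions, not derived quantities.

### Interactions

All non-bonded interactions are step functions of distance, which is what
makes exact event-driven dynamics possible.

* **Bonded geometry** — infinite square wells: Cα(i)–Cα(i+1) ∈ [3.6, 4.0] Å
  (3.8 Å ± 5%), the angle-like constraint Cα(i)–Cα(i+2) ∈ [4.2, 7.61] Å
  (upper edge just admits the fully extended chain), Cα–sidechain ∈
  [2.25, 2.55] Å.  Optional disulfide cross-links are sidechain–sidechain
  wells of [3.4, 4.6] Å (bead-centroid distance of bonded cysteines).
* **Sidechain–sidechain wells** — a Gaussian well of width 1.0 Å centred
  0.5 Å outside bead contact, truncated 3 Å beyond contact, with amplitude
  −(0.2 + 1.2·h′_i·h′_j) + d_i + d_j kcal/mol, where h′ is the
  Kyte–Doolittle hydropathy rescaled to [0, 1] and d_i = 0.06·max(0, −h_i)
  is a desolvation penalty for burying polar groups.  The continuous form
  is discretized into 4 equal-width shells by **shell averaging** (each
  step energy is the radial mean of the continuous energy over its shell;
  equal-probability shells were considered and rejected for simplicity —
  convergence of the Boltzmann average is tested either way).
* **Electrostatics** — Debye–Hückel screened Coulomb
  U = 332.06·q_i q_j·e^{−r/λ_D}/(ε_r r) with λ_D = 10 Å, ε_r = 80, cut to
  exactly zero at 30 Å, applied between charged sidechain beads (D/E −1,
  K/R +1, H neutral, termini uncharged); discretized with 4 additional
  tail shells between the short-range well edge and the cutoff.
* **Hydrogen bonds** — a reaction event between backbone beads of residues
  ≥ 3 apart in sequence (any separation across chains).  When an eligible
  free pair crosses the 6.5 Å reaction radius inward and the auxiliary
  geometric condition holds (the donor's next backbone bead lies 4.5–8 Å
  from the acceptor — a bead-level proxy for donor–acceptor alignment),
  the pair switches to a bonded well of depth ε_hb = 2 kcal/mol, with the
  kinetic energy adjusted so total energy is conserved exactly; the
  mirror-image outward crossing pays ε_hb to break the bond or reflects if
  the radial kinetic energy cannot.  Each backbone bead can hold at most
  two hydrogen bonds (a helix residue donates one and accepts one).  The
  6.5 Å radius is set by the Cα(i)–Cα(i+4) distance of an ideal helix
  (≈ 6.2 Å), so helices are stabilized at the bead level.  Ordinary
  backbone pairs carry a shallow −0.1 kcal/mol well to the same radius so
  that every eligible encounter generates a reaction-check event.

## Integrator

Between events every particle moves ballistically.  Events are predicted
per interacting pair by solving the quadratic |r + vt| = R for each
boundary radius of the pair's current shell, and held in a binary heap.
Invalidation is lazy: each particle carries a collision counter, stamped
into every scheduled event; an event whose participants have collided
since scheduling is discarded on pop.  Simultaneous events are ordered by
insertion sequence, which is deterministic for a fixed seed.  At an event
the pair is first projected exactly onto the boundary radius
(mass-weighted, preserving the centre of mass) to stop floating-point
drift through discontinuities, then the radial velocity components are
rescaled to pay the energy step — or reflected when the radial kinetic
energy is insufficient or the boundary is hard (core, bond wall, box
wall).  Linear momentum is conserved identically; total energy drift is at
the 10⁻¹³ relative level over 10⁴ events in the test suite (the invariant
asserts < 10⁻⁶).

Pair prediction is all-pairs.  Cell lists with crossing events were
considered and dropped: every system this package targets is under ~200
beads, where all-pairs prediction is both simpler and faster than cell
maintenance.

An optional reflecting cubic box (`MolecularSystem.box`) keeps multi-chain
systems at finite effective concentration so dissociated chains can
re-associate; it breaks momentum conservation (by design) and is off by
default.

**Andersen thermostat**: ghost collisions arrive as a Poisson process of
rate `ghost_rate × n_particles` (default 0.1 per particle per time unit);
each collision redraws one random particle's velocity from the
Maxwell–Boltzmann distribution at the target temperature (variance T/m per
component).  The resulting velocity distribution passes a
Kolmogorov–Smirnov test against the exact normal at α = 0.01 in the suite.

## Replica exchange

Defaults follow the production protocol: 8 replicas evenly spanning
T = 0.5–0.675, exchange attempts every 10³ time units alternating
even/odd neighbour pairs, Metropolis acceptance
min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]).  Only temperature labels move:
configurations stay with their replica, thermostat targets are swapped and
velocities rescaled by √(T_new/T_old).  Energy samples are demultiplexed
by temperature for WHAM, with the first half of every series discarded as
burn-in (the same latter-half convention used for contact maps).

`tune_ladder` adjusts interior temperatures toward a target acceptance
window (0.3–0.7 by default): a pilot run per temperature estimates the
mean and standard deviation of the potential energy, a Gaussian model
predicts each neighbour-pair acceptance, and interior temperatures are
re-spaced on the cumulative −log-acceptance (with 0.5 damping, since the
prediction responds nonlinearly to spacing) until all pairs are inside the
window.  Two honest edge cases: if even spacing cannot bring every pair
*up* to the lower edge (too few replicas for the landscape), the equalized
ladder is returned with `tuning_converged = False`; if every pair sits
*above* the upper edge (tiny systems with near-total histogram overlap),
the window is unreachable from above with fixed end temperatures, the
equalized ladder is optimal, and the flag stays true — high acceptance
does not harm sampling.

## WHAM and derived thermodynamics

Standard self-consistent histogram equations, iterated in log space
(log-sum-exp throughout) until max|Δf_k| < 10⁻⁷ (cap 10⁵ iterations), with
f of the lowest temperature anchored at 0.  Bins are shared across
temperatures: Freedman–Diaconis width on the pooled samples, except that
when the pooled energies take ≤ 64 distinct values (discrete toy models)
each value gets its own bin.  Adjacent-temperature histograms must share
at least one occupied bin; a gap raises a diagnostic naming the gap edges
rather than silently diverging.

Specific heat comes from the density-of-states moments,
C_v = (⟨E²⟩ − ⟨E⟩²)/T², clamped at 0 against roundoff.  Observables are
reweighted per sample with the standard unbiased weights
w_s(T) ∝ e^{−E_s/T} / Σ_k N_k e^{f_k − E_s/T_k}.  Transition temperatures
are C_v local maxima with prominence ≥ 5% of the curve's dynamic range
(peaks in this methodology are identified visually; 5% is this package's
reproducible stand-in).  Peaks are assigned to the auxiliary observable
(inter-chain contact count, RMSD, helix content, …) whose steepest
temperature derivative lies nearest; observables flat over the grid are
excluded, and with none usable the peak is labelled "unassigned".

## Structural analysis

* **Contacts**: residues are in contact when any bead pair between them is
  within 5 Å.  At this coarse level "any heavy-atom pair" maps to "any
  bead pair" — a documented divergence from the atomistic rule.
  Frequencies average the trailing half of each run (configurable), with
  independent runs pooled at equal frame weight.  Per-residue binding
  frequency is the frame-wise union ("touches any partner residue"), not
  the matrix row maximum, and is recorded during map construction; the
  union choice is stored in the output metadata.  Homodimer maps can be
  symmetrized by transpose-averaging (chain-exchange symmetry).
* **RMSD**: Kabsch superposition via SVD with the determinant correction.
* **Clustering**: concatenate runs; keep frames with potential energy at
  or below the ¼ quantile (ties included — the minimal superset; potential
  rather than total energy, since the kinetic part is thermostat noise);
  thin with a greedy sliding window of 3500 time units per run (midpoint
  of the 3000–4000 convention); agglomerative average-linkage clustering
  of the pairwise-RMSD matrix cut at 50 clusters; report clusters in
  descending size with population fractions; each centroid is the member
  with minimum summed RMSD to its co-members, verified against brute force
  in the suite.
* **Secondary structure**: from the Cα trace only.  A residue is helical
  inside a run of ≥ 4 consecutive virtual torsions within ±40° of the
  ideal helix torsion (≈ −50° under this module's sign convention);
  failing that, strand-like inside a run of ≥ 3 near-straight virtual bond
  angles (≥ 150°, with the collinear/undefined case counted as extended);
  otherwise coil.  This is a bead-level stand-in for a hydrogen-bond
  pattern assignment such as DSSP and is validated only against
  constructed geometries.

## Synthetic data: what it does and does not show

The toy models exist to give every analysis stage an independent
reference: the **two-level system** (direct Boltzmann sampler, Schottky
closed forms for ⟨E⟩, C_v and the peak temperature), the **tethered
square-well dimer** (two-body canonical averages as one-dimensional
integrals over r²dr, cross-checked by quadrature), and the
**harmonic-like chain** (integrator stress test).  Planted trajectories
realize exact contact frequencies by construction and rigid, well-
separated conformational groups that clustering must recover exactly.

Passing these tests demonstrates that the machinery — event scheduling,
swap acceptance, histogram reweighting, selection/thinning/clustering —
is correct.  It does not demonstrate that the coarse force field
reproduces real peptide thermodynamics: real systems have rugged energy
landscapes, anisotropic interactions and solvent effects that no planted
or two-state model emulates, and the bundled parameter table is a
plausibility-level stand-in.  Conclusions about specific residues or
transition temperatures of real peptides require a validated parameter
set supplied by the user.

## Problem sizes

The test suite and acceptance script run desk-scale versions of the
production protocol: engine invariants on a 10-residue fragment (10⁴
events), replica exchange and ladder tuning on the two-particle dimer
(2 × 10⁴ time units), WHAM oracles on 10⁵–10⁶ direct samples, and the
end-to-end smoke on a two-chain 6-residue system for 10⁴ time units.
These sizes were chosen so the whole validation cycle completes in a few
minutes; all protocol defaults (2 × 10⁶ time-unit production runs, 10–20
independent repeats, 8 replicas) remain the package defaults and scale
linearly in duration.

## Known limitations

* No forces or pressure control exist (step potentials have no gradients);
  electrostatics are truncated, not Ewald-like.
* The hydrogen-bond model is geometric and environment-independent.
* The two-bead model cannot express sidechain rotamers, backbone
  carbonyl/amide geometry, or sheet register beyond contact-diagonal
  orientation.
* WHAM error bars (bootstrap) are not implemented.
* C_v is reported per system (extensive); the normalization convention is
  recorded in output metadata.
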