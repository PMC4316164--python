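"""Readers/writers for FASTA, bead-level PDB, CSV outputs and run configs."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dmd_engine import Trajectory
from .peptide_model import (AMINO_ACIDS, BACKBONE_MASS, BACKBONE_RADIUS,
                            ForceFieldParams, MolecularSystem, Particle,
                            PotentialTable, Sequence, default_forcefield)


class FormatError(ValueError):
    pass


_NAME3_TO_1 = None


def _three_to_one() -> dict[str, str]:
    global _NAME3_TO_1
    if _NAME3_TO_1 is None:
        ff = default_forcefield()
        _NAME3_TO_1 = {rp.name3: aa for aa, rp in ff.residues.items()}
    return _NAME3_TO_1


# -- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Sequence]:
    """Read sequences from FASTA, validating residue codes."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"{path}: no FASTA records found")
        return []
    out = []
    for rec in records:
        residues = str(rec.seq).upper()
        for pos, aa in enumerate(residues, start=1):
            if aa not in AMINO_ACIDS:
                raise FormatError(
                    f"{path}: record {rec.id!r}: illegal residue {aa!r} "
                    f"at position {pos}")
        out.append(Sequence(rec.id, residues))
    return out


def write_fasta(seqs: list[Sequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# -- PDB -------------------------------------------------------------------

def write_pdb(system: MolecularSystem, path: str | Path,
              trajectory: Trajectory | None = None,
              bfactors: dict[str, np.ndarray] | None = None) -> None:
    """Write a bead system (or multi-model trajectory) as fixed-column PDB.

    Backbone beads are emitted as CA atoms and sidechain beads as CB.
    ``bfactors`` maps chain id to per-residue values written (clamped to
    [0, 99.99]) into the B-factor column — used for binding-frequency
    colouring.
    """
    if bfactors is not None:
        for cid, vals in bfactors.items():
            n_res = len(system.residues_of_chain(cid))
            if len(vals) != n_res:
                raise FormatError(
                    f"chain {cid}: {len(vals)} B-factor values for "
                    f"{n_res} residues")
    ff = system.forcefield or default_forcefield()

    def atom_lines(coords, out):
        serial = 1
        for p in system.particles:
            x, y, z = coords[p.id]
            name = " CA " if p.role == "backbone" else " CB "
            res3 = ff.residue(p.residue_name).name3
            b = 0.0
            if bfactors is not None and p.chain_id in bfactors:
                res_list = system.residues_of_chain(p.chain_id)
                b = float(bfactors[p.chain_id][res_list.index(p.residue_index)])
                b = min(max(b, 0.0), 99.99)
            chain1 = p.chain_id[0]
            out.append(
                f"ATOM  {serial:5d} {name} {res3} {chain1}"
                f"{p.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
                f"          {'C':>2s}")
            serial += 1

    lines: list[str] = []
    if trajectory is None:
        atom_lines(system.coordinates(), lines)
        lines.append("END")
    else:
        for f in range(trajectory.n_frames):
            lines.append(f"MODEL     {f + 1:4d}")
            lines.append(
                f"REMARK 250 T= {trajectory.times[f]:.1f} TU  "
                f"EPOT= {trajectory.e_pot[f]:.4f}  "
                f"EKIN= {trajectory.e_kin[f]:.4f} KCAL/MOL")
            atom_lines(trajectory.coords[f], lines)
            lines.append("ENDMDL")
        lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: str | Path,
             forcefield: ForceFieldParams | None = None) -> MolecularSystem:
    """Read CA/CB atoms from a PDB file into a bead system.

    Residues missing a CA are skipped with a warning; residue-number gaps
    are reported as chain breaks.  Only the first MODEL is read.
    """
    ff = forcefield or default_forcefield()
    table = PotentialTable(ff)
    three_to_one = _three_to_one()
    path = Path(path)
    residues: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break
            if not line.startswith(("ATOM", "HETATM")):
                continue
            name = line[12:16].strip()
            if name not in ("CA", "CB"):
                continue
            res3 = line[17:20].strip()
            chain = line[21].strip() or "A"
            resi = int(line[22:26])
            xyz = np.array([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
            aa = three_to_one.get(res3)
            if aa is None:
                warnings.warn(f"{path}: unknown residue {res3} "
                              f"{chain}:{resi}, skipped")
                continue
            key = (chain, resi)
            if key not in residues:
                residues[key] = {"aa": aa}
                order.append(key)
            residues[key][name] = xyz
    particles: list[Particle] = []
    from .peptide_model import BondConstraint, CA_SC_DISTANCE

    bonds = []
    exclusions: set[frozenset] = set()
    prev: dict[str, tuple[int, int]] = {}  # chain -> (resi, ca bead id)
    for chain, resi in order:
        entry = residues[(chain, resi)]
        if "CA" not in entry:
            warnings.warn(f"{path}: residue {chain}:{resi} lacks CA, skipped")
            continue
        aa = entry["aa"]
        rp = ff.residue(aa)
        ca_id = len(particles)
        particles.append(Particle(ca_id, chain, resi, aa, "backbone",
                                  BACKBONE_MASS, BACKBONE_RADIUS, 0.0,
                                  entry["CA"], np.zeros(3)))
        sc_id = None
        if aa != "G":
            sc = entry.get("CB")
            if sc is None:
                # place the sidechain bead along the local outward direction
                sc = entry["CA"] + np.array([0.0, 0.0, CA_SC_DISTANCE])
            sc_id = len(particles)
            particles.append(Particle(sc_id, chain, resi, aa, "sidechain",
                                      rp.sc_mass, rp.sc_radius, rp.charge,
                                      sc, np.zeros(3)))
            d = float(np.linalg.norm(particles[sc_id].position
                                     - particles[ca_id].position))
            bonds.append(BondConstraint(ca_id, sc_id, max(0.5, d - 0.15),
                                        d + 0.15))
        if chain in prev:
            last_resi, last_ca = prev[chain]
            if resi == last_resi + 1:
                d = float(np.linalg.norm(particles[ca_id].position
                                         - particles[last_ca].position))
                bonds.append(BondConstraint(last_ca, ca_id, 3.6, 4.0)
                             if 3.6 <= d <= 4.0 else
                             BondConstraint(last_ca, ca_id, d - 0.2, d + 0.2))
            else:
                warnings.warn(f"{path}: chain break in {chain} between "
                              f"residues {last_resi} and {resi}")
        prev[chain] = (resi, ca_id)
    for b in bonds:
        exclusions.add(frozenset((b.i, b.j)))
    return MolecularSystem(particles, bonds, table, exclusions,
                           forcefield=ff)


# -- energy log / thermo CSV ----------------------------------------------

def write_energy_log(traj: Trajectory, path: str | Path,
                     temperature: float | None = None) -> None:
    import pandas as pd

    n = traj.system.n_particles
    t_inst = traj.e_kin / (1.5 * n)
    df = pd.DataFrame({"t_tu": traj.times, "E_pot_kcal_mol": traj.e_pot,
                       "E_kin_kcal_mol": traj.e_kin,
                       "T_inst_reduced": t_inst})
    if temperature is not None:
        df["T_set_reduced"] = temperature
    df.to_csv(path, index=False)


# -- run configuration -----------------------------------------------------

_CONFIG_KEYS = {
    "model.start_conformation": str,
    "model.n_steps": int,
    "electrostatics.debye_length": float,
    "electrostatics.cutoff": float,
    "run.temperature": float,
    "run.duration": float,
    "run.sample_interval": float,
    "run.n_independent_runs": int,
    "run.seed": int,
    "run.box": float,
    "thermostat.ghost_rate": float,
    "rex.n_replicas": int,
    "rex.t_min": float,
    "rex.t_max": float,
    "rex.exchange_period": float,
    "analysis.contact_cutoff": float,
    "analysis.window_fraction": float,
    "analysis.selection_fraction": float,
    "analysis.cluster_window": float,
    "analysis.n_clusters": int,
}


@dataclass
class RunConfig:
    """Simulation protocol settings (defaults follow the production
    protocol: 2×10⁶ time-unit runs, 10 independent repeats, sampling every
    10³ time units)."""

    start_conformation: str = "helix"
    n_steps: int = 4
    debye_length: float = 10.0
    cutoff: float = 30.0
    temperature: float = 0.6
    duration: float = 2_000_000.0
    sample_interval: float = 1000.0
    n_independent_runs: int = 10
    seed: int = 0
    box: float | None = None
    ghost_rate: float = 0.1
    n_replicas: int = 8
    t_min: float = 0.5
    t_max: float = 0.675
    exchange_period: float = 1000.0
    contact_cutoff: float = 5.0
    window_fraction: float = 0.5
    selection_fraction: float = 0.25
    cluster_window: float = 3500.0
    n_clusters: int = 50
    extras: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        parts = []
        for f in fields(self):
            if f.name == "extras":
                continue
            parts.append(f"{f.name}={getattr(self, f.name)}")
        return hashlib.md5(";".join(parts).encode()).hexdigest()[:12]

    def echo(self, path: str | Path) -> None:
        lines = [f"# dmdpep run config (hash {self.config_hash()})"]
        mapping = _key_to_attr()
        for key in sorted(_CONFIG_KEYS):
            value = getattr(self, mapping[key])
            if value is None:
                continue
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


def _key_to_attr() -> dict[str, str]:
    return {k: k.split(".", 1)[1].replace("-", "_") for k in _CONFIG_KEYS}


def parse_config(path: str | Path | None = None,
                 overrides: dict[str, str] | None = None) -> RunConfig:
    """Flat dotted-key config file, with explicit overrides on top.

    Unknown keys are rejected rather than silently defaulted.
    """
    cfg = RunConfig()
    mapping = _key_to_attr()

    def apply(key: str, raw: str, where: str) -> None:
        if key not in _CONFIG_KEYS:
            raise FormatError(f"{where}: unknown config key {key!r}")
        caster = _CONFIG_KEYS[key]
        try:
            value = caster(raw)
        except ValueError as exc:
            raise FormatError(f"{where}: bad value for {key}: {raw!r}") from exc
        setattr(cfg, mapping[key], value)

    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            apply(key, raw, f"{path}:{lineno}")
    for key, raw in (overrides or {}).items():
        apply(key, str(raw), "command line")
    return cfg
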