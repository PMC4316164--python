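"""Contact maps, RMSD, secondary structure, and conformational clustering.

Two residues are in contact when any bead pair between them is within the
cutoff distance (5 Å by default); contact frequency is the fraction of
retained frames in contact, averaged over the latter part of each run.  At
the coarse bead level "any heavy-atom pair" maps to "any bead pair" (both
backbone and sidechain beads).

The clustering protocol follows the standard low-energy-ensemble recipe:
concatenate runs, keep the lowest-energy quarter of frames, thin with a
sliding time window, agglomeratively cluster the pairwise-RMSD matrix into
k clusters (50 by default), and report each cluster's centroid — the member
with minimum summed RMSD to its co-members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .dmd_engine import Trajectory

DEFAULT_CONTACT_CUTOFF = 5.0
DEFAULT_WINDOW_FRACTION = 0.5
DEFAULT_N_CLUSTERS = 50
DEFAULT_SELECTION_FRACTION = 0.25
#: Sliding-window width for thinning consecutive similar frames, time units.
DEFAULT_WINDOW_TU = 3500.0


@dataclass
class ContactMap:
    """Residue-pair contact frequencies between two chains (or within one)."""

    chain_a: str
    chain_b: str
    residues_a: list[int]
    residues_b: list[int]
    frequency: np.ndarray  # (n_res_a, n_res_b) in [0, 1]
    cutoff: float
    window_fraction: float
    n_frames: int
    #: per-residue fraction of frames with >= 1 contact to any partner residue
    binding_a: np.ndarray | None = None
    binding_b: np.ndarray | None = None


def _chain_beads(traj: Trajectory, chain_id: str) -> tuple[np.ndarray, np.ndarray]:
    """(bead indices, residue index per bead) for one chain."""
    idx, res = [], []
    for p in traj.system.particles:
        if p.chain_id == chain_id:
            idx.append(p.id)
            res.append(p.residue_index)
    if not idx:
        raise ValueError(f"chain {chain_id!r} not present in trajectory")
    return np.array(idx), np.array(res)


def retained_frames(n_frames: int, window_fraction: float) -> np.ndarray:
    """Indices of the trailing ``window_fraction`` of a run's frames."""
    n_keep = int(round(n_frames * window_fraction))
    n_keep = max(n_keep, 0)
    return np.arange(n_frames - n_keep, n_frames)


def contact_map(trajs: Trajectory | list[Trajectory],
                chain_pair: tuple[str, str],
                d_c: float = DEFAULT_CONTACT_CUTOFF,
                window_fraction: float = DEFAULT_WINDOW_FRACTION) -> ContactMap:
    """Residue-pair contact frequency over the retained frames of each run.

    Multiple runs are pooled with equal frame weight.  For an intra-chain
    map (both chain labels equal) pairs closer than 2 in sequence are
    skipped.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    ca, cb = chain_pair
    idx_a, res_a = _chain_beads(trajs[0], ca)
    idx_b, res_b = _chain_beads(trajs[0], cb)
    ra = sorted(set(res_a.tolist()))
    rb = sorted(set(res_b.tolist()))
    pos_a = {r: k for k, r in enumerate(ra)}
    pos_b = {r: k for k, r in enumerate(rb)}
    same = ca == cb
    hits = np.zeros((len(ra), len(rb)))
    bind_a = np.zeros(len(ra))
    bind_b = np.zeros(len(rb))
    n_used = 0
    for traj in trajs:
        keep = retained_frames(traj.n_frames, window_fraction)
        if len(keep) < 2:
            raise ValueError("averaging window must contain >= 2 frames")
        for f in keep:
            xa = traj.coords[f][idx_a]
            xb = traj.coords[f][idx_b]
            d = cdist(xa, xb)
            close = d < d_c
            frame_cm = np.zeros((len(ra), len(rb)), dtype=bool)
            ia, ib = np.nonzero(close)
            for a, b in zip(ia, ib):
                i, j = pos_a[res_a[a]], pos_b[res_b[b]]
                if same and abs(ra[i] - rb[j]) < 2:
                    continue
                frame_cm[i, j] = True
            hits += frame_cm
            bind_a += frame_cm.any(axis=1)
            bind_b += frame_cm.any(axis=0)
            n_used += 1
    return ContactMap(ca, cb, ra, rb, hits / n_used, d_c, window_fraction,
                      n_used, bind_a / n_used, bind_b / n_used)


def residue_binding_frequency(cm: ContactMap, axis: int = 0) -> np.ndarray:
    """Per-residue fraction of frames in contact with ANY partner residue.

    Computed from frame data during map construction (a frame-wise union),
    so it dominates any single matrix entry of the same row/column.
    """
    if cm.chain_a == cm.chain_b:
        raise ValueError("binding frequency requires a two-chain contact map")
    freq = cm.binding_a if axis == 0 else cm.binding_b
    if freq is None:
        raise ValueError("contact map lacks per-frame binding records")
    return freq


def symmetrize_homodimer(cm: ContactMap) -> ContactMap:
    """Average a homodimer map with its transpose (exchange symmetry)."""
    if cm.frequency.shape[0] != cm.frequency.shape[1]:
        raise ValueError("homodimer symmetrization needs equal chain lengths")
    sym = 0.5 * (cm.frequency + cm.frequency.T)
    out = ContactMap(cm.chain_a, cm.chain_b, cm.residues_a, cm.residues_b,
                     sym, cm.cutoff, cm.window_fraction, cm.n_frames,
                     cm.binding_a, cm.binding_b)
    return out


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray,
                selection: np.ndarray | list[int] | None = None) -> float:
    """Minimum RMSD between two coordinate sets over rigid superpositions.

    Optimal rotation via SVD of the covariance matrix with the
    proper-rotation (determinant) correction; both sets are centred first.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if selection is not None:
        X = X[np.asarray(selection)]
        Y = Y[np.asarray(selection)]
    if X.shape != Y.shape:
        raise ValueError(f"coordinate shapes differ: {X.shape} vs {Y.shape}")
    if len(X) < 3:
        raise ValueError("need at least 3 points for superposition")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Yc - Xc @ R.T
    return float(np.sqrt((diff ** 2).sum() / len(X)))


def select_low_energy_frames(energies: np.ndarray,
                             fraction: float = DEFAULT_SELECTION_FRACTION
                             ) -> np.ndarray:
    """Frames with energy at or below the ``fraction`` quantile.

    Ties at the cutoff energy are included, so the selected fraction is the
    minimal superset of size >= fraction.
    """
    energies = np.asarray(energies, dtype=float)
    n = len(energies)
    if n == 0:
        raise ValueError("no frames to select from")
    if fraction >= 1.0:
        return np.arange(n)
    k = max(1, int(math.ceil(fraction * n)))
    cutoff = np.sort(energies)[k - 1]
    return np.nonzero(energies <= cutoff)[0]


def window_filter(times: np.ndarray, W: float = DEFAULT_WINDOW_TU,
                  run_ids: np.ndarray | None = None) -> np.ndarray:
    """Greedy thinning: keep a frame only if >= W time units after the last
    kept frame of the same run."""
    times = np.asarray(times, dtype=float)
    if run_ids is None:
        run_ids = np.zeros(len(times), dtype=int)
    run_ids = np.asarray(run_ids)
    for r in np.unique(run_ids):
        t = times[run_ids == r]
        if np.any(np.diff(t) < 0):
            raise ValueError(f"frames of run {r} are not time-sorted")
    kept = []
    last: dict[int, float] = {}
    for k, (t, r) in enumerate(zip(times, run_ids)):
        prev = last.get(int(r))
        if prev is None or t - prev >= W:
            kept.append(k)
            last[int(r)] = t
    return np.array(kept, dtype=int)


@dataclass
class ClusterSet:
    """Partition of frames into clusters with centroid representatives,
    reported in descending size order."""

    members: list[np.ndarray]  # frame ids per cluster
    centroids: list[int]  # frame id of each cluster's centroid
    fractions: np.ndarray  # population fraction per cluster
    k: int
    rmsd_matrix: np.ndarray | None = None

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])


def pairwise_rmsd_matrix(frames: np.ndarray,
                         selection=None) -> np.ndarray:
    n = len(frames)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kabsch_rmsd(frames[i], frames[j], selection)
    return D


def cluster_structures(frames: np.ndarray, k: int = DEFAULT_N_CLUSTERS,
                       linkage_method: str = "average",
                       selection=None,
                       frame_ids: np.ndarray | None = None) -> ClusterSet:
    """Agglomerative clustering of conformations on the pairwise RMSD matrix.

    The tree is cut at ``k`` clusters; each centroid is the member with the
    smallest summed RMSD to its co-members.
    """
    frames = np.asarray(frames, dtype=float)
    n = len(frames)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} frames")
    if frame_ids is None:
        frame_ids = np.arange(n)
    frame_ids = np.asarray(frame_ids)
    D = pairwise_rmsd_matrix(frames, selection)
    iu = np.triu_indices(n, 1)
    Z = linkage(D[iu], method=linkage_method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    members, centroids = [], []
    for lab in np.unique(labels):
        rows = np.nonzero(labels == lab)[0]
        sub = D[np.ix_(rows, rows)]
        centroid_local = int(np.argmin(sub.sum(axis=1)))
        members.append(frame_ids[rows])
        centroids.append(int(frame_ids[rows[centroid_local]]))
    order = np.argsort([-len(m) for m in members], kind="stable")
    members = [members[i] for i in order]
    centroids = [centroids[i] for i in order]
    sizes = np.array([len(m) for m in members])
    return ClusterSet(members, centroids, sizes / n, k=len(members),
                      rmsd_matrix=D)


def cluster_pipeline(trajs: list[Trajectory],
                     fraction: float = DEFAULT_SELECTION_FRACTION,
                     window: float = DEFAULT_WINDOW_TU,
                     k: int = DEFAULT_N_CLUSTERS,
                     linkage_method: str = "average") -> ClusterSet:
    """Low-energy selection → sliding-window thinning → clustering."""
    coords = np.concatenate([t.coords for t in trajs])
    energies = np.concatenate([t.e_pot for t in trajs])
    times = np.concatenate([t.times for t in trajs])
    run_ids = np.concatenate([np.full(t.n_frames, i)
                              for i, t in enumerate(trajs)])
    sel = select_low_energy_frames(energies, fraction)
    kept = window_filter(times[sel], window, run_ids[sel])
    ids = sel[kept]
    return cluster_structures(coords[ids], k=min(k, len(ids)),
                              linkage_method=linkage_method, frame_ids=ids)


# -- secondary structure ---------------------------------------------------

#: Virtual Cα-trace torsion band for helix, degrees: the ideal α-helix
#: trace gives τ ≈ -50° under this module's dihedral sign convention, and
#: the band spans ±40° around it.
HELIX_TORSION_BAND = (-90.0, -10.0)
#: Virtual bond-angle threshold for extended (strand-like) geometry, degrees.
STRAND_ANGLE_MIN = 150.0


def _virtual_angles(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Virtual bond angles θ_i (at each interior Cα) and torsions τ_i
    (per Cα quadruple), both in degrees; NaN where degenerate."""
    v = np.diff(ca, axis=0)
    n = len(ca)
    thetas = np.full(n, np.nan)
    for i in range(1, n - 1):
        a, b = -v[i - 1], v[i]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
        thetas[i] = math.degrees(math.acos(cosang))
    taus = np.full(max(0, n - 3), np.nan)
    for i in range(n - 3):
        b1, b2, b3 = v[i], v[i + 1], v[i + 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        x = np.dot(n1, n2)
        y = np.dot(m1, n2)
        if x == 0.0 and y == 0.0:
            continue  # collinear segment: torsion undefined
        taus[i] = math.degrees(math.atan2(y, x))
    return thetas, taus


def assign_secondary_structure(ca_coords: np.ndarray,
                               min_helix_run: int = 4,
                               min_strand_run: int = 3) -> np.ndarray:
    """Per-residue labels in {"helix", "strand", "coil"} from the Cα trace.

    A residue is helical when it lies within a run of at least
    ``min_helix_run`` consecutive virtual torsions inside the helix band;
    failing that, strand-like when inside a run of ``min_strand_run``
    near-straight virtual bond angles.  Chains shorter than 4 residues are
    all coil.  This is a bead-level stand-in for an atomistic
    hydrogen-bond-pattern assignment.
    """
    ca = np.asarray(ca_coords, dtype=float)
    n = len(ca)
    labels = np.array(["coil"] * n, dtype=object)
    if n < 4:
        return labels
    thetas, taus = _virtual_angles(ca)
    lo, hi = HELIX_TORSION_BAND
    helical = np.array([(not math.isnan(t)) and lo <= t <= hi for t in taus])
    strandish = np.array([(not math.isnan(t)) and t >= STRAND_ANGLE_MIN
                          or math.isnan(t) for t in thetas])
    # torsion i spans residues i..i+3
    run_start = None
    for i in range(len(helical) + 1):
        if i < len(helical) and helical[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_helix_run:
                labels[run_start:i + 3] = "helix"
            run_start = None
    # angle i spans residues i-1..i+1
    run_start = None
    for i in range(1, n):
        inside = i < n - 1 and strandish[i]
        if inside:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_strand_run:
                seg = labels[run_start - 1:i + 1]
                seg[seg != "helix"] = "strand"
            run_start = None
    return labels


def secondary_structure_content(labels: np.ndarray) -> dict[str, float]:
    n = len(labels)
    return {kind: float(np.sum(labels == kind)) / n
            for kind in ("helix", "strand", "coil")}
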