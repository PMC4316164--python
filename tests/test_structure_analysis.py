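import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dmdpep.peptide_model import Sequence, build_chain
from dmdpep.structure_analysis import (assign_secondary_structure,
                                       cluster_structures, contact_map,
                                       kabsch_rmsd,
                                       residue_binding_frequency,
                                       secondary_structure_content,
                                       select_low_energy_frames,
                                       symmetrize_homodimer, window_filter)
from dmdpep.synthetic_data import planted_trajectory


class TestContactMap:
    def test_permanent_contact_is_one(self):
        traj = planted_trajectory(40, {(3, 7): 1.0}, seed=1)
        cm = contact_map(traj, ("A", "B"))
        assert cm.frequency[2, 6] == 1.0

    def test_never_within_cutoff_is_zero(self):
        traj = planted_trajectory(40, {}, seed=1)
        cm = contact_map(traj, ("A", "B"))
        assert cm.frequency.max() == 0.0

    def test_alternating_contact_is_half(self):
        traj = planted_trajectory(40, {(3, 7): 0.5}, seed=1)
        cm = contact_map(traj, ("A", "B"))
        assert cm.frequency[2, 6] == pytest.approx(0.5)

    def test_rigid_body_invariance(self):
        traj = planted_trajectory(20, {(2, 2): 0.5, (5, 9): 0.25}, seed=3)
        cm1 = contact_map(traj, ("A", "B"))
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        traj.coords = traj.coords @ R.T + np.array([5.0, -3.0, 11.0])
        cm2 = contact_map(traj, ("A", "B"))
        np.testing.assert_allclose(cm1.frequency, cm2.frequency, atol=1e-12)

    def test_unknown_chain_rejected(self):
        traj = planted_trajectory(10, {}, seed=1)
        with pytest.raises(ValueError, match="chain"):
            contact_map(traj, ("A", "Z"))


class TestBindingFrequency:
    def test_union_of_alternating_partners_is_one(self):
        # residue 5 touches partner 1 on odd frames and partner 2 on even
        # frames: the any-partner union covers every frame
        n = 40
        traj = planted_trajectory(n, {}, seed=2)
        na = 10
        window = range(n // 2, n)
        for f in window:
            a = traj.coords[f][4]
            j = 0 if (f % 2) else 1
            direction = traj.coords[f][na + j] - a
            traj.coords[f][na + j] = a + direction / np.linalg.norm(direction) * 4.0
        cm = contact_map(traj, ("A", "B"))
        bf = residue_binding_frequency(cm, 0)
        assert bf[4] == pytest.approx(1.0)
        assert cm.frequency[4, 0] == pytest.approx(0.5)
        assert cm.frequency[4, 1] == pytest.approx(0.5)

    def test_union_dominates_row_maximum(self):
        traj = planted_trajectory(60, {(1, 2): 0.4, (1, 7): 0.3, (4, 4): 0.8},
                                  seed=5)
        cm = contact_map(traj, ("A", "B"))
        bf = residue_binding_frequency(cm, 0)
        for i in range(len(bf)):
            assert bf[i] >= cm.frequency[i].max() - 1e-12

    def test_single_chain_map_rejected(self):
        traj = planted_trajectory(10, {}, seed=1)
        cm = contact_map(traj, ("A", "A"))
        with pytest.raises(ValueError):
            residue_binding_frequency(cm, 0)


class TestSymmetrizeHomodimer:
    def _map_with(self, M):
        from dmdpep.structure_analysis import ContactMap

        n = M.shape[0]
        return ContactMap("A", "A'", list(range(1, n + 1)),
                          list(range(1, n + 1)), M, 5.0, 0.5, 10)

    def test_symmetric_matrix_unchanged(self):
        M = np.array([[0.2, 0.5], [0.5, 0.8]])
        out = symmetrize_homodimer(self._map_with(M))
        np.testing.assert_array_equal(out.frequency, M)

    def test_asymmetric_entries_averaged(self):
        M = np.array([[0.0, 1.0], [0.0, 0.0]])
        out = symmetrize_homodimer(self._map_with(M))
        assert out.frequency[0, 1] == 0.5
        assert out.frequency[1, 0] == 0.5

    def test_random_matrix_matches_transpose_average(self, rng):
        M = rng.random((7, 7))
        out = symmetrize_homodimer(self._map_with(M))
        np.testing.assert_allclose(out.frequency, 0.5 * (M + M.T))

    def test_unequal_chains_rejected(self):
        from dmdpep.structure_analysis import ContactMap

        cm = ContactMap("A", "B", [1, 2, 3], [1, 2], np.zeros((3, 2)),
                        5.0, 0.5, 10)
        with pytest.raises(ValueError):
            symmetrize_homodimer(cm)


class TestKabschRmsd:
    def test_identical_coordinates_zero(self, rng):
        X = rng.normal(size=(10, 3))
        assert kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        X = rng.normal(size=(12, 3))
        R = Rotation.from_euler("zyx", [0.7, -0.2, 1.9]).as_matrix()
        Y = X @ R.T + np.array([3.0, -8.0, 0.5])
        assert kabsch_rmsd(X, Y) < 1e-8

    def test_four_point_brute_force_rotation_scan(self):
        """Optimal RMSD for a small toy pair matches an exhaustive search
        over a fine grid of rotations."""
        X = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0.3, 0.4, 1.7]])
        Y = np.array([[0.1, 0, 0], [1.4, 0.2, 0], [0, 1.8, 0.3], [0.5, 0.2, 1.5]])
        got = kabsch_rmsd(X, Y)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        def rmsd_at(angles):
            R = Rotation.from_euler("zyz", angles).as_matrix()
            return math.sqrt(((Yc - Xc @ R.T) ** 2).sum() / len(X))

        best, best_angles = math.inf, None
        grid = np.linspace(0, 2 * math.pi, 40, endpoint=False)
        half = np.linspace(0, math.pi, 20)
        for a, b, c in itertools.product(grid, half, grid):
            r = rmsd_at([a, b, c])
            if r < best:
                best, best_angles = r, [a, b, c]
        from scipy.optimize import minimize

        best = minimize(rmsd_at, best_angles, method="Nelder-Mead",
                        options={"xatol": 1e-8, "fatol": 1e-12}).fun
        assert got <= best + 1e-9
        assert got == pytest.approx(best, abs=1e-3)

    def test_symmetry_in_arguments(self, rng):
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(8, 3))
        assert kabsch_rmsd(X, Y) == pytest.approx(kabsch_rmsd(Y, X), rel=1e-10)

    def test_validation(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSelectLowEnergyFrames:
    def test_quarter_of_distinct_energies(self, rng):
        energies = rng.permutation(10_000).astype(float)
        sel = select_low_energy_frames(energies, 0.25)
        assert len(sel) == 2500
        assert energies[sel].max() < np.delete(energies, sel).min()

    def test_all_equal_selects_everything(self):
        sel = select_low_energy_frames(np.zeros(100), 0.25)
        assert len(sel) == 100

    def test_fraction_one_selects_all(self, rng):
        energies = rng.normal(size=57)
        assert len(select_low_energy_frames(energies, 1.0)) == 57

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_low_energy_frames(np.array([]))


class TestWindowFilter:
    def test_every_fourth_frame_at_default_window(self):
        times = 1000.0 * np.arange(20)
        kept = window_filter(times, 3500.0)
        np.testing.assert_array_equal(kept, np.arange(0, 20, 4))

    def test_single_frame_kept(self):
        assert window_filter(np.array([500.0]), 3500.0).tolist() == [0]

    def test_zero_window_keeps_all(self):
        times = 100.0 * np.arange(10)
        assert len(window_filter(times, 0.0)) == 10

    def test_runs_filtered_independently(self):
        times = np.array([0.0, 1000.0, 0.0, 1000.0])
        runs = np.array([0, 0, 1, 1])
        kept = window_filter(times, 3500.0, runs)
        np.testing.assert_array_equal(kept, [0, 2])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            window_filter(np.array([3.0, 1.0]))


class TestClusterStructures:
    def test_n_equals_k_gives_singletons(self, rng):
        frames = rng.normal(size=(6, 5, 3)) * 10
        cs = cluster_structures(frames, k=6)
        assert sorted(len(m) for m in cs.members) == [1] * 6
        assert sorted(cs.centroids) == sorted(
            i for m in cs.members for i in m)

    def test_planted_rigid_groups_recovered_exactly(self):
        traj = planted_trajectory(60, cluster_plan=[10, 20, 30], seed=9)
        cs = cluster_structures(traj.coords, k=3)
        assert cs.sizes.tolist() == [30, 20, 10]
        groups = [set(range(0, 10)), set(range(10, 30)), set(range(30, 60))]
        for m in cs.members:
            assert set(m.tolist()) in groups
        np.testing.assert_allclose(cs.fractions, [0.5, 1 / 3, 1 / 6])

    def test_centroid_minimizes_summed_rmsd(self):
        traj = planted_trajectory(24, cluster_plan=[8, 16], seed=13)
        cs = cluster_structures(traj.coords, k=2)
        D = cs.rmsd_matrix
        for members, centroid in zip(cs.members, cs.centroids):
            sums = {i: sum(D[i, j] for j in members) for i in members}
            assert sums[centroid] == min(sums.values())

    def test_fewer_frames_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_structures(rng.normal(size=(5, 4, 3)), k=6)

    def test_pipeline_deterministic(self):
        traj = planted_trajectory(60, cluster_plan=[20, 40], seed=21)
        a = cluster_structures(traj.coords, k=2)
        b = cluster_structures(traj.coords, k=2)
        assert [m.tolist() for m in a.members] == [m.tolist() for m in b.members]
        assert a.centroids == b.centroids


class TestSecondaryStructure:
    def _ca(self, system):
        return np.array([p.position for p in system.particles
                         if p.role == "backbone"])

    def test_ideal_helix_is_mostly_helical(self, sequences):
        system = build_chain(sequences["hIAPP"], "helix")
        labels = assign_secondary_structure(self._ca(system))
        content = secondary_structure_content(labels)
        assert content["helix"] >= 0.8

    def test_fully_extended_chain_has_no_helix(self, sequences):
        system = build_chain(sequences["hIAPP"], "extended")
        labels = assign_secondary_structure(self._ca(system))
        content = secondary_structure_content(labels)
        assert content["helix"] == 0.0

    def test_half_helix_half_extended_split(self):
        helix = build_chain(Sequence("h", "A" * 20), "helix")
        ca_h = self._ca(helix)
        # extend from the helix end along +z at 3.8 Å spacing
        tail = [ca_h[-1] + np.array([0.0, 0.0, 3.8 * (i + 1)])
                for i in range(17)]
        ca = np.vstack([ca_h, tail])
        labels = assign_secondary_structure(ca)
        n_helix = int(np.sum(labels == "helix"))
        n_strand = int(np.sum(labels == "strand"))
        assert abs(n_helix - 20) <= 1
        assert abs(n_strand - 17) <= 1

    def test_short_chain_all_coil(self):
        labels = assign_secondary_structure(np.zeros((3, 3)))
        assert set(labels) == {"coil"}
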