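"""COG mapping, Kabsch superposition, symmetry RMSD, modes."""

from itertools import permutations as all_permutations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgbind.errors import SelectionError
from cgbind.events import BindingEvent
from cgbind.pose import (CGMapping, SymmetricLigand, cog_map, cyclic_group,
                         dihedral_group, find_modes, kabsch_superpose,
                         plain_rmsd, rmsd_series, symmetry_rmsd)
from cgbind.synthetic import SyntheticPoseSpec, generate_pose_set
from cgbind.trajectory import FrameSet, Selection

TRIANGLE = np.array([[1.0, 0.0, 0.0],
                     [-0.5, np.sqrt(3) / 2, 0.0],
                     [-0.5, -np.sqrt(3) / 2, 0.0]])


def hexagon(radius=0.14):
    angles = np.arange(6) * np.pi / 3
    return np.stack([radius * np.cos(angles), radius * np.sin(angles),
                     np.zeros(6)], axis=1)


class TestCogMap:
    def test_one_atom_per_bead_is_identity(self, rng):
        atoms = rng.normal(size=(5, 3))
        mapping = CGMapping(beads=[[i] for i in range(5)])
        assert np.array_equal(cog_map(atoms, mapping), atoms)

    def test_three_bead_ring_maps_to_concentric_triangle(self):
        # six ring atoms pairwise grouped into 3 beads: beads form an
        # equilateral triangle concentric with the ring
        ring = hexagon()
        mapping = CGMapping(beads=[[0, 1], [2, 3], [4, 5]])
        beads = cog_map(ring, mapping)
        assert np.allclose(beads.mean(axis=0), 0.0, atol=1e-12)
        d = np.linalg.norm(beads - np.roll(beads, 1, axis=0), axis=1)
        assert np.allclose(d, d[0])  # equilateral
        # bead radius = atom radius * cos(30 deg)
        assert np.allclose(np.linalg.norm(beads, axis=1),
                           0.14 * np.cos(np.pi / 6))

    def test_translation_equivariance(self, rng):
        atoms = rng.normal(size=(6, 3))
        mapping = CGMapping(beads=[[0, 1, 2], [3, 4, 5]])
        v = np.array([1.0, -2.0, 0.5])
        assert np.allclose(cog_map(atoms + v, mapping),
                           cog_map(atoms, mapping) + v)

    def test_empty_bead_rejected(self):
        with pytest.raises(ValueError):
            CGMapping(beads=[[0], []])

    def test_out_of_range_atom_rejected(self):
        with pytest.raises(SelectionError):
            cog_map(np.zeros((2, 3)), CGMapping(beads=[[0], [5]]))


class TestKabsch:
    def test_identity_transform(self, rng):
        x = rng.normal(size=(6, 3))
        r_mat, t, moved = kabsch_superpose(x, x)
        assert np.allclose(r_mat, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)
        assert plain_rmsd(moved, x) < 1e-9

    def test_recovers_known_rotation(self, rng):
        x = rng.normal(size=(8, 3))
        true_rot = Rotation.from_rotvec([0.3, -0.7, 1.1]).as_matrix()
        true_t = np.array([2.0, -1.0, 0.5])
        y = x @ true_rot.T + true_t
        r_mat, t, moved = kabsch_superpose(x, y)
        assert np.allclose(r_mat, true_rot, atol=1e-10)
        assert np.allclose(t, true_t, atol=1e-10)
        assert plain_rmsd(moved, y) < 1e-10

    def test_reflection_never_returned(self, rng):
        x = rng.normal(size=(7, 3))
        y = x.copy()
        y[:, 2] *= -1  # mirror image
        r_mat, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(r_mat) == pytest.approx(1.0)

    def test_optimality_against_random_rivals(self, rng):
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(5, 3))
        _, _, moved = kabsch_superpose(x, y)
        best = plain_rmsd(moved, y)
        for _ in range(50):
            rival_rot = Rotation.random(rng=rng).as_matrix()
            rival_t = rng.normal(size=3)
            rival = x @ rival_rot.T + rival_t
            assert best <= plain_rmsd(rival, y) + 1e-12

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 0.0, 0.0])
        with pytest.raises(SelectionError):
            kabsch_superpose(line, line + 1.0)


class TestSymmetryRMSD:
    def test_identical_pose_is_zero(self):
        ref = SymmetricLigand(TRIANGLE, cyclic_group(3))
        assert symmetry_rmsd(TRIANGLE, ref) == 0.0

    def test_c3_rotation_detected(self):
        # 120 deg in-plane rotation: chemically identical for a C3 ligand
        rot = Rotation.from_rotvec([0, 0, 2 * np.pi / 3]).as_matrix()
        pose = TRIANGLE @ rot.T
        ref_sym = SymmetricLigand(TRIANGLE, cyclic_group(3))
        ref_id = SymmetricLigand(TRIANGLE, [])
        assert symmetry_rmsd(pose, ref_sym) < 1e-9
        assert symmetry_rmsd(pose, ref_id) > 1.0  # Å

    def test_equals_exhaustive_minimum(self, rng):
        # group = S3: compare against a brute-force scan of every permutation
        perms = [tuple(p) for p in all_permutations(range(3))]
        ref = SymmetricLigand(TRIANGLE, perms)
        for _ in range(30):
            pose = TRIANGLE + rng.normal(scale=0.3, size=TRIANGLE.shape)
            brute = min(
                np.sqrt(np.mean(np.sum((pose - TRIANGLE[list(p)]) ** 2, axis=1)))
                for p in perms
            ) * 10.0
            assert symmetry_rmsd(pose, ref) == pytest.approx(brute, abs=1e-12)

    def test_never_exceeds_plain_rmsd(self, rng):
        ref = SymmetricLigand(TRIANGLE, cyclic_group(3))
        for _ in range(20):
            pose = TRIANGLE + rng.normal(scale=0.2, size=TRIANGLE.shape)
            assert symmetry_rmsd(pose, ref) <= plain_rmsd(pose, TRIANGLE) * 10 + 1e-12

    def test_invariant_under_group_precomposition(self, rng):
        ref = SymmetricLigand(TRIANGLE, cyclic_group(3))
        pose = TRIANGLE + rng.normal(scale=0.2, size=TRIANGLE.shape)
        base = symmetry_rmsd(pose, ref)
        for perm in ref.symmetry_permutations:
            assert symmetry_rmsd(pose[list(perm)], ref) == pytest.approx(base, abs=1e-9)

    def test_group_closure_enforced(self):
        # a single 4-cycle generates the full C4 group
        ref = SymmetricLigand(np.zeros((4, 3)), [(1, 2, 3, 0)])
        assert len(ref.symmetry_permutations) == 4

    def test_bead_count_mismatch_rejected(self):
        ref = SymmetricLigand(TRIANGLE, [])
        with pytest.raises(ValueError):
            symmetry_rmsd(np.zeros((4, 3)), ref)


class TestDihedralHelpers:
    def test_group_sizes(self):
        assert len(cyclic_group(3)) == 3
        assert len(dihedral_group(3)) == 6
        assert (0, 1, 2) in cyclic_group(3)


def make_pose_frames(poses, pocket=None):
    """FrameSet: 4 pocket beads (square) + len(reference) ligand beads."""
    n = poses.shape[0]
    pocket = pocket if pocket is not None else np.array(
        [[2.0, 0, 0], [0, 2.0, 0], [-2.0, 0, 0], [0, -2.0, 0]])
    n_beads = pocket.shape[0] + poses.shape[1]
    positions = np.empty((n, n_beads, 3))
    positions[:, : pocket.shape[0], :] = pocket
    positions[:, pocket.shape[0]:, :] = poses
    return FrameSet(times=np.arange(n) * 0.1, positions=positions + 5.0,
                    box=np.full(3, 10.0))


class TestRmsdSeries:
    pocket_sel = Selection("pocket", np.arange(4))
    ligand_sel = Selection("ligand", 4 + np.arange(3))

    def test_reference_trajectory_gives_zero(self):
        poses = np.repeat(TRIANGLE[None, :, :], 5, axis=0)
        frames = make_pose_frames(poses)
        events = [BindingEvent("replica-0", t_bind=0.0, bound_at_start=True)]
        ref = SymmetricLigand(TRIANGLE + 5.0, [])
        out = rmsd_series(frames, events, ref, self.pocket_sel, self.ligand_sel)
        assert np.allclose(out.rmsd, 0.0, atol=1e-9)

    def test_noise_expectation_and_bound_filtering(self):
        spec = SyntheticPoseSpec(reference_beads=TRIANGLE,
                                 positional_noise=0.1, n_poses=500, seed=21)
        poses = generate_pose_set(spec).poses
        frames = make_pose_frames(poses)
        # only the first half of the frames is bound
        events = [BindingEvent("replica-0", t_bind=0.0,
                               t_unbind=float(frames.times[249]),
                               bound_at_start=True)]
        ref = SymmetricLigand(TRIANGLE + 5.0, [])
        out = rmsd_series(frames, events, ref, self.pocket_sel, self.ligand_sel)
        assert out.rmsd.size == 250
        assert out.mean == pytest.approx(np.sqrt(3) * 0.1 * 10, rel=0.1)
        # the conventional filtered-pose convention is a plain threshold
        good = out.rmsd[out.rmsd < 2.6]
        assert good.size <= out.rmsd.size
        assert np.all(good < 2.6)

    def test_no_bound_frames_rejected(self):
        poses = np.repeat(TRIANGLE[None, :, :], 5, axis=0)
        frames = make_pose_frames(poses)
        events = [BindingEvent("replica-0", t_bind=100.0)]
        ref = SymmetricLigand(TRIANGLE, [])
        with pytest.raises(ValueError):
            rmsd_series(frames, events, ref, self.pocket_sel, self.ligand_sel)

    def test_summary_style(self):
        poses = np.repeat(TRIANGLE[None, :, :], 12, axis=0)
        frames = make_pose_frames(poses)
        events = [BindingEvent("replica-0", t_bind=0.0, bound_at_start=True)]
        ref = SymmetricLigand(TRIANGLE + 5.0, [])
        out = rmsd_series(frames, events, ref, self.pocket_sel, self.ligand_sel)
        assert "±" in out.summary() and out.summary().endswith("Å")


class TestFindModes:
    def test_unimodal_gaussian(self, rng):
        x = rng.normal(2.5, 0.3, size=2000)
        modes = find_modes(x, bandwidth=0.2)
        assert modes.size >= 1
        assert modes[0] == pytest.approx(2.5, abs=0.2)

    def test_three_conformational_families(self, rng):
        # mixture mimicking a multi-modal bound-pose histogram
        x = np.concatenate([
            rng.normal(2.0, 0.2, 1500),
            rng.normal(2.7, 0.2, 1000),
            rng.normal(3.6, 0.2, 800),
        ])
        modes = np.sort(find_modes(x, bandwidth=0.15))
        assert modes.size == 3
        assert np.allclose(modes, [2.0, 2.7, 3.6], atol=0.15)

    def test_degenerate_input_returns_single_value(self):
        modes = find_modes(np.full(50, 1.4), bandwidth=0.2)
        assert np.array_equal(modes, [1.4])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            find_modes(np.arange(5.0))
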