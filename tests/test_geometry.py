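"""Geometric primitives: minimum image, distances/angles, COM, Kabsch
superposition, RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from gpcrtraj.geometry import (
    DegenerateGeometryError,
    angle,
    center_of_mass,
    distance,
    kabsch_superpose,
    min_image_displacement,
    rmsf,
)
from gpcrtraj.model import Frame, Topology, Trajectory

from conftest import make_atom, rigid_transform


def frame_of(*points, box=None):
    return Frame(np.array(points, dtype=float), box=None if box is None else np.array(box))


class TestMinImage:
    def test_wraps_across_boundary(self):
        d = min_image_displacement(np.array([1.0, 0, 0]), np.array([79.0, 0, 0]),
                                   np.array([80.0, 80, 80]))
        np.testing.assert_allclose(d, [-2.0, 0, 0])

    def test_identity(self):
        a = np.array([5.0, 5, 5])
        np.testing.assert_array_equal(
            min_image_displacement(a, a, np.array([10.0, 10, 10])), np.zeros(3)
        )

    def test_no_box_is_plain_difference(self):
        d = min_image_displacement(np.zeros(3), np.array([3.0, 4, 0]))
        assert np.linalg.norm(d) == 5.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-200, 200), min_size=6, max_size=6))
    def test_antisymmetry_exact(self, vals):
        a, b = np.array(vals[:3]), np.array(vals[3:])
        box = np.array([37.0, 53.0, 71.0])
        np.testing.assert_array_equal(
            min_image_displacement(a, b, box), -min_image_displacement(b, a, box)
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_components_bounded_by_half_box(self, seed):
        rng = np.random.default_rng(seed)
        box = rng.uniform(5, 50, 3)
        a, b = rng.uniform(-100, 100, 3), rng.uniform(-100, 100, 3)
        d = min_image_displacement(a, b, box)
        assert np.all(np.abs(d) <= box / 2 + 1e-9)


class TestDistanceAngle:
    def test_unit_separation(self):
        f = frame_of([0, 0, 0], [1, 0, 0])
        assert distance(f, 0, 1) == pytest.approx(1.0)

    def test_wrapped_distance(self):
        f = frame_of([1, 0, 0], [79, 0, 0], box=[80, 80, 80])
        assert distance(f, 0, 1) == pytest.approx(2.0)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        f = Frame(rng.uniform(0, 30, (10, 3)), box=np.array([30.0, 30, 30]))
        for i, j in [(0, 5), (2, 7), (3, 3)]:
            assert distance(f, i, j) == distance(f, j, i) >= 0.0

    def test_huge_box_matches_naive_no_wrap(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(-50, 50, (200, 3))
        f = Frame(coords, box=np.array([1e6] * 3))
        pairs = rng.integers(0, 200, (1000, 2))
        for i, j in pairs:
            naive = float(np.linalg.norm(coords[j] - coords[i]))
            assert distance(f, int(i), int(j)) == pytest.approx(naive, abs=1e-9)

    def test_collinear_angle_is_180(self):
        f = frame_of([0, 0, 0], [1, 0, 0], [2, 0, 0])
        assert angle(f, 0, 1, 2) == pytest.approx(180.0)

    def test_right_angle(self):
        f = frame_of([1, 0, 0], [0, 0, 0], [0, 1, 0])
        assert angle(f, 0, 1, 2) == pytest.approx(90.0)

    def test_coincident_vertex_raises(self):
        f = frame_of([0, 0, 0], [0, 0, 0], [1, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            angle(f, 0, 1, 2)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-10, 10, (5, 3))
        f1 = Frame(coords.copy())
        f2 = Frame(rigid_transform(coords, rng))
        assert distance(f1, 0, 3) == pytest.approx(distance(f2, 0, 3), abs=1e-9)
        assert angle(f1, 0, 2, 4) == pytest.approx(angle(f2, 0, 2, 4), abs=1e-9)


class TestCenterOfMass:
    def _topo(self, masses):
        atoms = [make_atom(i, mass=m) for i, m in enumerate(masses)]
        atoms.append(make_atom(len(masses), chain="L"))
        return Topology(
            atoms=atoms,
            groups={"ligand": {len(masses)}, "receptor": set(range(len(masses)))},
        )

    def test_single_atom_is_its_position(self):
        topo = self._topo([5.0])
        f = frame_of([3, 4, 5], [0, 0, 0])
        np.testing.assert_allclose(center_of_mass(f, [0], topo), [3, 4, 5])

    def test_equal_masses_midpoint(self):
        topo = self._topo([2.0, 2.0])
        f = frame_of([0, 0, 0], [2, 0, 0], [9, 9, 9])
        np.testing.assert_allclose(center_of_mass(f, [0, 1], topo), [1, 0, 0])

    def test_mass_weighted_mean(self):
        # masses 1 and 3 at x=0 and x=4 -> weighted mean x = 3
        topo = self._topo([1.0, 3.0])
        f = frame_of([0, 0, 0], [4, 0, 0], [9, 9, 9])
        np.testing.assert_allclose(center_of_mass(f, [0, 1], topo), [3, 0, 0])

    def test_unwraps_residue_straddling_boundary(self):
        topo = self._topo([1.0, 1.0])
        f = frame_of([0.5, 0, 0], [9.5, 0, 0], [5, 5, 5], box=[10, 10, 10])
        com = center_of_mass(f, [0, 1], topo)
        # atom 1 is really at -0.5 relative to atom 0's image
        np.testing.assert_allclose(com, [0.0, 0.0, 0.0], atol=1e-12)


class TestKabsch:
    def test_identical_sets_give_identity(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (6, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, np.zeros(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (8, 3))
        r_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t_true = np.array([1.0, -2.0, 3.0])
        moved = pts @ r_true.T + t_true
        rot, trans, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, r_true.T, atol=1e-9)
        fitted = moved @ rot.T + trans
        np.testing.assert_allclose(fitted, pts, atol=1e-9)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-5, 5, (5, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_beats_random_rotation_search(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ref = rng.uniform(-5, 5, (4, 3))
            mob = ref + rng.normal(0, 0.5, ref.shape)
            _, _, rmsd = kabsch_superpose(mob, ref)
            rand = Rotation.random(10_000, random_state=12345).as_matrix()
            mob0 = mob - mob.mean(axis=0)
            ref0 = ref - ref.mean(axis=0)
            fitted = np.einsum("rij,nj->rni", rand, mob0)
            best = np.sqrt(((fitted - ref0) ** 2).sum(axis=2).mean(axis=1).min())
            assert rmsd <= best + 1e-12

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(-5, 5, (10, 3))
        mob = ref + rng.normal(0, 0.3, ref.shape)
        rot, _, rmsd = kabsch_superpose(mob, ref)
        sp_rot, sp_rssd = Rotation.align_vectors(
            ref - ref.mean(axis=0), mob - mob.mean(axis=0)
        )
        np.testing.assert_allclose(rot, sp_rot.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(sp_rssd / np.sqrt(len(ref)), abs=1e-8)

    def test_collinear_reference_raises(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line + 0.1, line)


class TestRmsf:
    def _static_traj(self, coords, n=5):
        frames = [Frame(coords.copy(), time=float(t)) for t in range(n)]
        return Trajectory(frames=frames)

    def _topo(self, n):
        atoms = [make_atom(i, residue_index=i + 1) for i in range(n)]
        atoms.append(make_atom(n, chain="L"))
        return Topology(
            atoms=atoms, groups={"ligand": {n}, "receptor": set(range(n))}
        )

    def test_static_trajectory_gives_zero(self):
        rng = np.random.default_rng(0)
        coords = np.vstack([rng.uniform(-5, 5, (8, 3)), [[50, 50, 50]]])
        topo = self._topo(8)
        res = rmsf(self._static_traj(coords), topo, list(range(8)), list(range(8)))
        assert all(abs(v) < 1e-12 for v in res.per_residue_rmsf.values())
        assert res.selection_sum == pytest.approx(0.0, abs=1e-12)

    def test_planted_gaussian_noise_recovers_sigma_sqrt3(self):
        # rigid 10-atom alignment scaffold + 5 noisy atoms, sigma = 0.1 A
        rng = np.random.default_rng(1)
        base = np.vstack([rng.uniform(-10, 10, (15, 3)), [[50, 50, 50]]])
        sigma = 0.10
        frames = []
        for t in range(8000):
            c = base.copy()
            c[10:15] += rng.normal(0, sigma, (5, 3))
            frames.append(Frame(c, time=float(t)))
        topo = self._topo(15)
        res = rmsf(Trajectory(frames=frames), topo, list(range(10, 15)),
                   list(range(10)))
        expected = sigma * np.sqrt(3)
        for v in res.per_residue_rmsf.values():
            assert v == pytest.approx(expected, rel=0.05)

    def test_selection_sum_is_additive(self):
        rng = np.random.default_rng(2)
        base = np.vstack([rng.uniform(-10, 10, (10, 3)), [[50, 50, 50]]])
        frames = [Frame(base + rng.normal(0, 0.1, base.shape), time=float(t))
                  for t in range(200)]
        topo = self._topo(10)
        traj = Trajectory(frames=frames)
        r_half = rmsf(traj, topo, [5, 6], list(range(5)))
        r_full = rmsf(traj, topo, [5, 6, 5, 6], list(range(5)))
        assert r_full.selection_sum == pytest.approx(2 * r_half.selection_sum)

    def test_invariant_under_uniform_rigid_transform(self):
        rng = np.random.default_rng(3)
        base = np.vstack([rng.uniform(-10, 10, (10, 3)), [[50, 50, 50]]])
        frames = [Frame(base + rng.normal(0, 0.2, base.shape), time=float(t))
                  for t in range(50)]
        topo = self._topo(10)
        sel, align = [7, 8, 9], list(range(7))
        r1 = rmsf(Trajectory(frames=frames), topo, sel, align)
        q = Rotation.from_euler("xyz", [30, -60, 110], degrees=True).as_matrix()
        moved = [Frame(f.coordinates @ q.T + np.array([5.0, -3, 8]), time=f.time)
                 for f in frames]
        r2 = rmsf(Trajectory(frames=moved), topo, sel, align)
        for rid in r1.per_residue_rmsf:
            assert r1.per_residue_rmsf[rid] == pytest.approx(
                r2.per_residue_rmsf[rid], abs=1e-6
            )

    def test_fewer_than_two_frames_rejected(self):
        coords = np.random.default_rng(0).uniform(-5, 5, (11, 3))
        topo = self._topo(10)
        traj = self._static_traj(coords, n=1)
        with pytest.raises(ValueError, match="2"):
            rmsf(traj, topo, [0], list(range(10)))
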