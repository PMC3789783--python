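"""Geometric observables against independent oracles and constructions."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gpcrtraj.bw_numbering import HelixDefinition
from gpcrtraj.geometry import (
    ChiDefinitionError,
    GeometryError,
    InsufficientDataError,
    chi_series,
    dihedral,
    end_distance_series,
    fit_helix_axis,
    kink_series,
    rmsd_series,
    superpose,
)
from gpcrtraj.synthetic_data import (
    HelixPlacement,
    KinkSchedule,
    SyntheticSpec,
    build_bundle,
    nerf,
)

from conftest import make_trajectory


def oracle_dihedral(p1, p2, p3, p4):
    """Independent two-normal atan2 formulation (IUPAC sign)."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(y, np.dot(n1, n2)))


class TestDihedral:
    def test_planar_cis_is_zero(self):
        p = np.array([[1.0, 1.0, 0], [0, 0, 0], [2, 0, 0], [3, 1, 0]])
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        p = np.array([[1.0, 1.0, 0], [0, 0, 0], [2, 0, 0], [3, -1, 0]])
        assert dihedral(*p) == pytest.approx(180.0, abs=1e-9)

    def test_matches_oracle_on_100_random_quadruples(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3
            got = dihedral(*pts)
            want = oracle_dihedral(*pts)
            # both in (-180, 180]; compare circularly
            assert abs((got - want + 180) % 360 - 180) < 1e-9

    def test_rigid_motion_invariance_and_mirror_negation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3))
        base = dihedral(*pts)
        rot = Rotation.random(random_state=7).as_matrix()
        moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
        assert dihedral(*moved) == pytest.approx(base, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-base, abs=1e-9)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0])
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])


class TestChiSeries:
    @staticmethod
    def _trp_frame(chi1=-60.0, chi2=90.0):
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([1.46, 0.0, 0.0])
        cb = nerf(np.array([2.0, 1.2, 0.3]), n, ca, 1.53, 110.5, -122.0)
        cg = nerf(n, ca, cb, 1.52, 114.0, chi1)
        cd1 = nerf(ca, cb, cg, 1.37, 127.0, chi2)
        return np.array([n, ca, cb, cg, cd1])

    ATOMS = [
        ("N", "TRP", 269, "A", "N"),
        ("CA", "TRP", 269, "A", "C"),
        ("CB", "TRP", 269, "A", "C"),
        ("CG", "TRP", 269, "A", "C"),
        ("CD1", "TRP", 269, "A", "C"),
    ]

    def test_constructed_chi2_is_exact(self):
        traj = make_trajectory(self.ATOMS, self._trp_frame(chi2=90.0))
        series = chi_series(traj, 269, "chi2")
        assert series.values[0] == pytest.approx(90.0, abs=1e-6)

    def test_constant_coordinates_give_constant_series(self):
        frame = self._trp_frame()
        traj = make_trajectory(self.ATOMS, np.repeat(frame[None], 5, axis=0))
        series = chi_series(traj, 269, "chi1")
        assert np.ptp(series.values) == pytest.approx(0.0, abs=1e-12)

    def test_glycine_chi1_rejected(self):
        atoms = [("N", "GLY", 5, "A", "N"), ("CA", "GLY", 5, "A", "C")]
        traj = make_trajectory(atoms, np.array([[0.0, 0, 0], [1.46, 0, 0]]))
        with pytest.raises(ChiDefinitionError):
            chi_series(traj, 5, "chi1")

    def test_missing_atom_rejected_not_skipped(self):
        traj = make_trajectory(self.ATOMS[:4], self._trp_frame()[:4])
        with pytest.raises(ChiDefinitionError):
            chi_series(traj, 269, "chi2")


def ideal_helix(n, rise=1.5, twist=100.0, radius=2.3, phase=0.0):
    k = np.arange(n)
    th = np.radians(k * twist + phase)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th), k * rise])


class TestHelixAxis:
    def test_ideal_helix_along_z(self):
        d, _ = fit_helix_axis(ideal_helix(7, phase=33.0))
        assert np.degrees(np.arccos(abs(d[2]))) < 1.0

    def test_rotated_helix_tracks_rotation(self):
        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        d, _ = fit_helix_axis(ideal_helix(9) @ rot.T)
        want = rot @ np.array([0.0, 0.0, 1.0])
        assert np.degrees(np.arccos(abs(np.dot(d, want)))) < 1.0

    def test_too_few_residues(self):
        with pytest.raises(InsufficientDataError):
            fit_helix_axis(ideal_helix(3))


TM7 = HelixDefinition(7, 291, 315, 308, 50, "end")


def _kinked_bundle(kink_deg=None, n_frames=1):
    spec = SyntheticSpec(
        n_frames=n_frames,
        seed=11,
        helices=(HelixPlacement(TM7, 0.0),),
        residue_names={308: "PRO"},
        noise_sigma=0.0,
        kink_schedules=(
            (KinkSchedule(7, 308, ((0, float(kink_deg)),)),) if kink_deg else ()
        ),
    )
    traj, _ = build_bundle(spec)
    return traj


class TestKink:
    def test_straight_helix_reads_180(self):
        traj = _kinked_bundle(None)
        ks = kink_series(traj, TM7, 308, window=7)
        assert ks.values[0] == pytest.approx(180.0, abs=2.0)

    @pytest.mark.parametrize("target", [130.0, 155.0])
    def test_constructed_arm_rotation(self, target):
        # a rigid rotation of the post-pivot arm by (180 - target) degrees
        traj = _kinked_bundle(target)
        ks = kink_series(traj, TM7, 308, window=7)
        assert ks.values[0] == pytest.approx(target, abs=2.0)

    def test_monotone_in_bend(self):
        readings = [
            kink_series(_kinked_bundle(k), TM7, 308, window=7).values[0]
            for k in (180.0, 160.0, 140.0, 120.0, 100.0)
        ]
        assert all(a > b for a, b in zip(readings, readings[1:]))

    def test_arm_outside_helix_range(self):
        traj = _kinked_bundle(None)
        with pytest.raises(InsufficientDataError):
            kink_series(traj, TM7, 310, window=7)  # C-arm would end at 317


class TestSuperpose:
    def test_self_superposition_zero(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        _, _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot = Rotation.random(random_state=5).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -1.0, 2.0])
        _, _, rmsd = superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_transform_maps_mobile_onto_ref(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(5, 3))
        mobile = rng.normal(size=(5, 3))
        rot, trans, rmsd = superpose(ref, mobile)
        moved = mobile @ rot.T + trans
        direct = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
        assert direct == pytest.approx(rmsd, abs=1e-9)

    def test_matches_brute_force_minimization(self):
        # independent oracle: numerically minimize RMSD over rotation vectors
        rng = np.random.default_rng(9)
        for _ in range(5):
            ref = rng.normal(size=(4, 3)) * 2
            mob = rng.normal(size=(4, 3)) * 2
            _, _, rmsd = superpose(ref, mob)
            rc = ref - ref.mean(0)
            mc = mob - mob.mean(0)

            def cost(v):
                r = Rotation.from_rotvec(v).as_matrix()
                return np.sqrt(np.mean(np.sum((mc @ r.T - rc) ** 2, axis=1)))

            best = min(
                minimize(cost, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-14}).fun
                for x0 in rng.normal(size=(12, 3))
            )
            assert rmsd == pytest.approx(best, abs=1e-6)

    def test_matches_kabsch_library_on_100_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            ref = rng.normal(size=(6, 3))
            mob = rng.normal(size=(6, 3))
            _, _, rmsd = superpose(ref, mob)
            _, rssd = Rotation.align_vectors(
                ref - ref.mean(0), mob - mob.mean(0)
            )
            assert rmsd == pytest.approx(rssd / np.sqrt(len(ref)), abs=1e-6)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(GeometryError):
            superpose(line, line + 1.0)


class TestRmsdSeries:
    ATOMS = [
        ("N", "GLY", 1, "A", "N"), ("CA", "GLY", 1, "A", "C"),
        ("C", "GLY", 1, "A", "C"), ("O", "GLY", 1, "A", "O"),
        ("N", "GLY", 2, "A", "N"), ("CA", "GLY", 2, "A", "C"),
        ("C", "GLY", 2, "A", "C"), ("O", "GLY", 2, "A", "O"),
    ]

    def _base(self):
        return np.random.default_rng(4).normal(size=(8, 3)) * 3

    def test_constant_trajectory_all_zero(self):
        frame = self._base()
        traj = make_trajectory(self.ATOMS, np.repeat(frame[None], 4, axis=0))
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-9)

    def test_per_frame_rigid_motion_all_zero(self):
        frame = self._base()
        frames = []
        for i in range(5):
            rot = Rotation.random(random_state=i).as_matrix()
            frames.append(frame @ rot.T + i * np.array([1.0, 0.5, -0.2]))
        traj = make_trajectory(self.ATOMS, np.array(frames))
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-6)

    def test_matches_per_frame_formula_oracle(self):
        rng = np.random.default_rng(6)
        frame = self._base()
        frames = frame[None] + rng.normal(0, 0.5, size=(6, 8, 3))
        frames[0] = frame
        traj = make_trajectory(self.ATOMS, frames)
        got = rmsd_series(traj)
        ref = frame - frame.mean(0)
        for f in range(6):
            mob = frames[f] - frames[f].mean(0)
            _, rssd = Rotation.align_vectors(ref, mob)
            assert got[f] == pytest.approx(rssd / np.sqrt(8), abs=1e-9)


class TestEndDistances:
    @staticmethod
    def _three_helices(offset7=(5.0, 8.0)):
        atoms, coords = [], []
        for res0, x, y in ((1, 0.0, 0.0), (101, 10.0, 0.0),
                           (201, offset7[0], offset7[1])):
            for i in range(8):
                atoms.append(("CA", "GLY", res0 + i, "A", "C"))
                coords.append([x, y, float(i) * 1.5])
        h3 = HelixDefinition(3, 1, 8, 4, 50, "end")
        h6 = HelixDefinition(6, 101, 108, 104, 50, "end")
        h7 = HelixDefinition(7, 201, 208, 204, 50, "end")
        return make_trajectory(atoms, np.array(coords)), h3, h6, h7

    def test_parallel_helices_at_10_angstrom(self):
        traj, h3, h6, h7 = self._three_helices()
        ed = end_distance_series(traj, h3, h6, h7, end_length=4)
        assert ed.values[0][1] == pytest.approx(10.0, abs=1e-6)  # TM3-TM6

    def test_end_length_one_is_single_calpha_distance(self):
        traj, h3, h6, h7 = self._three_helices()
        ed = end_distance_series(traj, h3, h6, h7, end_length=1)
        assert ed.values[0][1] == pytest.approx(10.0, abs=1e-6)

    def test_random_configuration_matches_direct_centroids(self):
        rng = np.random.default_rng(8)
        traj, h3, h6, h7 = self._three_helices()
        coords = rng.normal(size=traj.coordinates.shape) * 5
        traj.coordinates = coords
        ed = end_distance_series(traj, h3, h6, h7, end_length=4)
        # oracle: last four residues of each helix are atoms 4:8 per block
        c3 = coords[0, 4:8].mean(0)
        c6 = coords[0, 12:16].mean(0)
        c7 = coords[0, 20:24].mean(0)
        want = [np.linalg.norm(c7 - c3), np.linalg.norm(c3 - c6),
                np.linalg.norm(c6 - c7)]
        np.testing.assert_allclose(ed.values[0], want, atol=1e-9)

    def test_excessive_end_length(self):
        traj, h3, h6, h7 = self._three_helices()
        with pytest.raises(Exception):
            end_distance_series(traj, h3, h6, h7, end_length=9)


def test_observables_invariant_under_global_rigid_motion():
    spec = SyntheticSpec(
        n_frames=4, seed=13,
        helices=(HelixPlacement(TM7, 0.0),),
        residue_names={308: "PRO"},
        noise_sigma=0.1,
        kink_schedules=(KinkSchedule(7, 308, ((0, 150.0), (3, 140.0))),),
    )
    traj, _ = build_bundle(spec)
    base_kink = kink_series(traj, TM7, 308, 7).values
    base_rmsd = rmsd_series(traj)
    rot = Rotation.random(random_state=21).as_matrix()
    traj.coordinates = traj.coordinates @ rot.T + np.array([5.0, -3.0, 1.0])
    np.testing.assert_allclose(kink_series(traj, TM7, 308, 7).values, base_kink, atol=1e-8)
    np.testing.assert_allclose(rmsd_series(traj), base_rmsd, atol=1e-8)
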