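"""Rotamer binning, switch events, hydrogen bonds and ligand contacts."""

import numpy as np
import pytest

from gpcrtraj.geometry import DihedralSeries
from gpcrtraj.switch_analysis import (
    BinDefinitionError,
    DEFAULT_CHI_BINS,
    TOGGLE_BINS,
    RotamerBins,
    classify_rotamers,
    contact_occupancy,
    detect_switches,
    hbond_series,
)
from gpcrtraj.trajectory_io import SelectionError

from conftest import make_trajectory


def series(values, residue=98, angle="chi1"):
    values = np.asarray(values, dtype=float)
    return DihedralSeries(residue, angle, values, np.arange(values.size, dtype=float))


class TestBins:
    def test_overlapping_bins_rejected(self):
        with pytest.raises(BinDefinitionError):
            RotamerBins((("a", -180.0, 10.0), ("b", 0.0, 180.0)))

    def test_gap_rejected(self):
        with pytest.raises(BinDefinitionError):
            RotamerBins((("a", -180.0, 0.0), ("b", 10.0, 180.0)))

    def test_wrapping_trans_bin(self):
        labels = DEFAULT_CHI_BINS.classify(np.array([179.9, -179.9, 150.0, -150.0]))
        assert set(labels) == {"t"}


class TestClassify:
    def test_constant_gauche_minus(self):
        states = classify_rotamers(series(np.full(100, -60.0)))
        assert set(states.labels) == {"g-"}

    def test_wraparound_continuity(self):
        states = classify_rotamers(series(np.array([179.9, -179.9] * 30)), filter_window=1)
        assert set(states.labels) == {"t"}

    def test_planted_two_state_schedule_recovered_outside_filter_window(self):
        rng = np.random.default_rng(5)
        truth = np.where(np.arange(400) < 180, 0.0, 90.0)
        noisy = truth + rng.normal(0, 10.0, 400)
        states = classify_rotamers(series(noisy), bins=TOGGLE_BINS, filter_window=21)
        want = np.where(truth == 0.0, "horizontal", "vertical")
        inner = np.ones(400, dtype=bool)
        inner[180 - 11:180 + 11] = False  # filter half-window around transition
        assert (states.labels[inner] == want[inner]).all()


class TestDetectSwitches:
    def test_constant_series_no_events(self):
        states = classify_rotamers(series(np.full(300, -60.0)))
        assert detect_switches(states, min_dwell=50) == []

    def test_clean_step_single_event_at_step_frame(self):
        vals = np.where(np.arange(700) < 500, -60.0, 170.0)
        states = classify_rotamers(series(vals), filter_window=1)
        events = detect_switches(states, min_dwell=50)
        assert len(events) == 1
        assert events[0].frame_index == 500
        assert (events[0].from_state, events[0].to_state) == ("g-", "t")
        assert events[0].post_dwell == 200

    def test_short_excursion_ignored(self):
        vals = np.full(300, -60.0)
        vals[100:110] = 170.0  # 10-frame excursion
        states = classify_rotamers(series(vals), filter_window=1)
        assert detect_switches(states, min_dwell=50) == []

    def test_event_count_invariant_to_prepended_initial_state(self):
        vals = np.where(np.arange(400) < 200, -60.0, 170.0)
        states = classify_rotamers(series(vals), filter_window=1)
        padded = classify_rotamers(series(np.r_[np.full(150, -60.0), vals]),
                                   filter_window=1)
        assert len(detect_switches(states, 50)) == len(detect_switches(padded, 50)) == 1

    def test_back_and_forth_counts_two_events(self):
        vals = np.r_[np.full(100, -60.0), np.full(100, 170.0), np.full(100, -60.0)]
        states = classify_rotamers(series(vals), filter_window=1)
        events = detect_switches(states, min_dwell=50)
        assert [(e.from_state, e.to_state) for e in events] == [("g-", "t"), ("t", "g-")]


class TestHBond:
    # serine hydroxyl donating to a backbone carbonyl; explicit hydrogen
    @staticmethod
    def _micro(d_a: float, angle_deg: float):
        og = np.array([0.0, 0.0, 0.0])
        # hydrogen 0.96 A from donor; acceptor placed to set the D-H...A angle
        hg = og + np.array([0.96, 0.0, 0.0])
        theta = np.radians(180.0 - angle_deg)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        # choose acceptor along `direction` from H such that |D-A| = d_a
        # solve |hg + t*direction - og| = d_a for t > 0
        b = 2 * np.dot(hg, direction)
        c = np.dot(hg, hg) - d_a**2
        t = (-b + np.sqrt(b * b - 4 * c)) / 2
        o_acc = hg + t * direction
        atoms = [
            ("OG", "SER", 304, "A", "O"),
            ("HG", "SER", 304, "A", "H"),
            ("O", "TYR", 98, "A", "O"),
        ]
        return make_trajectory(atoms, np.array([og, hg, o_acc]))

    def test_good_geometry_present(self):
        traj = self._micro(2.8, 170.0)
        hs = hbond_series(traj, donor=(304, "OG"), acceptor=(98, "O"))
        assert hs.present[0] and not hs.heavy_only
        assert hs.occupancy == 1.0

    def test_long_distance_absent(self):
        traj = self._micro(4.0, 170.0)
        assert not hbond_series(traj, (304, "OG"), (98, "O")).present[0]

    def test_bent_angle_absent(self):
        traj = self._micro(2.8, 120.0)
        assert not hbond_series(traj, (304, "OG"), (98, "O")).present[0]

    def test_heavy_only_fallback_flagged(self):
        atoms = [("OG", "SER", 304, "A", "O"), ("O", "TYR", 98, "A", "O")]
        traj = make_trajectory(atoms, np.array([[0.0, 0, 0], [2.8, 0, 0]]))
        hs = hbond_series(traj, (304, "OG"), (98, "O"))
        assert hs.heavy_only and hs.present[0]

    def test_missing_atom_is_selection_error(self):
        traj = self._micro(2.8, 170.0)
        with pytest.raises(SelectionError):
            hbond_series(traj, (304, "OD1"), (98, "O"))


class TestContacts:
    ATOMS = [
        ("C1", "LIG", 900, "L", "C"),
        ("CA", "GLY", 1, "A", "C"),
        ("CA", "GLY", 2, "A", "C"),
        ("CA", "GLY", 3, "A", "C"),
    ]

    def test_single_residue_in_contact(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [8.0, 0, 0], [12.0, 0, 0]])
        traj = make_trajectory(self.ATOMS, coords)
        table = contact_occupancy(traj, "resname LIG", cutoff=4.0)
        assert table.occupancy == {1: 1.0, 2: 0.0, 3: 0.0}
        assert table.snapshots[0] == [1]

    def test_zero_cutoff_no_contacts(self):
        coords = np.zeros((4, 3))
        traj = make_trajectory(self.ATOMS, coords)
        table = contact_occupancy(traj, "resname LIG", cutoff=0.0)
        assert all(v == 0.0 for v in table.occupancy.values())

    def test_empty_ligand_selection_rejected(self):
        traj = make_trajectory(self.ATOMS, np.zeros((4, 3)))
        with pytest.raises(SelectionError):
            contact_occupancy(traj, "resname NOPE")

    def test_random_geometry_matches_brute_force(self):
        rng = np.random.default_rng(11)
        atoms = [("C1", "LIG", 900, "L", "C"), ("C2", "LIG", 900, "L", "C")]
        for r in range(1, 9):
            atoms += [("CA", "GLY", r, "A", "C"), ("CB", "GLY", r, "A", "C")]
        coords = rng.uniform(-8, 8, size=(3, len(atoms), 3))
        traj = make_trajectory(atoms, coords)
        table = contact_occupancy(traj, "resname LIG", cutoff=5.0)
        # brute force over every frame / residue / atom pair
        lig = coords[:, :2, :]
        for r in range(1, 9):
            res = coords[:, 2 * r : 2 * r + 2, :]
            hits = 0
            for f in range(3):
                d = np.linalg.norm(lig[f][:, None] - res[f][None], axis=2)
                hits += bool((d <= 5.0).any())
            assert table.occupancy[r] == pytest.approx(hits / 3)

    def test_occupancy_frame_permutation_invariant(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(-6, 6, size=(8, 4, 3))
        traj = make_trajectory(self.ATOMS, coords)
        base = contact_occupancy(traj, "resname LIG", cutoff=5.0).occupancy
        perm = rng.permutation(8)
        traj2 = make_trajectory(self.ATOMS, coords[perm])
        assert contact_occupancy(traj2, "resname LIG", cutoff=5.0).occupancy == base
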