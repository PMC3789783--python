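"""PDB reading/writing and the selection grammar."""

import numpy as np
import pytest

from gpcrtraj.synthetic_data import build_bundle, fixture_specs
from gpcrtraj.trajectory_io import (
    ConsistencyError,
    FormatError,
    SelectionError,
    read_structure,
    read_trajectory,
    select_atoms,
    write_trajectory,
)

PDB_TEN_ATOMS = """\
ATOM      1  N   ASP A  91      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP A  91      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ASP A  91      12.821   7.012  -4.989  1.00  0.00           C
ATOM      4  O   ASP A  91      13.421   7.441  -5.975  1.00  0.00           O
ATOM      5  CB  ASP A  91      12.042   4.631  -4.829  1.00  0.00           C
ATOM      6  CG  ASP A  91      10.931   3.635  -5.106  1.00  0.00           C
ATOM      7  OD1 ASP A  91       9.791   3.879  -4.662  1.00  0.00           O
ATOM      8  OD2 ASP A  91      11.201   2.598  -5.750  1.00  0.00           O
ATOM      9  N   GLY A  92      13.150   7.332  -3.740  1.00  0.00           N
ATOM     10  CA  GLY A  92      14.256   8.232  -3.430  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  N   SER A  10       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A  10       1.400   0.000   0.000  0.50  0.00           C
ATOM      3  CA BSER A  10       1.500   0.100   0.000  0.50  0.00           C
ATOM      4  CB ASER A  10       2.000   1.400   0.000  0.50  0.00           C
ATOM      5  CB BSER A  10       2.100   1.500   0.000  0.50  0.00           C
ATOM      6  OG  SER A  10       3.300   1.400   0.500  1.00  0.00           O
END
"""


def test_identity_read(tmp_path):
    path = tmp_path / "ten.pdb"
    path.write_text(PDB_TEN_ATOMS)
    topo, coords = read_structure(path)
    assert topo.n_atoms == 10
    assert [a.serial for a in topo.atoms] == list(range(1, 11))
    assert [a.name for a in topo.atoms][:5] == ["N", "CA", "C", "O", "CB"]
    assert topo.atoms[0].residue_name == "ASP"
    assert topo.atoms[0].residue_seq == 91
    np.testing.assert_allclose(coords[0], [11.104, 6.134, -6.504])


def test_altloc_b_dropped(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(PDB_ALTLOC)
    # expected count computed from the raw text: altloc in {' ', 'A'}
    expected = sum(
        1
        for line in PDB_ALTLOC.splitlines()
        if line.startswith("ATOM") and line[16] in (" ", "A")
    )
    topo, _ = read_structure(path)
    assert topo.n_atoms == expected == 4
    assert all(a.serial != 3 and a.serial != 5 for a in topo.atoms)


def test_empty_file_is_format_error(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(FormatError):
        read_structure(path)


def test_missing_file_is_io_error(tmp_path):
    with pytest.raises(IOError):
        read_structure(tmp_path / "nope.pdb")


def test_three_model_trajectory(tmp_path):
    body = "".join(
        f"MODEL {m+1:8d}\n" + PDB_TEN_ATOMS.replace("END\n", "") + "ENDMDL\n"
        for m in range(3)
    )
    path = tmp_path / "traj.pdb"
    path.write_text(body)
    topo, _ = read_structure(path)
    traj = read_trajectory(topo, path, dt_ns=0.5)
    assert traj.n_frames == 3
    np.testing.assert_allclose(traj.times, [0.0, 0.5, 1.0])


def test_model_atom_mismatch_is_consistency_error(tmp_path):
    lines = PDB_TEN_ATOMS.replace("END\n", "")
    short = "\n".join(lines.splitlines()[:-1]) + "\n"
    body = (
        "MODEL        1\n" + lines + "ENDMDL\n"
        "MODEL        2\n" + short + "ENDMDL\n"
    )
    path = tmp_path / "bad.pdb"
    path.write_text(body)
    topo, _ = read_structure(path)
    with pytest.raises(ConsistencyError):
        read_trajectory(topo, path)


def test_round_trip_preserves_coordinates(tmp_path):
    spec = fixture_specs(seed=7, n_frames=40, noise_sigma=0.1)["apo"]
    traj, _ = build_bundle(spec)
    path = tmp_path / "rt.pdb"
    write_trajectory(traj, path)
    topo, _ = read_structure(path)
    back = read_trajectory(topo, path)
    assert back.n_frames == traj.n_frames
    np.testing.assert_allclose(back.coordinates, traj.coordinates, atol=1e-3)


def test_write_read_write_is_stable(tmp_path):
    spec = fixture_specs(seed=7, n_frames=40, noise_sigma=0.1)["apo"]
    traj, _ = build_bundle(spec)
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_trajectory(traj, p1)
    topo, _ = read_structure(p1)
    write_trajectory(read_trajectory(topo, p1), p2)
    assert p1.read_text() == p2.read_text()


class TestSelection:
    @pytest.fixture()
    def topo(self, tmp_path):
        path = tmp_path / "sel.pdb"
        path.write_text(PDB_TEN_ATOMS)
        topo, _ = read_structure(path)
        return topo

    def test_resid_and_heavy(self, topo):
        # D91 has 8 heavy atoms in the fixture
        assert len(select_atoms(topo, "resid 91 and heavy")) == 8

    def test_water_on_waterless(self, topo):
        assert len(select_atoms(topo, "water")) == 0

    def test_backbone_single_residue(self, topo):
        idx = select_atoms(topo, "backbone and resid 91")
        assert [topo.atoms[i].name for i in idx] == ["N", "CA", "C", "O"]

    def test_invalid_spec_raises(self, topo):
        with pytest.raises(SelectionError):
            select_atoms(topo, "resid and heavy")
        with pytest.raises(SelectionError):
            select_atoms(topo, "frobnicate 9")
        with pytest.raises(SelectionError):
            select_atoms(topo, "( resid 91")

    def test_union_is_set_union(self, topo):
        a = set(select_atoms(topo, "resid 91").tolist())
        b = set(select_atoms(topo, "name CA").tolist())
        ab = set(select_atoms(topo, "resid 91 or name CA").tolist())
        assert ab == a | b

    def test_indices_strictly_increasing_and_idempotent(self, topo):
        idx = select_atoms(topo, "heavy or name CA")
        assert np.all(np.diff(idx) > 0)
        np.testing.assert_array_equal(
            idx, select_atoms(topo, "heavy or name CA")
        )

    def test_ranges_and_parentheses(self, topo):
        idx = select_atoms(topo, "( resid 91-92 and name CA ) or name OD1")
        names = [topo.atoms[i].name for i in idx]
        assert sorted(names) == ["CA", "CA", "OD1"]
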