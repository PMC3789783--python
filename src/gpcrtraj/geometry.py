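"""Geometric observables over trajectories.

Dihedral angles (side-chain chi series), helix-axis fits, kink angles at
a pivot residue, least-squares superposition RMSD, and distances between
intracellular helix ends — the raw material for rotamer-switch detection
and conformational-state clustering.

Conventions
-----------
* Angles in degrees.  Dihedrals are signed IUPAC angles in (-180, 180].
* Kink angle: 180 deg = straight helix; bending decreases the angle
  (a 50 deg arm rotation reads 130 deg).
* RMSD after optimal (Kabsch) superposition, in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bw_numbering import HelixDefinition
from .trajectory_io import SelectionError, Trajectory, select_atoms

__all__ = [
    "GeometryError",
    "InsufficientDataError",
    "ChiDefinitionError",
    "DihedralSeries",
    "KinkSeries",
    "EndDistanceSeries",
    "dihedral",
    "chi_series",
    "fit_helix_axis",
    "kink_series",
    "superpose",
    "rmsd_series",
    "end_distance_series",
    "CHI_ATOMS",
]


class GeometryError(ValueError):
    """Degenerate geometry (coincident/collinear points)."""


class InsufficientDataError(GeometryError):
    """Too few points/residues for the requested fit."""


class ChiDefinitionError(ValueError):
    """Residue type has no such chi angle or lacks the required atoms."""


@dataclass
class DihedralSeries:
    """Per-frame dihedral values for one residue/angle."""

    residue_seq: int
    angle_name: str
    values: np.ndarray  # degrees in (-180, 180]
    times: np.ndarray   # ns


@dataclass
class KinkSeries:
    """Per-frame helix kink angle about a pivot residue."""

    helix_id: int
    pivot_seq: int
    window: int
    values: np.ndarray  # degrees in (0, 180]
    times: np.ndarray


@dataclass
class EndDistanceSeries:
    """Per-frame distances between intracellular helix-end centroids.

    Columns ordered (TM7-TM3, TM3-TM6, TM6-TM7), Angstrom.
    """

    values: np.ndarray  # F x 3
    times: np.ndarray
    labels: tuple[str, str, str] = ("TM7-TM3", "TM3-TM6", "TM6-TM7")


# --------------------------------------------------------------------------
# dihedrals
# --------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float | np.ndarray:
    """Signed IUPAC dihedral angle, degrees in (-180, 180].

    Accepts single 3-vectors or broadcastable ``(..., 3)`` arrays (the
    leading axes typically being frames).  Invariant under rigid motion,
    negated by mirror reflection.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3

    b1n = np.linalg.norm(b1, axis=-1, keepdims=True)
    if np.any(b1n < 1e-10):
        raise GeometryError("coincident central atoms in dihedral")
    b1u = b1 / b1n

    # components of b0/b2 perpendicular to the central bond
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    if np.any(np.linalg.norm(v, axis=-1) < 1e-10) or np.any(
        np.linalg.norm(w, axis=-1) < 1e-10
    ):
        raise GeometryError("collinear atoms in dihedral")

    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 to keep the half-open convention
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return float(ang) if ang.ndim == 0 else ang


#: chi1/chi2 atom quadruples by residue type (IUPAC naming).
CHI_ATOMS: dict[str, dict[str, tuple[str, str, str, str]]] = {
    "chi1": {
        res: ("N", "CA", "CB", g)
        for res, g in {
            "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
            "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
            "PRO": "CG", "TRP": "CG", "TYR": "CG",
            "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1",
        }.items()
    },
    "chi2": {
        "ARG": ("CA", "CB", "CG", "CD"),
        "GLN": ("CA", "CB", "CG", "CD"),
        "GLU": ("CA", "CB", "CG", "CD"),
        "LYS": ("CA", "CB", "CG", "CD"),
        "PRO": ("CA", "CB", "CG", "CD"),
        "ILE": ("CA", "CB", "CG1", "CD1"),
        "LEU": ("CA", "CB", "CG", "CD1"),
        "MET": ("CA", "CB", "CG", "SD"),
        "PHE": ("CA", "CB", "CG", "CD1"),
        "TYR": ("CA", "CB", "CG", "CD1"),
        "TRP": ("CA", "CB", "CG", "CD1"),
        "HIS": ("CA", "CB", "CG", "ND1"),
        "ASP": ("CA", "CB", "CG", "OD1"),
        "ASN": ("CA", "CB", "CG", "OD1"),
    },
}


def _backbone_quad(angle_name: str) -> None:
    raise ChiDefinitionError(
        f"angle {angle_name!r} not supported; use chi1 or chi2"
    )


def chi_series(traj: Trajectory, residue_seq: int, angle_name: str) -> DihedralSeries:
    """Side-chain dihedral time series for one residue.

    The residue type must define the requested chi angle and carry all
    four atoms; a missing atom raises instead of silently skipping.
    """
    if angle_name not in CHI_ATOMS:
        _backbone_quad(angle_name)
    topo = traj.topology
    res_atoms = {
        topo.atoms[i].name: i for i in topo.atom_indices_of_residue(residue_seq)
    }
    if not res_atoms:
        raise SelectionError(f"residue {residue_seq} not in topology")
    res_name = next(
        a.residue_name for a in topo.atoms if a.residue_seq == residue_seq
    )
    table = CHI_ATOMS[angle_name]
    if res_name not in table:
        raise ChiDefinitionError(f"{res_name} has no {angle_name}")
    quad = table[res_name]
    try:
        idx = [res_atoms[name] for name in quad]
    except KeyError as exc:
        raise ChiDefinitionError(
            f"residue {res_name}{residue_seq} lacks atom {exc.args[0]} "
            f"required for {angle_name}"
        ) from None
    coords = traj.coordinates[:, idx, :]  # F x 4 x 3
    values = dihedral(coords[:, 0], coords[:, 1], coords[:, 2], coords[:, 3])
    return DihedralSeries(residue_seq, angle_name, np.atleast_1d(values), traj.times)


# --------------------------------------------------------------------------
# helix axes and kinks
# --------------------------------------------------------------------------

def fit_helix_axis(
    calpha_coords: np.ndarray, twist_deg: float | None = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Axis of a CA helix segment, oriented first residue -> last.

    Returns (unit direction, centroid).  Needs >= 4 residues.

    A raw principal-component fit of a short segment is biased by the
    helical wobble itself (for a 7-residue arm of an ideal alpha helix
    the tilt is ~18 deg), so the axial trend is estimated with the
    per-residue helical harmonic (default 100 deg/residue) projected
    out: the direction is ``sum_i c_i P_i`` where the coefficients are
    the residue indices orthogonalized against {1, cos(w i), sin(w i)}.
    This is exact for an ideal helix of the stated twist, any phase or
    radius, and reduces to a straight-line fit for ``twist_deg=None``.
    """
    coords = np.asarray(calpha_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise GeometryError("expected n x 3 coordinates")
    n = coords.shape[0]
    if n < 4:
        raise InsufficientDataError(
            f"helix axis fit needs >= 4 residues, got {n}"
        )
    centroid = coords.mean(axis=0)
    k = np.arange(n, dtype=float)
    if twist_deg is None:
        basis = np.ones((n, 1))
    else:
        w = np.radians(twist_deg)
        basis = np.column_stack([np.ones(n), np.cos(w * k), np.sin(w * k)])
    coef, *_ = np.linalg.lstsq(basis, k, rcond=None)
    resid = k - basis @ coef
    norm = np.linalg.norm(resid)
    if norm < 1e-8:  # twist aliases the axial trend (e.g. twist ~ 0)
        raise GeometryError("degenerate twist for axis fit")
    c = resid / norm
    direction = (c[:, None] * coords).sum(axis=0)
    dnorm = np.linalg.norm(direction)
    if dnorm < 1e-10:
        raise GeometryError("degenerate CA geometry; no axial trend")
    direction = direction / dnorm
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    return direction, centroid


def kink_series(
    traj: Trajectory,
    helix: HelixDefinition,
    pivot_seq: int,
    window: int = 7,
    chain: str | None = None,
) -> KinkSeries:
    """Helix kink angle about a pivot residue, per frame.

    Two arms of ``window`` residues flank the pivot (pivot excluded);
    each arm's N->C principal axis is fitted per frame and the kink is
    ``180 - angle(u, v)``: straight reads ~180, a 50 deg bend reads 130.
    """
    if window < 4:
        raise InsufficientDataError("arm window must be >= 4 residues")
    n_side = list(range(pivot_seq - window, pivot_seq))
    c_side = list(range(pivot_seq + 1, pivot_seq + window + 1))
    for arm in (n_side, c_side):
        if arm[0] < helix.start_seq or arm[-1] > helix.end_seq:
            raise InsufficientDataError(
                f"helix {helix.helix_id} range {helix.start_seq}-{helix.end_seq} "
                f"cannot host a {window}-residue arm about pivot {pivot_seq}"
            )

    topo = traj.topology

    def ca_indices(residues: list[int]) -> list[int]:
        out = []
        for seq in residues:
            hits = [
                i for i in topo.atom_indices_of_residue(seq, chain)
                if topo.atoms[i].name == "CA"
            ]
            if not hits:
                raise SelectionError(f"residue {seq} lacks a CA atom")
            out.append(hits[0])
        return out

    idx_n = ca_indices(n_side)
    idx_c = ca_indices(c_side)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        u, _ = fit_helix_axis(traj.coordinates[f, idx_n])
        v, _ = fit_helix_axis(traj.coordinates[f, idx_c])
        cosang = np.clip(np.dot(u, v), -1.0, 1.0)
        values[f] = 180.0 - np.degrees(np.arccos(cosang))
    return KinkSeries(helix.helix_id, pivot_seq, window, values, traj.times)


# --------------------------------------------------------------------------
# superposition and RMSD
# --------------------------------------------------------------------------

def superpose(
    ref: np.ndarray,
    mobile: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of ``mobile`` onto ``ref``.

    Kabsch algorithm; returns (rotation 3x3, translation 3, RMSD) such
    that ``mobile @ R.T + t`` best fits ``ref``.  Proper rotation only
    (no reflection).
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError("ref and mobile must be matching n x 3 arrays")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError("superposition needs >= 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be n non-negative values")
        w = w / w.sum()

    ref_c = ref - (w[:, None] * ref).sum(axis=0)
    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    # collinearity check: rank of the point cloud
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise GeometryError("reference points are collinear")

    cov = (w[:, None] * mob_c).T @ ref_c
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    translation = (w[:, None] * ref).sum(axis=0) - rot @ (w[:, None] * mobile).sum(axis=0)
    moved = mob_c @ rot.T
    rmsd = float(np.sqrt((w * np.sum((moved - ref_c) ** 2, axis=1)).sum()))
    return rot, translation, rmsd


def rmsd_series(
    traj: Trajectory,
    reference_frame_index: int = 0,
    atom_selection: str = "backbone",
) -> np.ndarray:
    """RMSD of each frame to a reference frame after superposition.

    ``atom_selection`` is a selection expression; each frame is
    independently superposed onto the reference before the RMSD.
    """
    idx = select_atoms(traj.topology, atom_selection)
    if idx.size == 0:
        raise SelectionError(f"selection {atom_selection!r} matches no atoms")
    ref = traj.coordinates[reference_frame_index, idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = superpose(ref, traj.coordinates[f, idx])
    return out


# --------------------------------------------------------------------------
# intracellular end distances
# --------------------------------------------------------------------------

def end_distance_series(
    traj: Trajectory,
    tm3: HelixDefinition,
    tm6: HelixDefinition,
    tm7: HelixDefinition,
    end_length: int = 4,
) -> EndDistanceSeries:
    """Distances between cytoplasmic end centroids of TM3/TM6/TM7.

    Per frame, each helix end is the centroid of the CA atoms of its
    ``end_length`` most intracellular residues; output columns are
    (TM7-TM3, TM3-TM6, TM6-TM7) in Angstrom.
    """
    if end_length < 1:
        raise ValueError("end_length must be >= 1")
    topo = traj.topology

    def end_centroids(helix: HelixDefinition) -> np.ndarray:
        idx = []
        for seq in helix.intracellular_residues(end_length):
            hits = [
                i for i in topo.atom_indices_of_residue(seq)
                if topo.atoms[i].name == "CA"
            ]
            if not hits:
                raise SelectionError(f"residue {seq} lacks a CA atom")
            idx.append(hits[0])
        return traj.coordinates[:, idx, :].mean(axis=1)  # F x 3

    c3, c6, c7 = end_centroids(tm3), end_centroids(tm6), end_centroids(tm7)
    values = np.stack(
        [
            np.linalg.norm(c7 - c3, axis=1),
            np.linalg.norm(c3 - c6, axis=1),
            np.linalg.norm(c6 - c7, axis=1),
        ],
        axis=1,
    )
    return EndDistanceSeries(values, traj.times)
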