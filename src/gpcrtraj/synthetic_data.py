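"""Synthetic 7-TM-bundle trajectories with planted ground truth.

Every analysis stage in this package is tested against trajectories in
which the observable of interest is *scheduled*: side-chain dihedrals
are realized exactly by internal-coordinate construction, helix kinks by
rigid rotation of the post-pivot arm, intracellular end distances by
rigid whole-helix translation, and water-shell occupancies by placing
exactly the scheduled number of water oxygens inside the target shell.
Gaussian coordinate noise is added last.  The generator returns the
planted truth alongside the trajectory so recovery can be asserted.

Geometry: ideal alpha-helices (CA rise 1.5 A/residue, 100 deg/residue
twist, CA helix radius 2.3 A) stood on a circle of radius 12 A, odd
helices running extracellular->intracellular and even ones the reverse,
as in a GPCR bundle.  Physical realism beyond what the analyses measure
(membrane, packing, full side chains) is deliberately absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bw_numbering import HelixDefinition
from .trajectory_io import AtomRecord, Topology, Trajectory, write_trajectory

__all__ = [
    "SyntheticSpec",
    "HelixPlacement",
    "ChiSchedule",
    "KinkSchedule",
    "WaterSchedule",
    "EndDistancePhase",
    "GroundTruthManifest",
    "SpecError",
    "build_bundle",
    "write_fixture_suite",
    "default_helices",
    "default_residue_names",
    "step_breakpoints",
    "DEFAULT_FIXTURE_SEED",
]

RISE = 1.5          # A per residue along the axis
TWIST = 100.0       # deg per residue
R_HELIX = 2.3       # CA helix radius, A
R_BUNDLE = 12.0     # bundle circle radius, A

DEFAULT_FIXTURE_SEED = 20130


class SpecError(ValueError):
    """Contradictory or unrealizable generator specification."""


# --------------------------------------------------------------------------
# spec dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixPlacement:
    """Where a helix stands in the bundle (angle on the bundle circle)."""

    definition: HelixDefinition
    placement_angle_deg: float


@dataclass(frozen=True)
class ChiSchedule:
    """Piecewise-linear chi target, breakpoints (frame, degrees).

    A rotamer flip is two adjacent breakpoints one frame apart (see
    :func:`step_breakpoints`).
    """

    residue_seq: int
    angle_name: str  # chi1 | chi2
    breakpoints: tuple[tuple[int, float], ...]


@dataclass(frozen=True)
class KinkSchedule:
    """Piecewise-linear kink-angle target about a pivot residue."""

    helix_id: int
    pivot_seq: int
    breakpoints: tuple[tuple[int, float], ...]  # (frame, kink degrees)


@dataclass(frozen=True)
class WaterSchedule:
    """Scheduled water-shell occupancy around target residues.

    Either ``breakpoints`` (piecewise-linear counts, rounded) or
    ``random_range`` (per-frame uniform integer draw, inclusive).
    """

    label: str
    target_residues: tuple[int, ...]
    cutoff: float = 4.0
    breakpoints: tuple[tuple[int, float], ...] | None = None
    random_range: tuple[int, int] | None = None


@dataclass(frozen=True)
class EndDistancePhase:
    """One conformational phase of the TM3/TM6/TM7 end-distance schedule."""

    start_frame: int
    label: str
    distances: tuple[float, float, float]  # (TM7-TM3, TM3-TM6, TM6-TM7), A


@dataclass
class SyntheticSpec:
    n_frames: int
    seed: int
    dt_ns: float = 1.0
    helices: tuple[HelixPlacement, ...] = ()
    residue_names: dict[int, str] = field(default_factory=dict)
    noise_sigma: float = 0.0
    chi_schedules: tuple[ChiSchedule, ...] = ()
    kink_schedules: tuple[KinkSchedule, ...] = ()
    water_schedules: tuple[WaterSchedule, ...] = ()
    background_waters: int = 0
    end_distance_phases: tuple[EndDistancePhase, ...] = ()
    end_length: int = 4


@dataclass
class GroundTruthManifest:
    """Planted truth: fully determines expected analysis output up to noise."""

    seed: int
    n_frames: int
    dt_ns: float
    noise_sigma: float
    chi: dict[str, list[float]]                  # "res/angle" -> F values
    chi_transitions: dict[str, list[int]]        # "res/angle" -> flip frames
    kink: dict[str, list[float]]                 # "helix_id" -> F values
    water_counts: dict[str, list[int]]           # label -> F counts
    state_labels: list[str | None]
    state_transitions: list[int]
    end_distances: list[list[float]] | None      # F x 3 scheduled, or None
    spec_echo: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def step_breakpoints(
    segments: list[tuple[int, float]], n_frames: int
) -> tuple[tuple[tuple[int, float], ...], list[int]]:
    """Breakpoints for a piecewise-constant schedule with sharp steps.

    ``segments`` are (start_frame, value) with the first start at 0.
    Returns (breakpoints, transition_frames): each step happens between
    frame f-1 and f, so the new value first holds at its start frame.
    """
    if not segments or segments[0][0] != 0:
        raise SpecError("step schedule must start at frame 0")
    bps: list[tuple[int, float]] = [(0, segments[0][1])]
    transitions: list[int] = []
    for (f, v) in segments[1:]:
        if f <= bps[-1][0] + 1:
            raise SpecError("step segments must be >= 2 frames apart")
        bps.append((f - 1, bps[-1][1]))
        bps.append((f, v))
        transitions.append(f)
    bps.append((n_frames - 1, bps[-1][1]))
    # drop a duplicate terminal breakpoint if the last step is at the end
    if len(bps) >= 2 and bps[-1][0] == bps[-2][0]:
        bps.pop()
    return tuple(bps), transitions


def _interp_schedule(breakpoints, n_frames: int) -> np.ndarray:
    frames = np.array([b[0] for b in breakpoints], dtype=float)
    vals = np.array([b[1] for b in breakpoints], dtype=float)
    if np.any(np.diff(frames) <= 0):
        raise SpecError("breakpoint frames must be strictly increasing")
    if frames[0] > 0 or frames[-1] > n_frames - 1:
        # clamp is fine at the start; forbid beyond the last frame
        if frames[-1] > n_frames - 1:
            raise SpecError("breakpoint beyond last frame")
    return np.interp(np.arange(n_frames), frames, vals)


# --------------------------------------------------------------------------
# internal-coordinate placement
# --------------------------------------------------------------------------

def nerf(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from three reference atoms and internal coordinates.

    Natural-extension reference frame: |c-d| = bond, angle(b,c,d) =
    ``angle_deg`` and dihedral(a,b,c,d) = ``dihedral_deg`` hold exactly.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    frame = np.column_stack([bc_hat, m_hat, n_hat])
    return c + frame @ d_local


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


#: side-chain build recipes: (atom, bond A, angle deg, dihedral spec)
#: dihedral spec: "chi1", "chi2", ("chi2", offset) or a fixed number;
#: reference atoms are the previous three of the chain N-CA-CB-G-D.
_SIDE_CHAINS: dict[str, list[tuple[str, float, float, object]]] = {
    "ALA": [],
    "PRO": [],
    "SER": [],   # OG is the chi1 atom itself, handled via G atom name
    "ASP": [("OD1", 1.25, 118.0, "chi2"), ("OD2", 1.25, 118.0, ("chi2", 180.0))],
    "ASN": [("OD1", 1.23, 121.0, "chi2"), ("ND2", 1.33, 117.0, ("chi2", 180.0))],
    "PHE": [("CD1", 1.40, 120.0, "chi2"), ("CD2", 1.40, 120.0, ("chi2", 180.0))],
    "TYR": [("CD1", 1.40, 120.0, "chi2"), ("CD2", 1.40, 120.0, ("chi2", 180.0))],
    "TRP": [("CD1", 1.37, 127.0, "chi2"), ("CD2", 1.43, 126.6, ("chi2", 180.0))],
    "LEU": [("CD1", 1.53, 110.5, "chi2"), ("CD2", 1.53, 110.5, ("chi2", 120.0))],
    "MET": [("SD", 1.80, 112.7, "chi2")],
}

_G_ATOM = {"SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1"}

_DEFAULT_CHI = {"chi1": -60.0, "chi2": 90.0}


def _has_side_chain(res_name: str) -> bool:
    return res_name not in ("GLY",) and (res_name in _SIDE_CHAINS or res_name in _G_ATOM)


# --------------------------------------------------------------------------
# bundle construction
# --------------------------------------------------------------------------

def default_helices() -> tuple[HelixPlacement, ...]:
    """Reconstructed TM helix definitions for the S1P receptor bundle.

    The crystal-structure papers print BW superscripts for individual
    residues but not helix boundaries; these ranges are consistent with
    every printed residue/superscript pair (e.g. D91=2.50, W269=6.48,
    P308=7.50) and are flagged as reconstructed in the docs.
    """
    defs = [
        HelixDefinition(1, 49, 77, 63, 50, "end"),
        HelixDefinition(2, 84, 110, 91, 50, "start"),
        HelixDefinition(3, 115, 145, 142, 50, "end"),
        HelixDefinition(4, 160, 184, 171, 50, "start"),
        HelixDefinition(5, 198, 226, 213, 50, "end"),
        HelixDefinition(6, 252, 277, 269, 48, "start"),
        HelixDefinition(7, 291, 315, 308, 50, "end"),
    ]
    return tuple(
        HelixPlacement(d, angle)
        for d, angle in zip(defs, (0.0, 51.4, 102.9, 154.3, 205.7, 257.1, 308.6))
    )


def default_residue_names() -> dict[int, str]:
    """Residue types at the positions the analyses care about."""
    return {
        63: "ASN", 91: "ASP", 98: "TYR", 101: "ASN", 105: "SER",
        120: "ARG", 121: "GLU", 124: "MET", 125: "PHE",
        265: "PHE", 269: "TRP", 273: "PHE",
        297: "LEU", 303: "ASN", 304: "SER", 307: "ASN", 308: "PRO", 311: "TYR",
    }


def _helix_frame_atoms(hp: HelixPlacement, residue_names: dict[int, str]):
    """Static backbone coordinates + atom bookkeeping for one helix."""
    d = hp.definition
    n_res = d.end_seq - d.start_seq + 1
    phi0 = np.radians(hp.placement_angle_deg)
    center = np.array([R_BUNDLE * np.cos(phi0), R_BUNDLE * np.sin(phi0), 0.0])
    # chain z direction: 'end' intracellular means z decreases along sequence
    s = -1.0 if d.intracellular_end == "end" else 1.0
    z0 = -s * (n_res - 1) / 2.0 * RISE

    def on_curve(i: float, dtheta: float, radius: float, dz: float) -> np.ndarray:
        theta = np.radians(i * TWIST + dtheta) + phi0
        z = z0 + s * (i * RISE + dz)
        return center + np.array([radius * np.cos(theta), radius * np.sin(theta), z])

    atoms: list[tuple[int, str, str]] = []  # (residue_seq, res_name, atom_name)
    coords: list[np.ndarray] = []
    for i in range(n_res):
        seq = d.start_seq + i
        res_name = residue_names.get(seq, "GLY")
        n_pos = on_curve(i, -29.0, 1.56, -0.75)
        ca = on_curve(i, 0.0, R_HELIX, 0.0)
        c_pos = on_curve(i, 27.0, 1.64, 0.55)
        radial = c_pos - np.array([center[0], center[1], c_pos[2]])
        o_pos = c_pos + 1.23 * radial / np.linalg.norm(radial)
        for name, pos in (("N", n_pos), ("CA", ca), ("C", c_pos), ("O", o_pos)):
            atoms.append((seq, res_name, name))
            coords.append(pos)
        if _has_side_chain(res_name):
            cb = nerf(c_pos, n_pos, ca, 1.53, 110.5, -122.0)
            atoms.append((seq, res_name, "CB"))
            coords.append(cb)
            # gamma/delta atoms are frame-dependent (chi schedules); placed later
    return atoms, np.array(coords)


def _chi_atom_names(res_name: str) -> list[tuple[str, float, float, object]]:
    """Gamma atom + delta recipes for one residue type."""
    g_name = _G_ATOM.get(res_name, "CG")
    recipes: list[tuple[str, float, float, object]] = [(g_name, 1.52, 114.0, "chi1")]
    recipes.extend(_SIDE_CHAINS.get(res_name, []))
    return recipes


def build_bundle(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruthManifest]:
    """Generate the trajectory and its ground-truth manifest.

    Construction order per frame: side chains at the scheduled chi ->
    kink rotation of the post-pivot arm -> whole-helix translations
    realizing the end-distance schedule -> water placement -> global
    i.i.d. Gaussian noise.  Deterministic for identical spec + seed.
    """
    if spec.n_frames < 1:
        raise SpecError("n_frames must be >= 1")
    helices = spec.helices or default_helices()
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    helix_by_id = {hp.definition.helix_id: hp for hp in helices}

    # ---- static backbone + atom table -------------------------------------
    atom_meta: list[tuple[int, str, str]] = []
    base_coords: list[np.ndarray] = []
    residue_names = dict(spec.residue_names) or default_residue_names()
    for hp in helices:
        atoms, coords = _helix_frame_atoms(hp, residue_names)
        atom_meta.extend(atoms)
        base_coords.extend(coords)
    base = np.array(base_coords)
    n_protein = len(atom_meta)

    res_atom_idx: dict[int, dict[str, int]] = {}
    for i, (seq, _rn, name) in enumerate(atom_meta):
        res_atom_idx.setdefault(seq, {})[name] = i
    res_name_of = {seq: rn for seq, rn, _name in atom_meta}

    # ---- chi schedules: add gamma/delta atoms -----------------------------
    chi_targets: dict[tuple[int, str], np.ndarray] = {}
    for cs in spec.chi_schedules:
        if cs.residue_seq not in res_atom_idx:
            raise SpecError(f"chi schedule references unknown residue {cs.residue_seq}")
        if not _has_side_chain(res_name_of[cs.residue_seq]):
            raise SpecError(
                f"residue {cs.residue_seq} ({res_name_of[cs.residue_seq]}) "
                "has no buildable side chain"
            )
        chi_targets[(cs.residue_seq, cs.angle_name)] = _interp_schedule(
            cs.breakpoints, n_frames
        )

    # every residue with a side chain gets gamma (+delta) atoms; extend table
    sidechain_jobs: list[tuple[int, str, list[tuple[str, float, float, object]]]] = []
    extra_meta: list[tuple[int, str, str]] = []
    for seq in sorted(res_atom_idx):
        rn = res_name_of[seq]
        if not _has_side_chain(rn) or "CB" not in res_atom_idx[seq]:
            continue
        recipes = _chi_atom_names(rn)
        sidechain_jobs.append((seq, rn, recipes))
        for (name, *_rest) in recipes:
            extra_meta.append((seq, rn, name))
    offset = n_protein
    extra_index: dict[tuple[int, str], int] = {}
    for j, (seq, _rn, name) in enumerate(extra_meta):
        extra_index[(seq, name)] = offset + j
        res_atom_idx[seq][name] = offset + j  # side-chain atoms are residue atoms too
    atom_meta.extend(extra_meta)
    n_protein = len(atom_meta)

    # ---- kink schedules ---------------------------------------------------
    kink_truth: dict[int, np.ndarray] = {}
    kink_jobs = []
    for ks in spec.kink_schedules:
        if ks.helix_id not in helix_by_id:
            raise SpecError(f"kink schedule references unknown helix {ks.helix_id}")
        hp = helix_by_id[ks.helix_id]
        d = hp.definition
        if not d.start_seq < ks.pivot_seq < d.end_seq:
            raise SpecError(f"pivot {ks.pivot_seq} not inside helix {ks.helix_id}")
        target = _interp_schedule(ks.breakpoints, n_frames)
        if np.any(target <= 0) or np.any(target > 180):
            raise SpecError("kink targets must lie in (0, 180]")
        kink_truth[ks.helix_id] = target
        phi0 = np.radians(hp.placement_angle_deg)
        axis = np.array([np.cos(phi0), np.sin(phi0), 0.0])  # radial, perp to z
        pivot_ca = base[res_atom_idx[ks.pivot_seq]["CA"]]
        arm_atoms = [
            i for i, (seq, _rn, _name) in enumerate(atom_meta)
            if seq in res_atom_idx and seq > ks.pivot_seq
            and d.start_seq <= seq <= d.end_seq
        ]
        kink_jobs.append((ks.helix_id, target, axis, pivot_ca, np.array(arm_atoms)))

    # ---- end-distance schedule --------------------------------------------
    state_labels: list[str | None] = [None] * n_frames
    state_transitions: list[int] = []
    end_target: np.ndarray | None = None
    if spec.end_distance_phases:
        for h_id in (3, 6, 7):
            if h_id not in helix_by_id:
                raise SpecError("end-distance schedule needs helices 3, 6 and 7")
        phases = sorted(spec.end_distance_phases, key=lambda p: p.start_frame)
        if phases[0].start_frame != 0:
            raise SpecError("first end-distance phase must start at frame 0")
        end_target = np.empty((n_frames, 3))
        for i, ph in enumerate(phases):
            d73, d36, d67 = ph.distances
            if d73 + d36 <= d67 or d36 + d67 <= d73 or d67 + d73 <= d36:
                raise SpecError(f"phase {ph.label}: triangle inequality violated")
            stop = phases[i + 1].start_frame if i + 1 < len(phases) else n_frames
            end_target[ph.start_frame:stop] = ph.distances
            state_labels[ph.start_frame:stop] = [ph.label] * (stop - ph.start_frame)
            if i > 0:
                state_transitions.append(ph.start_frame)

    def end_ca_indices(h_id: int) -> np.ndarray:
        d = helix_by_id[h_id].definition
        return np.array(
            [res_atom_idx[seq]["CA"] for seq in d.intracellular_residues(spec.end_length)]
        )

    def helix_atom_indices(h_id: int) -> np.ndarray:
        """All protein atoms of a helix, side-chain atoms included."""
        d = helix_by_id[h_id].definition
        return np.array(
            [
                i for i, (seq, _rn, _name) in enumerate(atom_meta[:n_protein])
                if d.start_seq <= seq <= d.end_seq
            ]
        )

    # ---- water schedules --------------------------------------------------
    water_counts_truth: dict[str, np.ndarray] = {}
    water_plans = []  # (schedule, counts F, target atom indices, topo slice)
    labels_seen = set()
    for ws in spec.water_schedules:
        if ws.label in labels_seen:
            raise SpecError(f"duplicate water schedule label {ws.label!r}")
        labels_seen.add(ws.label)
        if (ws.breakpoints is None) == (ws.random_range is None):
            raise SpecError(
                f"water schedule {ws.label!r}: give breakpoints or random_range"
            )
        if ws.breakpoints is not None:
            counts = np.rint(_interp_schedule(ws.breakpoints, n_frames)).astype(int)
        else:
            lo, hi = ws.random_range
            counts = rng.integers(lo, hi + 1, size=n_frames)
        if np.any(counts < 0):
            raise SpecError("negative water occupancy")
        tgt = []
        for seq in ws.target_residues:
            if seq not in res_atom_idx:
                raise SpecError(f"water schedule {ws.label!r}: unknown residue {seq}")
            tgt.extend(
                idx for name, idx in res_atom_idx[seq].items() if not name.startswith("H")
            )
        water_counts_truth[ws.label] = counts
        water_plans.append((ws, counts, np.array(sorted(tgt))))

    # water atom table (fixed topology across frames: parked when not in shell)
    water_meta: list[tuple[int, str, str]] = []
    water_slices = []
    w_seq = 400
    for ws, counts, _tgt in water_plans:
        n_w = int(counts.max()) if counts.size else 0
        start = n_protein + len(water_meta)
        for _ in range(n_w):
            w_seq += 1
            water_meta.append((w_seq, "HOH", "O"))
        water_slices.append(slice(start, start + n_w))
    bg_start = n_protein + len(water_meta)
    for _ in range(spec.background_waters):
        w_seq += 1
        water_meta.append((w_seq, "HOH", "O"))
    atom_meta.extend(water_meta)
    n_atoms = len(atom_meta)

    # ---- per-frame assembly ------------------------------------------------
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, :len(base), :] = base  # backbone + CB, static before transforms

    # side chains per frame
    for seq, rn, recipes in sidechain_jobs:
        ai = res_atom_idx[seq]
        n_pos, ca, cb = base[ai["N"]], base[ai["CA"]], base[ai["CB"]]
        chi1 = chi_targets.get((seq, "chi1"), np.full(n_frames, _DEFAULT_CHI["chi1"]))
        chi2 = chi_targets.get((seq, "chi2"), np.full(n_frames, _DEFAULT_CHI["chi2"]))
        g_recipe = recipes[0]
        # cache by (chi1, chi2) pair; schedules are piecewise so few distinct values
        cache: dict[tuple[float, float], dict[str, np.ndarray]] = {}
        for f in range(n_frames):
            key = (round(float(chi1[f]), 9), round(float(chi2[f]), 9))
            placed = cache.get(key)
            if placed is None:
                placed = {}
                g = nerf(n_pos, ca, cb, g_recipe[1], g_recipe[2], key[0])
                placed[g_recipe[0]] = g
                for name, bond, angle, dspec in recipes[1:]:
                    if dspec == "chi2":
                        dval = key[1]
                    elif isinstance(dspec, tuple):
                        dval = key[1] + dspec[1]
                    else:
                        dval = float(dspec)
                    placed[name] = nerf(ca, cb, g, bond, angle, dval)
                cache[key] = placed
            for name, pos in placed.items():
                coords[f, extra_index[(seq, name)]] = pos

    # kink rotations (post-pivot arm, per frame)
    for h_id, target, axis, pivot_ca, arm in kink_jobs:
        for f in range(n_frames):
            bend = 180.0 - target[f]
            if abs(bend) < 1e-12:
                continue
            rot = _rotation_about_axis(axis, bend)
            coords[f, arm] = (coords[f, arm] - pivot_ca) @ rot.T + pivot_ca

    # end-distance translations (rigid per helix, per frame)
    if end_target is not None:
        idx3, idx6, idx7 = (end_ca_indices(h) for h in (3, 6, 7))
        sl = {h: helix_atom_indices(h) for h in (3, 6, 7)}
        for f in range(n_frames):
            c3 = coords[f, idx3].mean(axis=0)
            c6 = coords[f, idx6].mean(axis=0)
            c7 = coords[f, idx7].mean(axis=0)
            d73, d36, d67 = end_target[f]
            # template triangle with the scheduled side lengths
            x7 = (d36**2 + d73**2 - d67**2) / (2 * d36)
            y7 = np.sqrt(max(d73**2 - x7**2, 0.0))
            tmpl = np.array([[0.0, 0.0, 0.0], [d36, 0.0, 0.0], [x7, y7, 0.0]])
            cur = np.array([c3, c6, c7])
            # rigid-fit template onto current centroids (Kabsch, 3 points)
            tc, cc = tmpl.mean(axis=0), cur.mean(axis=0)
            u, _, vt = np.linalg.svd((tmpl - tc).T @ (cur - cc))
            dsign = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, dsign]) @ u.T
            placed = (tmpl - tc) @ rot.T + cc
            for h, target_c, cur_c in zip((3, 6, 7), placed, cur):
                coords[f, sl[h]] += target_c - cur_c

    # water placement (after transforms so shells track their targets)
    def _sample_shell(center_atoms: np.ndarray, others: np.ndarray, cutoff: float) -> np.ndarray:
        lo, hi = 1.2, cutoff - 1.0
        for _ in range(200):
            anchor = center_atoms[rng.integers(len(center_atoms))]
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos = anchor + v * rng.uniform(lo, hi)
            d_own = np.linalg.norm(center_atoms - pos, axis=1).min()
            if not (lo <= d_own <= hi):
                continue
            if others.size and np.linalg.norm(others - pos, axis=1).min() < cutoff + 1.5:
                continue
            return pos
        raise SpecError("failed to place a shell water; shell too crowded")

    all_targets = [plan[2] for plan in water_plans]
    for k, ((ws, counts, tgt_idx), w_slice) in enumerate(zip(water_plans, water_slices)):
        other_idx = (
            np.concatenate([t for j, t in enumerate(all_targets) if j != k])
            if len(all_targets) > 1
            else np.empty(0, dtype=int)
        )
        n_w = w_slice.stop - w_slice.start
        for f in range(n_frames):
            tgt = coords[f, tgt_idx]
            others = coords[f, other_idx] if other_idx.size else np.empty((0, 3))
            n_in = int(counts[f])
            for w in range(n_w):
                slot = w_slice.start + w
                if w < n_in:
                    coords[f, slot] = _sample_shell(tgt, others, ws.cutoff)
                else:  # parked far outside every shell
                    coords[f, slot] = (
                        80.0 + 3.0 * (w % 50), 80.0 + 3.0 * (w // 50), 40.0
                    )

    # background waters: static positions exterior to every scheduled shell
    if spec.background_waters:
        tgt0 = (
            np.concatenate(all_targets) if all_targets else np.empty(0, dtype=int)
        )
        placed = 0
        guard = 0
        while placed < spec.background_waters:
            guard += 1
            if guard > 100000:
                raise SpecError("could not place background waters")
            pos = rng.uniform(-30.0, 30.0, size=3)
            if tgt0.size:
                dmin = min(
                    np.linalg.norm(coords[f, tgt0] - pos, axis=1).min()
                    for f in (0, n_frames - 1, n_frames // 2)
                )
                if dmin < max(ws.cutoff for ws, *_ in water_plans) + 6.0:
                    continue
            coords[:, bg_start + placed] = pos
            placed += 1

    # global Gaussian coordinate noise, last
    if spec.noise_sigma > 0:
        coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    # ---- topology + manifest ----------------------------------------------
    records = []
    for i, (seq, rn, name) in enumerate(atom_meta):
        element = "O" if rn == "HOH" else name[0]
        chain = "W" if rn == "HOH" else "A"
        records.append(
            AtomRecord(
                serial=i + 1, name=name, residue_name=rn,
                residue_seq=seq, chain=chain, element=element,
            )
        )
    topo = Topology(records)
    times = np.arange(n_frames) * spec.dt_ns
    traj = Trajectory(topo, coords, times)

    chi_truth_out: dict[str, list[float]] = {}
    chi_trans_out: dict[str, list[int]] = {}
    for (seq, angle), vals in chi_targets.items():
        key = f"{seq}/{angle}"
        chi_truth_out[key] = [float(v) for v in vals]
        steps = np.flatnonzero(np.abs(np.diff(vals)) > 1e-9) + 1
        chi_trans_out[key] = [int(s) for s in steps]

    manifest = GroundTruthManifest(
        seed=spec.seed,
        n_frames=n_frames,
        dt_ns=spec.dt_ns,
        noise_sigma=spec.noise_sigma,
        chi=chi_truth_out,
        chi_transitions=chi_trans_out,
        kink={str(h): [float(v) for v in vals] for h, vals in kink_truth.items()},
        water_counts={lab: [int(c) for c in counts] for lab, counts in water_counts_truth.items()},
        state_labels=list(state_labels),
        state_transitions=state_transitions,
        end_distances=(
            [[float(v) for v in row] for row in end_target]
            if end_target is not None
            else None
        ),
        spec_echo={
            "n_frames": n_frames,
            "dt_ns": spec.dt_ns,
            "seed": spec.seed,
            "noise_sigma": spec.noise_sigma,
            "background_waters": spec.background_waters,
            "end_length": spec.end_length,
        },
    )
    return traj, manifest


# --------------------------------------------------------------------------
# fixture suite: apo-like / antagonist-like / agonist-like
# --------------------------------------------------------------------------

def _toggle_segments(flips: list[int], values: tuple[float, float]) -> list[tuple[int, float]]:
    segs = [(0, values[0])]
    for i, f in enumerate(flips):
        segs.append((f, values[(i + 1) % 2]))
    return segs


def fixture_specs(
    seed: int = DEFAULT_FIXTURE_SEED,
    n_frames: int = 700,
    noise_sigma: float = 0.2,
) -> dict[str, SyntheticSpec]:
    """The three study-condition fixtures.

    apo-like: early Y98 chi1 flip, toggle residues quiet, 3-4 shell
    waters at the conserved TM2 aspartate; antagonist-like: late Y98
    flip, early W-toggle fluctuation, 5-7 waters; agonist-like: Y98
    stable, W/F toggle instability, 8-10 waters, TM7 kink drifting
    155 -> 130 deg and a three-phase end-distance schedule.
    """
    common = dict(n_frames=n_frames, dt_ns=1.0, noise_sigma=noise_sigma)

    def fr(frame_at_700: int) -> int:
        # canonical schedules are stated on a 700-frame timeline; scale for
        # smaller fixtures while keeping frame 0 fixed
        return max(2, int(round(frame_at_700 * n_frames / 700)))

    def chi(seq, angle, segments):
        bps, _ = step_breakpoints(segments, n_frames)
        return ChiSchedule(seq, angle, bps)

    d91 = (91,)
    npxxy = (307, 308, 309, 310, 311)

    apo = SyntheticSpec(
        seed=seed,
        chi_schedules=(
            chi(98, "chi1", [(0, -60.0), (fr(100), 170.0)]),
            chi(269, "chi2", [(0, 90.0)]),
            chi(265, "chi1", [(0, -60.0)]),
        ),
        water_schedules=(
            WaterSchedule("D91(2.50)", d91, 4.0, random_range=(3, 4)),
            WaterSchedule("NPxxY", npxxy, 4.0, random_range=(1, 2)),
        ),
        background_waters=40,
        **common,
    )
    antagonist = SyntheticSpec(
        seed=seed + 1,
        chi_schedules=(
            chi(98, "chi1", [(0, -60.0), (fr(550), 170.0)]),
            chi(269, "chi2",
                _toggle_segments([fr(90), fr(210), fr(330), fr(450)], (90.0, 0.0))),
            chi(265, "chi1", [(0, -60.0)]),
        ),
        water_schedules=(
            WaterSchedule("D91(2.50)", d91, 4.0, random_range=(5, 7)),
            WaterSchedule("NPxxY", npxxy, 4.0, random_range=(2, 3)),
        ),
        background_waters=40,
        **common,
    )
    agonist = SyntheticSpec(
        seed=seed + 2,
        chi_schedules=(
            chi(98, "chi1", [(0, -60.0)]),
            chi(269, "chi2",
                _toggle_segments([fr(120), fr(260), fr(430), fr(590)], (90.0, 0.0))),
            chi(265, "chi1", [(0, -60.0), (fr(200), 60.0), (fr(480), -60.0)]),
        ),
        water_schedules=(
            WaterSchedule("D91(2.50)", d91, 4.0, random_range=(8, 10)),
            WaterSchedule("NPxxY", npxxy, 4.0,
                          breakpoints=((0, 2.0), (fr(150) - 1, 2.0), (fr(150), 8.0),
                                       (n_frames - 1, 8.0))),
        ),
        kink_schedules=(
            KinkSchedule(7, 308, ((0, 155.0), (n_frames - 1, 130.0))),
        ),
        end_distance_phases=(
            EndDistancePhase(0, "inactive", (9.0, 11.0, 10.0)),
            EndDistancePhase(fr(250), "intermediate", (11.5, 13.5, 12.5)),
            EndDistancePhase(fr(500), "active", (14.0, 16.0, 15.0)),
        ),
        background_waters=40,
        **common,
    )
    return {"apo": apo, "antagonist": antagonist, "agonist": agonist}


def write_fixture_suite(
    output_dir: str | Path,
    seed: int = DEFAULT_FIXTURE_SEED,
    n_frames: int = 700,
    noise_sigma: float = 0.2,
) -> dict[str, dict[str, Path]]:
    """Write the three condition fixtures (multi-model PDB + JSON manifest).

    Deterministic: identical seed gives byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for name, spec in fixture_specs(seed, n_frames, noise_sigma).items():
        traj, manifest = build_bundle(spec)
        pdb = out / f"{name}.pdb"
        man = out / f"{name}.manifest.json"
        write_trajectory(traj, pdb)
        manifest.to_json(man)
        written[name] = {"trajectory": pdb, "manifest": man}
    return written
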