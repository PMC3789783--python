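"""Rotamer-state classification, switch-event detection, hydrogen bonds
and ligand contacts.

A rotamer switch is a persistent jump of a side-chain chi angle between
discrete bins (e.g. the conserved TM6 tryptophan toggling its chi2
between ~0 and ~90 deg).  Classification is circular-bin based with an
optional circular median filter; an event requires the new state to
persist for a minimum dwell so brief excursions are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.spatial.distance import cdist

from .geometry import DihedralSeries
from .trajectory_io import SelectionError, Trajectory, select_atoms, selection_mask

__all__ = [
    "RotamerBins",
    "RotamerStateSeries",
    "SwitchEvent",
    "HBondSeries",
    "ContactTable",
    "BinDefinitionError",
    "DEFAULT_CHI_BINS",
    "TOGGLE_BINS",
    "classify_rotamers",
    "detect_switches",
    "hbond_series",
    "contact_occupancy",
]


class BinDefinitionError(ValueError):
    """Rotamer bins overlap or fail to cover the circle."""


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Map to (-180, 180]."""
    a = -(np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0)
    return a


@dataclass(frozen=True)
class RotamerBins:
    """Labeled half-open circular intervals (lo, hi] in degrees.

    An interval with lo > hi wraps through +/-180 (the trans bin
    (120, -120] is the canonical example).  Bins must tile the circle.
    """

    bins: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for _, lo, hi in self.bins:
            arc = (hi - lo) % 360.0
            if arc == 0.0:
                raise BinDefinitionError("zero- or full-width bin")
            total += arc
        if not np.isclose(total, 360.0):
            raise BinDefinitionError(
                f"bins cover {total} degrees, must tile the circle exactly"
            )
        # probe overlap on a fine grid: every angle must fall in exactly one bin
        probe = np.arange(-179.75, 180.01, 0.5)
        hits = np.zeros(probe.size, dtype=int)
        for _, lo, hi in self.bins:
            hits += self._contains(probe, lo, hi)
        if np.any(hits != 1):
            raise BinDefinitionError("bins overlap or leave gaps")

    @staticmethod
    def _contains(angle: np.ndarray, lo: float, hi: float) -> np.ndarray:
        rel = np.mod(np.asarray(angle) - lo, 360.0)
        width = (hi - lo) % 360.0
        return (rel > 0) & (rel <= width + 1e-12)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bins)

    def centers(self) -> dict[str, float]:
        out = {}
        for label, lo, hi in self.bins:
            width = (hi - lo) % 360.0
            out[label] = float(_wrap(lo + width / 2.0))
        return out

    def classify(self, angles: np.ndarray) -> np.ndarray:
        angles = np.asarray(angles, dtype=float)
        labels = np.empty(angles.shape, dtype=object)
        assigned = np.zeros(angles.shape, dtype=bool)
        for label, lo, hi in self.bins:
            mask = self._contains(angles, lo, hi) & ~assigned
            labels[mask] = label
            assigned |= mask
        if not assigned.all():  # boundary numerics; snap to nearest center
            centers = self.centers()
            for i in np.flatnonzero(~assigned):
                best = min(
                    centers,
                    key=lambda lab: abs(_wrap(angles.flat[i] - centers[lab])),
                )
                labels.flat[i] = best
        return labels


#: gauche-/trans/gauche+ tiling of the chi circle.
DEFAULT_CHI_BINS = RotamerBins(
    (("g-", -120.0, 0.0), ("g+", 0.0, 120.0), ("t", 120.0, -120.0))
)

#: Two-state bins for toggle-switch chi2 analyses (centers ~0 and ~90 deg).
TOGGLE_BINS = RotamerBins((("horizontal", -45.0, 45.0), ("vertical", 45.0, -45.0)))


@dataclass
class RotamerStateSeries:
    residue_seq: int
    angle_name: str
    labels: np.ndarray            # F object array of bin labels
    bin_centers: dict[str, float]
    times: np.ndarray
    filter_window: int = 1


@dataclass(frozen=True)
class SwitchEvent:
    """A persistent rotamer-state change."""

    residue_seq: int
    angle_name: str
    frame_index: int
    time_ns: float
    from_state: str
    to_state: str
    pre_dwell: int
    post_dwell: int


def circular_median_filter(values: np.ndarray, window: int) -> np.ndarray:
    """Median-filter a degree series respecting wraparound.

    Componentwise median of the unit-circle embedding (median of sin and
    cos separately, recombined by atan2) — robust to single-frame spikes
    and continuous across +/-180.
    """
    if window <= 1:
        return np.asarray(values, dtype=float)
    rad = np.radians(np.asarray(values, dtype=float))
    s = median_filter(np.sin(rad), size=window, mode="nearest")
    c = median_filter(np.cos(rad), size=window, mode="nearest")
    return _wrap(np.degrees(np.arctan2(s, c)))


def classify_rotamers(
    series: DihedralSeries,
    bins: RotamerBins = DEFAULT_CHI_BINS,
    filter_window: int = 21,
) -> RotamerStateSeries:
    """Assign each frame's (median-filtered) angle to a circular bin."""
    filtered = circular_median_filter(series.values, filter_window)
    labels = bins.classify(filtered)
    return RotamerStateSeries(
        series.residue_seq,
        series.angle_name,
        labels,
        bins.centers(),
        series.times,
        filter_window=filter_window,
    )


def detect_switches(states: RotamerStateSeries, min_dwell: int = 50) -> list[SwitchEvent]:
    """Report persistent state changes.

    An event is logged at the first frame of each maximal run of a new
    state whose length is >= ``min_dwell``; shorter excursions are
    ignored (the accepted state is retained through them).
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    labels = states.labels
    if labels.size == 0:
        return []
    # run-length encode
    runs: list[tuple[str, int, int]] = []  # (label, start, length)
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.append((str(labels[start]), start, i - start))
            start = i
    events: list[SwitchEvent] = []
    accepted = runs[0][0]
    accepted_since = 0
    for label, run_start, run_len in runs[1:]:
        if label != accepted and run_len >= min_dwell:
            events.append(
                SwitchEvent(
                    residue_seq=states.residue_seq,
                    angle_name=states.angle_name,
                    frame_index=run_start,
                    time_ns=float(states.times[run_start]),
                    from_state=accepted,
                    to_state=label,
                    pre_dwell=run_start - accepted_since,
                    post_dwell=run_len,
                )
            )
            accepted = label
            accepted_since = run_start
    return events


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

@dataclass
class HBondSeries:
    """Per-frame presence of a donor-acceptor hydrogen bond.

    Criterion: heavy-atom D-A distance <= ``distance_cutoff`` AND, when
    the donor carries hydrogens (D-H <= 1.2 A), a D-H...A angle >=
    ``angle_cutoff`` for at least one such hydrogen.  Without hydrogens
    the angle term is dropped and ``heavy_only`` flags the fallback.
    """

    donor: tuple[int, str]
    acceptor: tuple[int, str]
    present: np.ndarray  # F booleans
    times: np.ndarray
    distance_cutoff: float
    angle_cutoff: float
    heavy_only: bool

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.present))


def _single_atom_index(traj: Trajectory, residue_seq: int, atom_name: str) -> int:
    topo = traj.topology
    hits = [
        i for i in topo.atom_indices_of_residue(residue_seq)
        if topo.atoms[i].name == atom_name
    ]
    if not hits:
        raise SelectionError(f"atom {atom_name} of residue {residue_seq} not found")
    return hits[0]


def hbond_series(
    traj: Trajectory,
    donor: tuple[int, str],
    acceptor: tuple[int, str],
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 150.0,
) -> HBondSeries:
    """Geometric hydrogen-bond presence over frames (3.5 A / 150 deg)."""
    d_idx = _single_atom_index(traj, *donor)
    a_idx = _single_atom_index(traj, *acceptor)
    topo = traj.topology
    h_idx = [
        i for i in topo.atom_indices_of_residue(donor[0])
        if topo.atoms[i].element == "H"
    ]
    d = traj.coordinates[:, d_idx]
    a = traj.coordinates[:, a_idx]
    dist_ok = np.linalg.norm(d - a, axis=1) <= distance_cutoff
    heavy_only = len(h_idx) == 0
    if heavy_only:
        present = dist_ok
    else:
        h = traj.coordinates[:, h_idx]              # F x nH x 3
        dh = np.linalg.norm(h - d[:, None], axis=2)  # F x nH
        bonded = dh <= 1.2
        # angle at H between H->D and H->A
        v1 = d[:, None] - h
        v2 = a[:, None] - h
        cosang = np.sum(v1 * v2, axis=2) / (
            np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2) + 1e-12
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ang_ok = np.any(bonded & (ang >= angle_cutoff), axis=1)
        present = dist_ok & ang_ok
    return HBondSeries(
        donor, acceptor, present, traj.times, distance_cutoff, angle_cutoff, heavy_only
    )


# --------------------------------------------------------------------------
# ligand contacts
# --------------------------------------------------------------------------

@dataclass
class ContactTable:
    """Per-residue contact occupancy with a ligand selection.

    ``occupancy[res]`` is the fraction of frames in which any heavy-atom
    pair (ligand, residue) is within ``cutoff``; ``snapshots`` lists the
    residues in contact at designated frames (e.g. initial/final).
    """

    ligand_label: str
    cutoff: float
    occupancy: dict[int, float]
    snapshots: dict[int, list[int]] = field(default_factory=dict)


def contact_occupancy(
    traj: Trajectory,
    ligand_selection: str,
    receptor_residues: list[int] | None = None,
    cutoff: float = 4.0,
    snapshot_frames: tuple[int, ...] | None = None,
    ligand_label: str = "ligand",
) -> ContactTable:
    """Heavy-atom contact occupancy between a ligand and receptor residues."""
    topo = traj.topology
    lig_idx = select_atoms(topo, f"( {ligand_selection} ) and heavy")
    if lig_idx.size == 0:
        raise SelectionError(f"ligand selection {ligand_selection!r} is empty")
    lig_set = set(lig_idx.tolist())
    if receptor_residues is None:
        receptor_residues = sorted(
            {
                a.residue_seq
                for i, a in enumerate(topo.atoms)
                if i not in lig_set and a.is_heavy and not topo.is_water(a)
            }
        )
    res_atom_idx: dict[int, np.ndarray] = {}
    for res in receptor_residues:
        idx = np.array(
            [
                i for i in topo.atom_indices_of_residue(res)
                if topo.atoms[i].is_heavy and i not in lig_set
            ]
        )
        if idx.size:
            res_atom_idx[res] = idx
    if snapshot_frames is None:
        snapshot_frames = (0, traj.n_frames - 1)

    counts = {res: 0 for res in res_atom_idx}
    snapshots: dict[int, list[int]] = {f: [] for f in snapshot_frames}
    for f in range(traj.n_frames):
        lig = traj.coordinates[f, lig_idx]
        for res, idx in res_atom_idx.items():
            dmin = cdist(lig, traj.coordinates[f, idx]).min()
            hit = bool(cutoff > 0) and dmin <= cutoff
            if hit:
                counts[res] += 1
                if f in snapshots:
                    snapshots[f].append(res)
    occ = {res: counts[res] / traj.n_frames for res in res_atom_idx}
    return ContactTable(ligand_label, cutoff, occ, snapshots)
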