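"""Water-shell occupancy and water-mediated bridges.

Counts water molecules whose oxygen lies within a cutoff (default 4 A,
the convention for conserved-residue hydration shells in GPCR work) of
any heavy atom of a target selection, and detects waters simultaneously
within the cutoff of two disjoint selections ("bridging" waters, the
geometric reading of solvent-mediated interactions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import SelectionError, Trajectory, select_atoms, selection_mask

__all__ = ["HydrationSeries", "BridgeSeries", "water_count_series", "bridging_waters"]


@dataclass
class HydrationSeries:
    """Per-frame water count in the shell of a target selection."""

    label: str
    cutoff: float
    counts: np.ndarray  # F non-negative integers
    times: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))


@dataclass
class BridgeSeries:
    """Per-frame bridging-water counts and identities.

    ``water_ids[f]`` holds (chain, residue_seq) of each bridging water.
    """

    label: str
    cutoff: float
    counts: np.ndarray
    water_ids: list[list[tuple[str, int]]]
    times: np.ndarray


def _water_oxygen_indices(traj: Trajectory) -> np.ndarray:
    topo = traj.topology
    return np.array(
        [
            i for i, a in enumerate(topo.atoms)
            if topo.is_water(a) and a.element == "O"
        ],
        dtype=int,
    )


def _target_heavy_indices(traj: Trajectory, selection: str) -> np.ndarray:
    topo = traj.topology
    mask = selection_mask(topo, selection)
    idx = np.array(
        [i for i in np.flatnonzero(mask) if topo.atoms[i].is_heavy and not topo.is_water(topo.atoms[i])],
        dtype=int,
    )
    if idx.size == 0:
        raise SelectionError(f"target selection {selection!r} has no heavy atoms")
    return idx


def water_count_series(
    traj: Trajectory,
    target_selection: str,
    cutoff: float = 4.0,
    label: str | None = None,
) -> HydrationSeries:
    """Count waters with oxygen within ``cutoff`` of any target heavy atom.

    Each water is counted once per frame regardless of how many target
    atoms it is close to.  A topology without waters yields an all-zero
    series and a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tgt_idx = _target_heavy_indices(traj, target_selection)
    wat_idx = _water_oxygen_indices(traj)
    label = label or target_selection
    counts = np.zeros(traj.n_frames, dtype=int)
    if wat_idx.size == 0:
        warnings.warn("topology contains no water residues; counts are all zero")
        return HydrationSeries(label, cutoff, counts, traj.times)
    for f in range(traj.n_frames):
        tree = cKDTree(traj.coordinates[f, tgt_idx])
        d, _ = tree.query(traj.coordinates[f, wat_idx], k=1)
        counts[f] = int(np.count_nonzero(d <= cutoff))
    return HydrationSeries(label, cutoff, counts, traj.times)


def bridging_waters(
    traj: Trajectory,
    selection_a: str,
    selection_b: str,
    cutoff: float = 4.0,
    label: str | None = None,
) -> BridgeSeries:
    """Waters whose oxygen is within ``cutoff`` of heavy atoms of both
    selections in the same frame.

    The two selections must be disjoint atom sets.
    """
    idx_a = _target_heavy_indices(traj, selection_a)
    idx_b = _target_heavy_indices(traj, selection_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("bridging selections overlap")
    wat_idx = _water_oxygen_indices(traj)
    label = label or f"{selection_a} | {selection_b}"
    topo = traj.topology
    counts = np.zeros(traj.n_frames, dtype=int)
    ids: list[list[tuple[str, int]]] = []
    for f in range(traj.n_frames):
        if wat_idx.size == 0:
            ids.append([])
            continue
        wat = traj.coordinates[f, wat_idx]
        da, _ = cKDTree(traj.coordinates[f, idx_a]).query(wat, k=1)
        db, _ = cKDTree(traj.coordinates[f, idx_b]).query(wat, k=1)
        bridge = (da <= cutoff) & (db <= cutoff)
        counts[f] = int(np.count_nonzero(bridge))
        ids.append(
            [
                (topo.atoms[wat_idx[j]].chain, topo.atoms[wat_idx[j]].residue_seq)
                for j in np.flatnonzero(bridge)
            ]
        )
    return BridgeSeries(label, cutoff, counts, ids, traj.times)
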