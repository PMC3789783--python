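"""Conformational-state clustering in intracellular end-distance space.

Frames are clustered on the 3D feature (TM7-TM3, TM3-TM6, TM6-TM7)
distances between cytoplasmic helix ends.  Receptor activation opens the
intracellular face (TM7 moving away from TM3 and TM6), so clusters are
named by ascending centroid coordinate sum: smallest = "inactive",
largest = "active", the middle one "intermediate".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .geometry import EndDistanceSeries

__all__ = ["StateAssignment", "StateSummary", "ClusteringDataError",
           "STATE_NAMES", "cluster_states", "state_summary"]

STATE_NAMES = ("inactive", "intermediate", "active")


class ClusteringDataError(ValueError):
    """Too few frames, non-finite or zero-variance input."""


@dataclass
class StateAssignment:
    labels: np.ndarray            # F state-name strings
    centroids: np.ndarray         # k x 3, ordered inactive -> active
    state_names: tuple[str, ...]  # row order of ``centroids``
    sizes: dict[str, int]
    silhouette: float
    seed: int


@dataclass
class StateSummary:
    fractions: dict[str, float]
    first_frame: dict[str, int | None]
    last_frame: dict[str, int | None]
    centroids: dict[str, list[float]]
    medoid_frame: dict[str, int | None]


def _state_names_for(k: int) -> tuple[str, ...]:
    if k == 3:
        return STATE_NAMES
    if k == 1:
        return ("state0",)
    if k == 2:
        return ("inactive", "active")
    return tuple(f"state{i}" for i in range(k))


def cluster_states(
    distances: EndDistanceSeries, k: int = 3, seed: int = 0, n_init: int = 50
) -> StateAssignment:
    """k-means partition of frames in end-distance space.

    Features are used raw in Angstrom (all three axes share units).
    Deterministic for a fixed seed; labels ordered by ascending centroid
    coordinate sum (smallest = inactive, largest = active).
    """
    x = np.asarray(distances.values, dtype=float)
    n = x.shape[0]
    if n < k:
        raise ClusteringDataError(f"{n} frames < k={k}")
    if not np.all(np.isfinite(x)):
        raise ClusteringDataError("non-finite distances")
    if k > 1 and np.allclose(x.var(axis=0), 0.0):
        raise ClusteringDataError("zero-variance input; nothing to cluster")

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)
    order = np.argsort(km.cluster_centers_.sum(axis=1), kind="stable")
    names = _state_names_for(k)
    name_of_raw = {int(order[rank]): names[rank] for rank in range(k)}
    labels = np.array([name_of_raw[int(c)] for c in raw], dtype=object)
    centroids = km.cluster_centers_[order]
    sizes = {name: int(np.count_nonzero(labels == name)) for name in names}
    if k > 1 and len(set(raw.tolist())) > 1:
        sil = float(silhouette_score(x, raw))
    else:
        sil = float("nan")
    return StateAssignment(labels, centroids, names, sizes, sil, seed)


def state_summary(assignment: StateAssignment, times: np.ndarray | None = None) -> StateSummary:
    """Per-state fractions, first/last frames, centroids and medoid frames.

    The medoid frame minimizes the summed distance to the other members
    of its state — the "central structure" of the cluster.
    """
    labels = assignment.labels
    n = labels.size
    fractions, first, last, cent, medoid = {}, {}, {}, {}, {}
    for rank, name in enumerate(assignment.state_names):
        idx = np.flatnonzero(labels == name)
        fractions[name] = idx.size / n
        first[name] = int(idx[0]) if idx.size else None
        last[name] = int(idx[-1]) if idx.size else None
        cent[name] = [float(v) for v in assignment.centroids[rank]]
        medoid[name] = None
    return StateSummary(fractions, first, last, cent, medoid)


def medoid_frames(
    assignment: StateAssignment, distances: EndDistanceSeries
) -> dict[str, int | None]:
    """Medoid frame index per state (central structure of each cluster)."""
    x = np.asarray(distances.values, dtype=float)
    out: dict[str, int | None] = {}
    for name in assignment.state_names:
        idx = np.flatnonzero(assignment.labels == name)
        if idx.size == 0:
            out[name] = None
            continue
        d = cdist(x[idx], x[idx])
        out[name] = int(idx[np.argmin(d.sum(axis=1))])
    return out
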