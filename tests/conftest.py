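"""Shared fixtures: micro-topologies built in memory and the synthetic
fixture suite written once per session."""

from __future__ import annotations

import numpy as np
import pytest

from gpcrtraj.synthetic_data import (
    DEFAULT_FIXTURE_SEED,
    build_bundle,
    fixture_specs,
    write_fixture_suite,
)
from gpcrtraj.trajectory_io import AtomRecord, Topology, Trajectory


def make_topology(atom_specs, water_names=None):
    """atom_specs: (name, res_name, res_seq, chain, element) tuples."""
    records = [
        AtomRecord(
            serial=i + 1, name=name, residue_name=res_name,
            residue_seq=res_seq, chain=chain, element=element,
        )
        for i, (name, res_name, res_seq, chain, element) in enumerate(atom_specs)
    ]
    if water_names is not None:
        return Topology(records, water_residue_names=frozenset(water_names))
    return Topology(records)


def make_trajectory(atom_specs, coords, times=None, water_names=None):
    topo = make_topology(atom_specs, water_names)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(topo, coords, times)


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory):
    """Small (120-frame) fixture suite on disk, one build per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return write_fixture_suite(out, seed=DEFAULT_FIXTURE_SEED, n_frames=120)


@pytest.fixture(scope="session")
def agonist_700():
    """Full-length agonist-like bundle (700 frames, sigma 0.2 A) in memory."""
    spec = fixture_specs(seed=DEFAULT_FIXTURE_SEED, n_frames=700, noise_sigma=0.2)[
        "agonist"
    ]
    return build_bundle(spec)
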