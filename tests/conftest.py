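"""Shared fixtures: tiny synthetic replica sets and hand-built trajectories."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import ionbind as ib
from ionbind.synthetic import (
    GATE_ANCHOR_A,
    GATE_ANCHOR_B,
    NA1_SELECTION,
    NA2_SELECTION,
    SyntheticConfig,
    generate_replica_set,
)
from ionbind.traj_core import Topology, Trajectory


def small_config(**overrides) -> SyntheticConfig:
    """A fast hybrid study: 150 ns replicas at coarse frame spacing."""
    params = dict(n_replicas=8, duration=150.0, dt_frame=0.1, n_ions=5, seed=11)
    params.update(overrides)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # concentration bookkeeping warning
        return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def hybrid_set():
    cfg = small_config()
    replica_set, truth = generate_replica_set(cfg)
    return cfg, replica_set, truth


@pytest.fixture(scope="session")
def detections(hybrid_set):
    """Gate/site definitions plus the detected event table for hybrid_set."""
    cfg, replica_set, truth = hybrid_set
    top = replica_set.topology
    gate = ib.GateDefinition(
        anchor_a=ib.select_atoms(top, GATE_ANCHOR_A),
        anchor_b=ib.select_atoms(top, GATE_ANCHOR_B),
    )
    sites = [
        ib.SiteDefinition(name="NA1", coordinating=ib.select_atoms(top, NA1_SELECTION)),
        ib.SiteDefinition(name="NA2", coordinating=ib.select_atoms(top, NA2_SELECTION)),
    ]
    ions = ib.select_ions(top)
    table = ib.build_event_table(
        replica_set.trajectories, gate, sites, ions, n_replicas=cfg.n_replicas
    )
    return gate, sites, ions, table


def static_site_topology() -> Topology:
    """Three coordinating atoms plus one ion, for scripted-path tests."""
    return Topology(
        atom_names=np.array(["O", "O", "O", "NA"], dtype=object),
        residue_names=np.array(["GLY", "VAL", "LEU", "NA"], dtype=object),
        residue_numbers=np.array([94, 97, 434, 1001]),
        elements=np.array(["O", "O", "O", "NA"], dtype=object),
        masses=np.array([15.999, 15.999, 15.999, 22.99]),
    )


def scripted_trajectory(ion_path: np.ndarray, dt: float = 0.1,
                        site_center=(0.0, 0.0, 0.0)) -> Trajectory:
    """Trajectory with 3 static coordinating atoms (centroid = site_center,
    circumradius 0.2 nm) and one ion following ``ion_path`` (n_frames, 3)."""
    n = len(ion_path)
    c = np.asarray(site_center, dtype=float)
    tri = 0.2 * np.array(
        [[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0], [-0.5, -np.sqrt(3) / 2, 0]]
    )
    pos = np.empty((n, 4, 3))
    pos[:, :3, :] = c + tri
    pos[:, 3, :] = ion_path
    return Trajectory(
        replica_id=0,
        times=np.arange(n) * dt,
        positions=pos + 5.0,  # keep everything inside a positive box
        box=np.array([10.0, 10.0, 10.0]),
    )
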