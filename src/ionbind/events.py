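"""Censoring-aware discrete event detection on replica trajectories.

Geometry is converted into per-ion, per-site interval records: vestibule
entry (plane-plus-cylinder gate predicate), transient and deep site
occupancy (hysteresis thresholds on the distance to the coordinating-atom
centroid), binding order statistics, and chloride release.  Censoring is
explicit: an interval still open at the final frame carries
``censored=True`` and ``exit_time=None``, never a sentinel time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .traj_core import AtomSelection, SelectionError, Topology, Trajectory

__all__ = [
    "GateDefinition",
    "SiteDefinition",
    "BindingEvent",
    "EventTable",
    "detect_vestibule_entries",
    "detect_site_occupancy",
    "first_binding_times",
    "binding_order_counts",
    "detect_release",
    "build_event_table",
]

VESTIBULE = "VESTIBULE"


@dataclass(frozen=True)
class GateDefinition:
    """The vestibule membership predicate.

    An ion is inside iff its projection on ``vestibule_axis`` lies beyond
    the midpoint plane of the two gate anchors (on the intracellular side)
    and its lateral distance from the axis through that midpoint is at most
    ``lateral_radius``.  The salt-bridge "structural cut-off" of the study
    is thus realised as a testable geometric predicate.
    """

    anchor_a: AtomSelection
    anchor_b: AtomSelection
    vestibule_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    lateral_radius: float = 1.2       # nm
    min_dwell: float = 0.0            # ns; 0 = any crossing counts

    def __post_init__(self) -> None:
        if self.anchor_a.n_atoms != 1 or self.anchor_b.n_atoms != 1:
            raise SelectionError("gate anchors must each resolve to exactly one atom")
        if self.lateral_radius <= 0:
            raise ValueError("lateral_radius must be > 0")
        axis = np.asarray(self.vestibule_axis, dtype=float)
        n = np.linalg.norm(axis)
        if not np.isfinite(n) or n == 0:
            raise ValueError("vestibule_axis must be a nonzero vector")

    @property
    def axis(self) -> np.ndarray:
        a = np.asarray(self.vestibule_axis, dtype=float)
        return a / np.linalg.norm(a)


@dataclass(frozen=True)
class SiteDefinition:
    """A binding site with hysteresis cutoffs on the centroid distance."""

    name: str
    coordinating: AtomSelection
    entry_cutoff: float = 0.30        # nm
    exit_cutoff: float = 0.50         # nm
    min_dwell: float = 1.0            # ns

    def __post_init__(self) -> None:
        if self.coordinating.n_atoms == 0:
            raise SelectionError(f"site {self.name}: empty coordinating selection")
        if not self.exit_cutoff > self.entry_cutoff:
            raise ValueError(
                f"site {self.name}: exit_cutoff must exceed entry_cutoff (hysteresis)"
            )
        if self.min_dwell < 0:
            raise ValueError(f"site {self.name}: min_dwell must be >= 0")


@dataclass(frozen=True)
class BindingEvent:
    """One maximal occupancy interval; ``exit_time=None`` iff censored."""

    replica_id: int
    ion_id: int
    site_name: str
    entry_time: float
    exit_time: Optional[float]

    @property
    def censored(self) -> bool:
        return self.exit_time is None

    def __post_init__(self) -> None:
        if self.exit_time is not None and not self.entry_time < self.exit_time:
            raise ValueError("entry_time must precede exit_time")


@dataclass
class EventTable:
    """All events of a replica set, sorted by (replica_id, entry_time)."""

    events: list[BindingEvent]
    n_replicas: int
    duration: float

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.replica_id, e.entry_time))

    def for_site(self, site_name: str) -> list[BindingEvent]:
        return [e for e in self.events if e.site_name == site_name]

    @property
    def site_names(self) -> list[str]:
        return sorted({e.site_name for e in self.events})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replica_id": [e.replica_id for e in self.events],
                "ion_id": [e.ion_id for e in self.events],
                "site": [e.site_name for e in self.events],
                "entry_ns": [e.entry_time for e in self.events],
                "exit_ns": [e.exit_time if e.exit_time is not None else np.nan
                            for e in self.events],
                "censored": [e.censored for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "schema": "ionbind.events/1",
            "n_replicas": self.n_replicas,
            "duration": self.duration,
            "events": [
                {
                    "replica_id": e.replica_id,
                    "ion_id": e.ion_id,
                    "site": e.site_name,
                    "entry_ns": e.entry_time,
                    "exit_ns": e.exit_time,
                }
                for e in self.events
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_csv(cls, path: str | Path, n_replicas: int, duration: float) -> "EventTable":
        df = pd.read_csv(path)
        events = [
            BindingEvent(
                replica_id=int(r.replica_id),
                ion_id=int(r.ion_id),
                site_name=str(r.site),
                entry_time=float(r.entry_ns),
                exit_time=None if pd.isna(r.exit_ns) else float(r.exit_ns),
            )
            for r in df.itertuples()
        ]
        return cls(events=events, n_replicas=n_replicas, duration=duration)


# ---------------------------------------------------------------------------
# Interval machinery
# ---------------------------------------------------------------------------

def _intervals_from_mask(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal True runs of a boolean series.

    Returns (start_frame, end_frame, censored): ``end_frame`` is the first
    frame *outside* the run; censored runs extend to the final frame.
    """
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    out = []
    n = len(mask)
    for s, e in zip(starts, ends):
        out.append((int(s), int(e), e == n))
    return out


def _hysteresis_mask(dist: np.ndarray, entry: float, exit_: float) -> np.ndarray:
    """Sticky occupancy: turn on below ``entry``, off only above ``exit_``."""
    state = np.where(dist < entry, 1, np.where(dist > exit_, 0, -1))
    known = state >= 0
    idx = np.where(known, np.arange(len(state)), -1)
    idx = np.maximum.accumulate(idx)
    filled = np.where(idx >= 0, state[np.maximum(idx, 0)], 0)
    return filled.astype(bool)


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_vestibule_entries(
    trajectory: Trajectory,
    gate: GateDefinition,
    ion_selection: AtomSelection,
) -> list[BindingEvent]:
    """One event per maximal inside-interval of each selected ion."""
    axis = gate.axis
    ia = int(gate.anchor_a.indices[0])
    ib = int(gate.anchor_b.indices[0])
    mid = 0.5 * (trajectory.positions[:, ia, :] + trajectory.positions[:, ib, :])

    events: list[BindingEvent] = []
    dt = trajectory.dt
    min_frames = int(np.ceil(gate.min_dwell / dt)) if gate.min_dwell > 0 else 1
    for j in ion_selection.indices:
        rel = trajectory.positions[:, j, :] - mid
        axial = rel @ axis
        lateral = np.linalg.norm(rel - axial[:, None] * axis[None, :], axis=1)
        inside = (axial > 0) & (lateral <= gate.lateral_radius)
        for s, e, censored in _intervals_from_mask(inside):
            if (e - s) < min_frames and not censored:
                continue
            events.append(
                BindingEvent(
                    replica_id=trajectory.replica_id,
                    ion_id=int(j),
                    site_name=VESTIBULE,
                    entry_time=float(trajectory.times[s]),
                    exit_time=None if censored else float(trajectory.times[e]),
                )
            )
    return events


def site_centroid_series(trajectory: Trajectory, site: SiteDefinition) -> np.ndarray:
    """Per-frame unweighted centroid of the coordinating atoms (n_frames, 3)."""
    return trajectory.positions[:, site.coordinating.indices, :].mean(axis=1)


def detect_site_occupancy(
    trajectory: Trajectory,
    site: SiteDefinition,
    ion_selection: AtomSelection,
) -> list[BindingEvent]:
    """Hysteresis occupancy of one site for each selected ion.

    Entry when the ion-to-centroid distance drops below ``entry_cutoff``
    and stays occupied (never beyond ``exit_cutoff``) for at least
    ``min_dwell``; intervals censored at the final frame are kept even if
    their observed dwell is shorter (the dwell is unresolved).
    """
    centroid = site_centroid_series(trajectory, site)
    dt = trajectory.dt
    min_frames = int(np.ceil(site.min_dwell / dt)) if site.min_dwell > 0 else 1
    events: list[BindingEvent] = []
    for j in ion_selection.indices:
        dist = np.linalg.norm(trajectory.positions[:, j, :] - centroid, axis=1)
        occupied = _hysteresis_mask(dist, site.entry_cutoff, site.exit_cutoff)
        for s, e, censored in _intervals_from_mask(occupied):
            if (e - s) < min_frames and not censored:
                continue
            events.append(
                BindingEvent(
                    replica_id=trajectory.replica_id,
                    ion_id=int(j),
                    site_name=site.name,
                    entry_time=float(trajectory.times[s]),
                    exit_time=None if censored else float(trajectory.times[e]),
                )
            )
    return events


def first_binding_times(
    table: EventTable, site_name: str
) -> list[Optional[float]]:
    """Per replica, the earliest entry time for a site (None = censored)."""
    if site_name not in table.site_names and not any(
        e.site_name == site_name for e in table.events
    ):
        # an empty table for this site is only an error if the name is
        # unknown to the table's universe of sites; distinguishable tables
        # carry no registry, so an entirely absent name is treated as error
        raise KeyError(f"site {site_name!r} has no events in this table")
    firsts: list[Optional[float]] = [None] * table.n_replicas
    for e in table.events:
        if e.site_name != site_name:
            continue
        if e.replica_id >= table.n_replicas:
            raise ValueError(f"event replica_id {e.replica_id} out of range")
        t = firsts[e.replica_id]
        if t is None or e.entry_time < t:
            firsts[e.replica_id] = e.entry_time
    return firsts


ORDER_CATEGORIES = ("NA2_first", "NA1_first", "tie", "only_NA1", "only_NA2", "neither")


def binding_order_counts(table: EventTable) -> dict[str, int]:
    """Partition replicas into six exclusive binding-order categories.

    Equal first times land in ``tie`` (never broken randomly), so the
    counts are deterministic and always sum to ``n_replicas``.
    """
    try:
        t1s = first_binding_times(table, "NA1")
    except KeyError:
        t1s = [None] * table.n_replicas
    try:
        t2s = first_binding_times(table, "NA2")
    except KeyError:
        t2s = [None] * table.n_replicas
    counts = {k: 0 for k in ORDER_CATEGORIES}
    for t1, t2 in zip(t1s, t2s):
        if t1 is None and t2 is None:
            counts["neither"] += 1
        elif t2 is None:
            counts["only_NA1"] += 1
        elif t1 is None:
            counts["only_NA2"] += 1
        elif t1 == t2:
            counts["tie"] += 1
        elif t2 < t1:
            counts["NA2_first"] += 1
        else:
            counts["NA1_first"] += 1
    return counts


def detect_release(
    trajectory: Trajectory,
    site: SiteDefinition,
    via_site: SiteDefinition,
    ion_selection: AtomSelection,
    via_window: float = 1.0,
) -> list[tuple[float, bool]]:
    """Release events of an initially bound ion, with the escape route.

    ``passed_via`` is True iff the ion comes within the via site's entry
    cutoff of its centroid during the ``via_window`` (ns) after release.
    The selected ion must start within ``site.entry_cutoff``.
    """
    centroid = site_centroid_series(trajectory, site)
    via_centroid = site_centroid_series(trajectory, via_site)
    out: list[tuple[float, bool]] = []
    for j in ion_selection.indices:
        dist = np.linalg.norm(trajectory.positions[:, j, :] - centroid, axis=1)
        if dist[0] >= site.entry_cutoff:
            raise ValueError(
                f"ion {j} not initially bound to {site.name} "
                f"(d0={dist[0]:.3f} nm >= {site.entry_cutoff} nm)"
            )
        occupied = _hysteresis_mask(dist, site.entry_cutoff, site.exit_cutoff)
        via_dist = np.linalg.norm(trajectory.positions[:, j, :] - via_centroid, axis=1)
        for s, e, censored in _intervals_from_mask(occupied):
            if censored:
                continue
            release_time = float(trajectory.times[e])
            in_window = (trajectory.times > release_time) & (
                trajectory.times <= release_time + via_window
            )
            passed = bool(np.any(via_dist[in_window] < via_site.entry_cutoff))
            out.append((release_time, passed))
    return out


def build_event_table(
    trajectories: Sequence[Trajectory],
    gate: Optional[GateDefinition],
    sites: Sequence[SiteDefinition],
    ion_selection: AtomSelection,
    n_replicas: Optional[int] = None,
) -> EventTable:
    """Run all detectors over every replica and collect one table."""
    events: list[BindingEvent] = []
    duration = 0.0
    for traj in trajectories:
        duration = max(duration, float(traj.times[-1]))
        if gate is not None:
            events.extend(detect_vestibule_entries(traj, gate, ion_selection))
        for site in sites:
            events.extend(detect_site_occupancy(traj, site, ion_selection))
    if n_replicas is None:
        n_replicas = 1 + max((t.replica_id for t in trajectories), default=-1)
    return EventTable(events=events, n_replicas=n_replicas, duration=duration)
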