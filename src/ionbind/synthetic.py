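"""Synthetic replica-set generator with exact ground truth.

Emulates the statistical structure of a sodium-binding replica study on an
outward-open SLC6 transporter: many short independent trajectories at fixed
bulk ion concentration, a gated outer vestibule, a transient engagement site
at the extracellular gate, a second transient site in the substrate pocket,
and two deep sodium sites (NA1 faster than NA2) that do not release on the
simulated timescale.  Coordinating pseudo-atoms compact upon binding
(induced fit).

Two modes:

``hybrid``
    Binding times are exact exponential draws; ions are rendered onto
    scripted approach paths so that event detection must recover the drawn
    times.  This is the mode with analytically known kinetics, used for
    parameter-recovery studies.

``spatial``
    Non-interacting overdamped-Langevin ions in a smooth attractive
    potential with absorbing deep-site capture.  Geometrically honest
    (density, displacement, entry paths emerge from the dynamics) but the
    effective association rate is emergent, not configured.

All coordinates nm, times ns, energies kT, rates ns^-1 internally;
``k_on_true`` is accepted in M^-1 s^-1 like the reported quantity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .traj_core import (
    Frame,
    IntegrityError,
    ReplicaSet,
    Topology,
    Trajectory,
)

__all__ = [
    "VestibulePotential",
    "SiteSpec",
    "GeometryProcessSpec",
    "ChlorideSpec",
    "SyntheticConfig",
    "ReplicaGroundTruth",
    "SyntheticGroundTruth",
    "ConfigError",
    "IntegrationError",
    "generate_replica_set",
    "step_langevin",
    "evolve_site_geometry",
    "build_topology",
    "write_replica",
    "write_replica_set",
    "load_ground_truth",
    "rate_from_kon",
    "kon_from_rate",
    "draw_ground_truth",
]

AVOGADRO_PER_NM3_M = 0.6022140761  # N_A * (1 nm^3 in L) ; ions per nm^3 per molar


class ConfigError(ValueError):
    """Invalid or geometrically infeasible synthetic configuration."""


class IntegrationError(RuntimeError):
    """The Langevin integrator produced a non-finite coordinate."""


def rate_from_kon(k_on: float, concentration: float) -> float:
    """Bimolecular k_on (M^-1 s^-1) -> pseudo-first-order rate (ns^-1)."""
    return k_on * concentration * 1e-9


def kon_from_rate(b: float, concentration: float) -> float:
    """Pseudo-first-order rate (ns^-1) -> bimolecular k_on (M^-1 s^-1)."""
    return b * 1e9 / concentration


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class VestibulePotential:
    """Smooth attractive field standing in for the vestibule electrostatics.

    A single Gaussian well centred on the vestibule axis below the gate;
    depth in kT.  This is a phenomenological stand-in with a known force
    field, not an electrostatics model.
    """

    funnel_depth: float = 6.0            # kT
    funnel_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    gate_z: float = 3.2                  # nm, plane of the gate anchors
    vestibule_radius: float = 0.8        # nm, lateral width of the well
    smoothing_length: float = 0.7        # nm, axial width of the well

    def __post_init__(self) -> None:
        if self.funnel_depth < 0:
            raise ConfigError("funnel_depth must be >= 0")
        if self.vestibule_radius <= 0 or self.smoothing_length <= 0:
            raise ConfigError("potential length scales must be > 0")


@dataclass
class SiteSpec:
    """One binding site: deep (NA1/NA2, absorbing) or transient (GATE/S1)."""

    name: str
    center: tuple[float, float, float]
    capture_radius: float = 0.3          # nm
    k_on_true: Optional[float] = None    # M^-1 s^-1, hybrid mode, deep sites
    well_depth: Optional[float] = None   # kT, spatial mode
    mean_dwell: Optional[float] = None   # ns, transient sites only

    def __post_init__(self) -> None:
        if self.capture_radius <= 0:
            raise ConfigError(f"site {self.name}: capture_radius must be > 0")

    @property
    def is_deep(self) -> bool:
        return self.name in ("NA1", "NA2")


@dataclass
class GeometryProcessSpec:
    """Ornstein-Uhlenbeck coordinating-atom shell that compacts on binding.

    Each coordinating pseudo-atom fluctuates about an anchor placed at
    radius R(t) from the site centre along a fixed symmetric direction set;
    R(t) relaxes exponentially from ``mean_radius_apo`` to
    ``mean_radius_bound`` after the binding time.  The positional noise
    amplitude relaxes from ``positional_stddev`` to
    ``positional_stddev_bound`` on the same clock, emulating the observed
    rigidification of the bound site.
    """

    n_coordinating: int = 6
    mean_radius_apo: float = 0.35        # nm
    mean_radius_bound: float = 0.25      # nm
    relaxation_time: float = 2.0         # ns, anchor relaxation after binding
    positional_stddev: float = 0.04      # nm, apo OU stationary sd per axis
    positional_stddev_bound: float = 0.02
    ou_timescale: float = 0.2            # ns, OU correlation time

    def __post_init__(self) -> None:
        if not self.mean_radius_apo > self.mean_radius_bound > 0:
            raise ConfigError("need mean_radius_apo > mean_radius_bound > 0")
        if self.n_coordinating < 2:
            raise ConfigError("n_coordinating must be >= 2")
        if self.positional_stddev < 0 or self.positional_stddev_bound < 0:
            raise ConfigError("positional stddevs must be >= 0")
        if self.ou_timescale <= 0 or self.relaxation_time < 0:
            raise ConfigError("timescales must be positive")


@dataclass
class ChlorideSpec:
    """Optional bound chloride that may escape through the NA1 region."""

    enabled: bool = False
    escape_rate: float = 0.002           # ns^-1
    via_na1: bool = True                 # escape path passes through NA1


def _default_sites() -> list[SiteSpec]:
    # Centres are in the canonical synthetic layout (box-centred xy axis,
    # gate plane at z = 3.2 nm); k_on defaults are the study-scale values.
    return [
        SiteSpec("GATE", (0.0, 0.0, 3.0), capture_radius=0.3, mean_dwell=1.0),
        SiteSpec("S1", (0.0, 0.0, 2.5), capture_radius=0.3, mean_dwell=2.0),
        SiteSpec("NA1", (0.35, 0.0, 2.0), capture_radius=0.3,
                 k_on_true=4.2e7, well_depth=8.0),
        SiteSpec("NA2", (-0.35, 0.0, 2.0), capture_radius=0.3,
                 k_on_true=1.9e7, well_depth=8.0),
    ]


def _default_geometry() -> dict[str, GeometryProcessSpec]:
    return {
        "NA1": GeometryProcessSpec(n_coordinating=6, mean_radius_apo=0.35,
                                   mean_radius_bound=0.25),
        "NA2": GeometryProcessSpec(n_coordinating=3, mean_radius_apo=0.32,
                                   mean_radius_bound=0.26),
    }


@dataclass
class SyntheticConfig:
    """Full description of a synthetic replica study.

    Defaults mirror the emulated study design: 51 replicas of 150 ns at
    150 mM NaCl with frames every 5 ps.  ``entry_rate`` is the per-replica
    pseudo-first-order vestibule entry rate (default ln2 / 5.7 ns).
    """

    mode: str = "hybrid"                 # {"hybrid", "spatial"}
    n_replicas: int = 51
    duration: float = 150.0              # ns
    dt_frame: float = 0.005              # ns (5 ps)
    box: tuple[float, float, float] = (6.0, 6.0, 6.0)   # nm
    n_ions: int = 20
    concentration: float = 0.15          # molar
    diffusion_coeff: float = 1.3         # nm^2/ns, free Na+ in water
    entry_rate: float = float(np.log(2) / 5.7)          # ns^-1
    potential: VestibulePotential = field(default_factory=VestibulePotential)
    sites: list[SiteSpec] = field(default_factory=_default_sites)
    geometry: dict[str, GeometryProcessSpec] = field(default_factory=_default_geometry)
    chloride: ChlorideSpec = field(default_factory=ChlorideSpec)
    order_coupling: bool = False         # NA1 capture conditional on NA2
    dt_integration: float = 0.0005       # ns, spatial-mode Langevin step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("hybrid", "spatial"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_replicas < 1:
            raise ConfigError("n_replicas must be >= 1")
        if self.duration <= 0 or self.dt_frame <= 0:
            raise ConfigError("duration and dt_frame must be > 0")
        n_steps = self.duration / self.dt_frame
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigError("duration must be an integral multiple of dt_frame")
        if self.dt_integration > self.dt_frame + 1e-12:
            raise ConfigError("dt_integration must be <= dt_frame")
        box = np.asarray(self.box, dtype=float)
        if np.any(box <= 0):
            raise ConfigError("box edges must be > 0")
        for s in self.sites:
            c = self._site_xyz(s)
            if np.any(c < 0) or np.any(c > box):
                raise ConfigError(f"site {s.name} lies outside the box")
        if self.concentration <= 0:
            raise ConfigError("concentration must be > 0")
        expected = self.n_ions / (AVOGADRO_PER_NM3_M * float(np.prod(box)))
        if self.n_ions > 0 and abs(expected - self.concentration) > 0.05 * self.concentration:
            warnings.warn(
                f"n_ions={self.n_ions} in box {tuple(box)} nm is {expected:.4f} M, "
                f"more than 5% from configured {self.concentration} M",
                stacklevel=2,
            )

    # site centres are stored relative to the vestibule axis; the axis runs
    # through the xy centre of the box
    def _site_xyz(self, site: SiteSpec) -> np.ndarray:
        cx, cy = self.box[0] / 2.0, self.box[1] / 2.0
        c = np.asarray(site.center, dtype=float)
        return np.array([cx + c[0], cy + c[1], c[2]])

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt_frame)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_frame

    def site(self, name: str) -> SiteSpec:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    def has_site(self, name: str) -> bool:
        return any(s.name == name for s in self.sites)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class ReplicaGroundTruth:
    """Exact generated event times for one replica (None = censored)."""

    replica_id: int
    entry_times: list[float]
    first_entry_time: Optional[float]
    site_first_binding: dict[str, Optional[float]]
    chloride_release_time: Optional[float] = None

    @property
    def binding_order(self) -> str:
        t1 = self.site_first_binding.get("NA1")
        t2 = self.site_first_binding.get("NA2")
        if t1 is None and t2 is None:
            return "neither"
        if t1 is None:
            return "only_NA2"
        if t2 is None:
            return "only_NA1"
        if t1 == t2:
            return "tie"
        return "NA2_first" if t2 < t1 else "NA1_first"


@dataclass
class SyntheticGroundTruth:
    """Generating rates plus per-replica exact event times; the oracle."""

    seed: int
    mode: str
    duration: float
    dt_frame: float
    concentration: float
    generating_rates: dict[str, float]   # ns^-1, pseudo-first-order
    replicas: list[ReplicaGroundTruth]

    def first_binding_times(self, site_name: str) -> list[Optional[float]]:
        return [r.site_first_binding.get(site_name) for r in self.replicas]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "schema": "ionbind.ground_truth/1",
            "seed": self.seed,
            "mode": self.mode,
            "duration": self.duration,
            "dt_frame": self.dt_frame,
            "concentration": self.concentration,
            "generating_rates": self.generating_rates,
            "replicas": [
                {
                    "replica_id": r.replica_id,
                    "entry_times": r.entry_times,
                    "first_entry_time": r.first_entry_time,
                    "site_first_binding": r.site_first_binding,
                    "chloride_release_time": r.chloride_release_time,
                }
                for r in self.replicas
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def load_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    data = json.loads(Path(path).read_text())
    if data.get("schema") != "ionbind.ground_truth/1":
        raise IntegrityError(f"unknown ground-truth schema in {path}")
    return SyntheticGroundTruth(
        seed=data["seed"],
        mode=data["mode"],
        duration=data["duration"],
        dt_frame=data["dt_frame"],
        concentration=data["concentration"],
        generating_rates=data["generating_rates"],
        replicas=[
            ReplicaGroundTruth(
                replica_id=r["replica_id"],
                entry_times=r["entry_times"],
                first_entry_time=r["first_entry_time"],
                site_first_binding=r["site_first_binding"],
                chloride_release_time=r.get("chloride_release_time"),
            )
            for r in data["replicas"]
        ],
    )


# ---------------------------------------------------------------------------
# Synthetic topology
# ---------------------------------------------------------------------------

# fixed protein pseudo-atom layout: (atom_name, residue_name, residue_number)
_NA1_ATOMS = [("O", "ALA", 96), ("CG", "ASP", 98), ("OD1", "ASN", 101),
              ("O", "SER", 336), ("OG", "SER", 336), ("OD1", "ASN", 368)]
_NA2_ATOMS = [("O", "GLY", 94), ("O", "VAL", 97), ("O", "LEU", 434)]
_GATE_ATOMS = [("CZ", "ARG", 104), ("CD", "GLU", 493)]
_N_SCAFFOLD = 8

#: canonical selection expressions for the synthetic topology
NA1_SELECTION = "96:O, 98:CG, 101:OD1, 336:O, 336:OG, 368:OD1"
NA2_SELECTION = "94:O, 97:O, 434:O"
GATE_ANCHOR_A = "104:CZ"
GATE_ANCHOR_B = "493:CD"

_OCTAHEDRON = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
_TRIANGLE = np.array([[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
                      [-0.5, -np.sqrt(3) / 2, 0]], dtype=float)


def _direction_set(n: int) -> np.ndarray:
    """Symmetric unit directions summing to zero (so the centroid stays put)."""
    if n == 6:
        return _OCTAHEDRON.copy()
    if n == 3:
        return _TRIANGLE.copy()
    angles = 2 * np.pi * np.arange(n) / n
    return np.stack([np.cos(angles), np.sin(angles), np.zeros(n)], axis=1)


def build_topology(config: SyntheticConfig) -> Topology:
    """Synthetic SERT-like topology: scaffold Cα ring, gate anchors,
    NA1/NA2 coordinating atoms, sodium ions and an optional chloride."""
    names: list[str] = []
    resnames: list[str] = []
    resnums: list[int] = []
    for i in range(_N_SCAFFOLD):
        names.append("CA")
        resnames.append("GLY")
        resnums.append(i + 1)
    for name, resname, resnum in _GATE_ATOMS + _NA1_ATOMS + _NA2_ATOMS:
        names.append(name)
        resnames.append(resname)
        resnums.append(resnum)
    for i in range(config.n_ions):
        names.append("NA")
        resnames.append("NA")
        resnums.append(1001 + i)
    if config.chloride.enabled:
        names.append("CL")
        resnames.append("CL")
        resnums.append(2001)
    elements = []
    for nm, rn in zip(names, resnames):
        elements.append(nm if rn in ("NA", "CL") else ("C" if nm[0] == "C" else nm[0]))
    from .traj_core import _MASSES, _DEFAULT_MASS
    masses = np.array([_MASSES.get(e, _DEFAULT_MASS) for e in elements])
    return Topology(
        atom_names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_numbers=np.array(resnums, dtype=int),
        elements=np.array(elements, dtype=object),
        masses=masses,
    )


def _protein_layout(config: SyntheticConfig) -> np.ndarray:
    """Static positions of scaffold + anchor atoms (nm, box coordinates)."""
    cx, cy = config.box[0] / 2.0, config.box[1] / 2.0
    gz = config.potential.gate_z
    pos = np.zeros((_N_SCAFFOLD + 2, 3))
    ring_r = 1.6
    zs = np.linspace(1.8, 3.4, _N_SCAFFOLD)
    for i in range(_N_SCAFFOLD):
        ang = 2 * np.pi * i / _N_SCAFFOLD
        pos[i] = [cx + ring_r * np.cos(ang), cy + ring_r * np.sin(ang), zs[i]]
    pos[_N_SCAFFOLD] = [cx + 0.5, cy, gz]       # R104 CZ
    pos[_N_SCAFFOLD + 1] = [cx - 0.5, cy, gz]   # E493 CD
    return pos


# atom index blocks in the synthetic topology
def _index_blocks(config: SyntheticConfig) -> dict[str, np.ndarray]:
    n_prot = _N_SCAFFOLD + 2
    blocks = {
        "scaffold": np.arange(_N_SCAFFOLD),
        "anchors": np.arange(_N_SCAFFOLD, n_prot),
        "NA1": np.arange(n_prot, n_prot + 6),
        "NA2": np.arange(n_prot + 6, n_prot + 9),
        "ions": np.arange(n_prot + 9, n_prot + 9 + config.n_ions),
    }
    if config.chloride.enabled:
        blocks["chloride"] = np.array([n_prot + 9 + config.n_ions])
    return blocks


# ---------------------------------------------------------------------------
# Stochastic primitives
# ---------------------------------------------------------------------------

def step_langevin(
    positions: np.ndarray,
    forces: np.ndarray,
    diffusion_coeff: float,
    dt_integration: float,
    rng: np.random.Generator,
    noise: bool = True,
) -> np.ndarray:
    """One overdamped Euler-Maruyama step.

    dx = D * F * dt + sqrt(2 D dt) * xi, with F in kT/nm (so D/kT == D in
    these units).  ``noise=False`` is a deterministic test hook.
    """
    positions = np.asarray(positions, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if not np.all(np.isfinite(forces)):
        raise IntegrationError("non-finite force encountered")
    new = positions + diffusion_coeff * forces * dt_integration
    if noise:
        new = new + np.sqrt(2.0 * diffusion_coeff * dt_integration) * rng.standard_normal(
            positions.shape
        )
    if not np.all(np.isfinite(new)):
        bad = np.where(~np.isfinite(new).all(axis=-1))[0]
        raise IntegrationError(f"non-finite position for ion index {bad[:1].tolist()}")
    return new


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold coordinates into [lo, hi] by specular reflection."""
    width = hi - lo
    m = np.mod(x - lo, 2.0 * width)
    return lo + np.minimum(m, 2.0 * width - m)


def _bulk_walk(
    rng: np.random.Generator,
    n_frames: int,
    dt: float,
    D: float,
    start: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Free diffusion with reflecting walls, one position per frame."""
    steps = rng.standard_normal((n_frames - 1, 3)) * np.sqrt(2.0 * D * dt)
    path = np.concatenate([start[None, :], start[None, :] + np.cumsum(steps, axis=0)])
    return _reflect(path, lo, hi)


def evolve_site_geometry(
    spec: GeometryProcessSpec,
    binding_time: Optional[float],
    duration: float,
    dt_frame: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Coordinating-atom positions relative to the site centre.

    Returns an array of shape (n_frames, n_coordinating, 3).  Censored
    replicas (``binding_time=None``) keep apo statistics throughout.
    """
    n_frames = int(round(duration / dt_frame)) + 1
    times = np.arange(n_frames) * dt_frame
    dirs = _direction_set(spec.n_coordinating)

    if binding_time is None:
        progress = np.zeros(n_frames)
    else:
        tau = spec.relaxation_time
        dtb = times - binding_time
        if tau <= 0:
            progress = (dtb >= 0).astype(float)
        else:
            progress = np.where(dtb >= 0, 1.0 - np.exp(-np.maximum(dtb, 0.0) / tau), 0.0)
    radius = spec.mean_radius_apo + (spec.mean_radius_bound - spec.mean_radius_apo) * progress
    sigma = spec.positional_stddev + (
        spec.positional_stddev_bound - spec.positional_stddev
    ) * progress

    anchors = radius[:, None, None] * dirs[None, :, :]
    if spec.positional_stddev == 0 and spec.positional_stddev_bound == 0:
        return anchors

    # exact OU discretisation with slowly varying target sd
    alpha = np.exp(-dt_frame / spec.ou_timescale)
    noise = np.empty((n_frames, spec.n_coordinating, 3))
    noise[0] = sigma[0] * rng.standard_normal((spec.n_coordinating, 3))
    kick = np.sqrt(1.0 - alpha * alpha)
    xi = rng.standard_normal((n_frames - 1, spec.n_coordinating, 3))
    for i in range(1, n_frames):
        noise[i] = alpha * noise[i - 1] + sigma[i] * kick * xi[i - 1]
    return anchors + noise


def _ou_jitter(
    rng: np.random.Generator, n: int, dt: float, sigma: float, tau: float = 0.1
) -> np.ndarray:
    """A stationary 3D OU noise track of length n (for pinned ions)."""
    if sigma == 0 or n == 0:
        return np.zeros((n, 3))
    alpha = np.exp(-dt / tau)
    kick = sigma * np.sqrt(1.0 - alpha * alpha)
    out = np.empty((n, 3))
    out[0] = sigma * rng.standard_normal(3)
    xi = rng.standard_normal((n - 1, 3))
    for i in range(1, n):
        out[i] = alpha * out[i - 1] + kick * xi[i - 1]
    return out


# ---------------------------------------------------------------------------
# Ground-truth draws (hybrid mode)
# ---------------------------------------------------------------------------

def _draw_replica_times(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, Optional[float]]:
    """Exact exponential event times for one hybrid replica (None=censored)."""
    T = config.duration
    out: dict[str, Optional[float]] = {}

    def expdraw(rate: float) -> Optional[float]:
        if rate <= 0:
            return None
        t = float(rng.exponential(1.0 / rate))
        return t if t < T else None

    out["ENTRY"] = expdraw(config.entry_rate)
    la1 = rate_from_kon(config.site("NA1").k_on_true or 0.0, config.concentration) \
        if config.has_site("NA1") else 0.0
    la2 = rate_from_kon(config.site("NA2").k_on_true or 0.0, config.concentration) \
        if config.has_site("NA2") else 0.0
    if config.order_coupling and la1 > 0 and la2 > 0:
        t2 = expdraw(la2)
        out["NA2"] = t2
        if t2 is None:
            out["NA1"] = None
        else:
            t1 = t2 + float(rng.exponential(1.0 / la1))
            out["NA1"] = t1 if t1 < T else None
    else:
        out["NA1"] = expdraw(la1) if la1 > 0 else None
        out["NA2"] = expdraw(la2) if la2 > 0 else None
    if config.chloride.enabled:
        out["CL_RELEASE"] = expdraw(config.chloride.escape_rate)
    if config.has_site("GATE"):
        md = config.site("GATE").mean_dwell or 1.0
        out["GATE_DWELL"] = float(rng.exponential(md))
    return out


def draw_ground_truth(config: SyntheticConfig) -> SyntheticGroundTruth:
    """Draw the full hybrid-mode ground truth without rendering trajectories.

    This is the fast path for kinetics parameter-recovery studies; the times
    are identical to those used by :func:`generate_replica_set` with the
    same config (both consume the same per-replica substreams).
    """
    if config.mode != "hybrid":
        raise ConfigError("draw_ground_truth is only defined for hybrid mode")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicas)
    replicas = []
    for rid, ss in enumerate(seeds):
        rng = np.random.default_rng(ss.spawn(3)[0])  # schedule substream
        replicas.append(_replica_truth(config, rid, _draw_replica_times(config, rng)))
    return _assemble_truth(config, replicas)


_APPROACH_LEAD = 1.0   # ns between gate crossing and deep-site arrival
_FINAL_APPROACH = 0.3  # ns of the scripted final run-in to the cutoff


def _entry_time_for_site(t_bind: float) -> float:
    """Gate-crossing time of the tracer that will bind at ``t_bind``."""
    return max(t_bind - _APPROACH_LEAD, t_bind * 0.5)


def _effective_draws(
    config: SyntheticConfig, draws: dict[str, Optional[float]]
) -> dict[str, Optional[float]]:
    """Events only happen if a tracer ion exists to realise them
    (roles: ion 0 -> NA1, ion 1 -> NA2, ion 2 -> vestibule entry)."""
    draws = dict(draws)
    if config.n_ions < 1:
        draws["NA1"] = None
    if config.n_ions < 2:
        draws["NA2"] = None
    if config.n_ions < 3:
        draws["ENTRY"] = None
    return draws


def _replica_truth(
    config: SyntheticConfig, replica_id: int, draws: dict[str, Optional[float]]
) -> ReplicaGroundTruth:
    draws = _effective_draws(config, draws)
    entries = []
    if draws.get("ENTRY") is not None:
        entries.append(draws["ENTRY"])
    for site in ("NA1", "NA2"):
        t = draws.get(site)
        if t is not None:
            entries.append(_entry_time_for_site(t))
    entries.sort()
    return ReplicaGroundTruth(
        replica_id=replica_id,
        entry_times=[float(t) for t in entries],
        first_entry_time=float(entries[0]) if entries else None,
        site_first_binding={
            "NA1": draws.get("NA1"),
            "NA2": draws.get("NA2"),
        },
        chloride_release_time=draws.get("CL_RELEASE"),
    )


def _assemble_truth(
    config: SyntheticConfig, replicas: list[ReplicaGroundTruth]
) -> SyntheticGroundTruth:
    rates = {"ENTRY": config.entry_rate}
    for name in ("NA1", "NA2"):
        if config.has_site(name):
            k = config.site(name).k_on_true
            if k:
                rates[name] = rate_from_kon(k, config.concentration)
    return SyntheticGroundTruth(
        seed=config.seed,
        mode=config.mode,
        duration=config.duration,
        dt_frame=config.dt_frame,
        concentration=config.concentration,
        generating_rates=rates,
        replicas=replicas,
    )


# ---------------------------------------------------------------------------
# Trajectory rendering
# ---------------------------------------------------------------------------

def _piecewise_path(
    times: np.ndarray, waypoints: list[tuple[float, np.ndarray]]
) -> np.ndarray:
    """Linear interpolation through (time, position) waypoints.

    Times outside the waypoint span clamp to the end positions.
    """
    wt = np.array([w[0] for w in waypoints])
    wp = np.stack([np.asarray(w[1], dtype=float) for w in waypoints])
    out = np.empty((len(times), 3))
    for k in range(3):
        out[:, k] = np.interp(times, wt, wp[:, k])
    return out


def _render_deep_tracer(
    config: SyntheticConfig,
    rng: np.random.Generator,
    t_bind: Optional[float],
    site_name: str,
    site_xyz: np.ndarray,
    coord_rel: np.ndarray,
    bulk_lo: np.ndarray,
    bulk_hi: np.ndarray,
) -> np.ndarray:
    """Path of the tracer ion assigned to one deep site.

    Before the approach it diffuses in the bulk compartment; it crosses the
    gate plane, descends to a waypoint above its site, and its final run-in
    is expressed as a distance-to-centroid schedule against the *realised*
    coordinating-atom centroid, so the drawn binding time is exactly the
    first instant the ion is within the entry cutoff.
    """
    times = config.times
    dt = config.dt_frame
    n = config.n_frames
    D = config.diffusion_coeff
    cx, cy = config.box[0] / 2.0, config.box[1] / 2.0
    gz = config.potential.gate_z

    start = bulk_lo + rng.random(3) * (bulk_hi - bulk_lo)
    path = _bulk_walk(rng, n, dt, D, start, bulk_lo, bulk_hi)
    if t_bind is None or t_bind >= config.duration:
        return path

    t_cross = _entry_time_for_site(t_bind)
    t_run = max(t_bind - _FINAL_APPROACH, t_cross + 0.25 * (t_bind - t_cross))
    side = 1.0 if site_xyz[0] >= cx else -1.0
    way = np.array([cx + side * 0.5, cy, 2.8])      # above the site, off-axis
    gate_pt = np.array([cx, cy, gz])
    t_app = max(t_cross - 0.5, 0.0)
    i_app = min(int(np.floor(t_app / dt)), n - 1)

    script = _piecewise_path(
        times,
        [
            (t_app, path[i_app]),
            (t_cross, gate_pt),
            (t_run, way),
        ],
    )
    path[times >= t_app] = script[times >= t_app]

    # final run-in: distance to the realised centroid crosses the capture
    # radius exactly at t_bind, then settles at a small rest radius
    centroid = site_xyz[None, :] + coord_rel.mean(axis=1)
    cutoff = config.site(site_name).capture_radius
    d_way = float(np.linalg.norm(way - site_xyz))
    rest = 0.05
    t_settle = t_bind + 0.1
    dist = np.interp(times, [t_run, t_bind, t_settle], [d_way, cutoff, rest])
    u = way - site_xyz
    u = u / np.linalg.norm(u)
    run_mask = times >= t_run
    pinned = centroid + dist[:, None] * u[None, :]
    # small jitter once settled, amplitude well inside the cutoff
    settle_mask = times > t_settle
    jit = _ou_jitter(rng, int(settle_mask.sum()), dt, sigma=0.02)
    pinned[settle_mask] += jit
    path[run_mask] = pinned[run_mask]
    return path


def _render_entry_tracer(
    config: SyntheticConfig,
    rng: np.random.Generator,
    t_entry: Optional[float],
    gate_dwell: float,
    bulk_lo: np.ndarray,
    bulk_hi: np.ndarray,
) -> np.ndarray:
    """Tracer that enters the vestibule, pauses at the gate site, then
    hovers at S1 without ever reaching a deep site."""
    times = config.times
    dt = config.dt_frame
    n = config.n_frames
    cx, cy = config.box[0] / 2.0, config.box[1] / 2.0
    gz = config.potential.gate_z

    start = bulk_lo + rng.random(3) * (bulk_hi - bulk_lo)
    path = _bulk_walk(rng, n, dt, config.diffusion_coeff, start, bulk_lo, bulk_hi)
    if t_entry is None or t_entry >= config.duration:
        return path

    gate_site = (
        config._site_xyz(config.site("GATE")) if config.has_site("GATE")
        else np.array([cx, cy, gz - 0.2])
    )
    s1 = (
        config._site_xyz(config.site("S1")) if config.has_site("S1")
        else np.array([cx, cy, gz - 0.7])
    )
    t_app = max(t_entry - 0.5, 0.0)
    i_app = min(int(np.floor(t_app / dt)), n - 1)
    t_at_gate_site = t_entry + 0.1
    t_leave_gate = t_at_gate_site + max(gate_dwell, dt)
    t_at_s1 = t_leave_gate + 0.2
    script = _piecewise_path(
        times,
        [
            (t_app, path[i_app]),
            (t_entry, np.array([cx, cy, gz])),
            (t_at_gate_site, gate_site),
            (t_leave_gate, gate_site),
            (t_at_s1, s1),
        ],
    )
    mask = times >= t_app
    path[mask] = script[mask]
    dwell_mask = (times >= t_at_gate_site) & (times <= t_leave_gate)
    path[dwell_mask] += _ou_jitter(rng, int(dwell_mask.sum()), dt, sigma=0.03)
    hover_mask = times > t_at_s1
    path[hover_mask] += _ou_jitter(rng, int(hover_mask.sum()), dt, sigma=0.04)
    return path


def _render_chloride(
    config: SyntheticConfig,
    rng: np.random.Generator,
    t_release: Optional[float],
    na1_xyz: np.ndarray,
    bulk_lo: np.ndarray,
    bulk_hi: np.ndarray,
) -> np.ndarray:
    """Bound chloride; on release it passes through (or beside) NA1 and
    diffuses out of the vestibule."""
    times = config.times
    dt = config.dt_frame
    n = config.n_frames
    cx, cy = config.box[0] / 2.0, config.box[1] / 2.0
    gz = config.potential.gate_z
    cl_site = na1_xyz + np.array([0.25, 0.35, -0.1])

    path = np.tile(cl_site, (n, 1)) + _ou_jitter(rng, n, dt, sigma=0.02)
    if t_release is None or t_release >= config.duration:
        return path
    via_pt = na1_xyz if config.chloride.via_na1 else na1_xyz + np.array([0.0, 0.9, 0.0])
    exit_top = np.array([cx, cy, gz + 0.4])
    script = _piecewise_path(
        times,
        [
            (t_release, cl_site),
            (t_release + 0.3, via_pt),
            (t_release + 0.8, np.array([cx, cy, 2.8])),
            (t_release + 1.5, exit_top),
        ],
    )
    mask = times >= t_release
    path[mask] = script[mask]
    free_mask = times > t_release + 1.5
    if free_mask.any():
        i0 = int(np.argmax(free_mask))
        walk = _bulk_walk(rng, int(free_mask.sum()) + 1, dt, config.diffusion_coeff,
                          path[i0 - 1] if i0 > 0 else exit_top, bulk_lo, bulk_hi)
        path[free_mask] = walk[1:]
    return path


def _generate_hybrid_replica(
    config: SyntheticConfig,
    replica_id: int,
    seedseq: np.random.SeedSequence,
) -> tuple[np.ndarray, ReplicaGroundTruth]:
    """Render one hybrid replica; returns (positions array, ground truth)."""
    ss_sched, ss_geom, ss_paths = seedseq.spawn(3)
    rng_sched = np.random.default_rng(ss_sched)
    rng_geom = np.random.default_rng(ss_geom)
    rng_paths = np.random.default_rng(ss_paths)

    draws = _draw_replica_times(config, rng_sched)
    truth = _replica_truth(config, replica_id, draws)
    draws = _effective_draws(config, draws)

    n = config.n_frames
    blocks = _index_blocks(config)
    n_atoms = blocks["ions"][-1] + 1 if config.n_ions else blocks["NA2"][-1] + 1
    if config.chloride.enabled:
        n_atoms = blocks["chloride"][-1] + 1
    pos = np.empty((n, int(n_atoms), 3))

    prot = _protein_layout(config)
    pos[:, blocks["scaffold"], :] = prot[:_N_SCAFFOLD][None, :, :]
    pos[:, blocks["anchors"], :] = prot[_N_SCAFFOLD:][None, :, :]

    coord_rel = {}
    for name, idx in (("NA1", blocks["NA1"]), ("NA2", blocks["NA2"])):
        spec = config.geometry.get(name)
        if spec is None:
            spec = GeometryProcessSpec(n_coordinating=len(idx))
        t_b = draws.get(name) if config.has_site(name) else None
        rel = evolve_site_geometry(spec, t_b, config.duration, config.dt_frame, rng_geom)
        coord_rel[name] = rel
        center = config._site_xyz(config.site(name)) if config.has_site(name) else None
        if center is None:
            center = np.array([config.box[0] / 2 + (0.35 if name == "NA1" else -0.35),
                               config.box[1] / 2, 2.0])
        pos[:, idx, :] = center[None, None, :] + rel

    box = np.asarray(config.box, dtype=float)
    bulk_lo = np.array([0.1, 0.1, config.potential.gate_z + 0.3])
    bulk_hi = box - 0.1

    ion_idx = blocks["ions"]
    role_of: dict[int, str] = {}
    if config.n_ions >= 1 and config.has_site("NA1"):
        role_of[0] = "NA1"
    if config.n_ions >= 2 and config.has_site("NA2"):
        role_of[1] = "NA2"
    if config.n_ions >= 3:
        role_of[2] = "ENTRY"

    for j in range(config.n_ions):
        role = role_of.get(j)
        if role in ("NA1", "NA2"):
            pos[:, ion_idx[j], :] = _render_deep_tracer(
                config, rng_paths, draws.get(role), role,
                config._site_xyz(config.site(role)), coord_rel[role],
                bulk_lo, bulk_hi,
            )
        elif role == "ENTRY":
            pos[:, ion_idx[j], :] = _render_entry_tracer(
                config, rng_paths, draws.get("ENTRY"),
                draws.get("GATE_DWELL", 1.0), bulk_lo, bulk_hi,
            )
        else:
            start = bulk_lo + rng_paths.random(3) * (bulk_hi - bulk_lo)
            pos[:, ion_idx[j], :] = _bulk_walk(
                rng_paths, n, config.dt_frame, config.diffusion_coeff,
                start, bulk_lo, bulk_hi,
            )

    if config.chloride.enabled:
        na1_xyz = (config._site_xyz(config.site("NA1"))
                   if config.has_site("NA1")
                   else np.array([config.box[0] / 2 + 0.35, config.box[1] / 2, 2.0]))
        pos[:, blocks["chloride"][0], :] = _render_chloride(
            config, rng_paths, draws.get("CL_RELEASE"), na1_xyz, bulk_lo, bulk_hi,
        )
    return pos, truth


# ---------------------------------------------------------------------------
# Spatial mode
# ---------------------------------------------------------------------------

def potential_forces(config: SyntheticConfig, positions: np.ndarray) -> np.ndarray:
    """Analytic forces (kT/nm) of the vestibule funnel plus site wells."""
    pot = config.potential
    cx, cy = config.box[0] / 2.0, config.box[1] / 2.0
    z0 = pot.gate_z - 1.0
    F = np.zeros_like(positions)

    dx = positions[:, 0] - cx
    dy = positions[:, 1] - cy
    dz = positions[:, 2] - z0
    r2 = pot.vestibule_radius ** 2
    l2 = pot.smoothing_length ** 2
    g = pot.funnel_depth * np.exp(-(dx * dx + dy * dy) / (2 * r2) - dz * dz / (2 * l2))
    F[:, 0] += -g * dx / r2
    F[:, 1] += -g * dy / r2
    F[:, 2] += -g * dz / l2

    for site in config.sites:
        if not site.well_depth:
            continue
        c = config._site_xyz(site)
        w2 = site.capture_radius ** 2
        d = positions - c[None, :]
        gw = site.well_depth * np.exp(-np.sum(d * d, axis=1) / (2 * w2))
        F += -(gw / w2)[:, None] * d
    return F


def _generate_spatial_replica(
    config: SyntheticConfig,
    replica_id: int,
    seedseq: np.random.SeedSequence,
) -> tuple[np.ndarray, ReplicaGroundTruth]:
    ss_geom, ss_dyn = seedseq.spawn(2)
    rng_geom = np.random.default_rng(ss_geom)
    rng = np.random.default_rng(ss_dyn)

    n = config.n_frames
    dt = config.dt_frame
    blocks = _index_blocks(config)
    n_atoms = (blocks["chloride"][0] + 1 if config.chloride.enabled
               else (blocks["ions"][-1] + 1 if config.n_ions else blocks["NA2"][-1] + 1))
    pos = np.empty((n, int(n_atoms), 3))
    prot = _protein_layout(config)
    pos[:, blocks["scaffold"], :] = prot[:_N_SCAFFOLD][None, :, :]
    pos[:, blocks["anchors"], :] = prot[_N_SCAFFOLD:][None, :, :]

    box = np.asarray(config.box, dtype=float)
    lo = np.full(3, 0.05)
    hi = box - 0.05

    deep_sites = [s for s in config.sites if s.is_deep]
    site_xyz = {s.name: config._site_xyz(s) for s in deep_sites}
    bound_by: dict[str, int] = {}
    capture_time: dict[str, float] = {}
    entry_times: list[float] = []
    entered = np.zeros(config.n_ions, dtype=bool)
    gz = config.potential.gate_z
    cxy = np.array([config.box[0] / 2.0, config.box[1] / 2.0])

    substeps = max(1, int(round(dt / config.dt_integration)))
    h = dt / substeps
    ion_pos = lo + rng.random((config.n_ions, 3)) * (hi - lo)
    frames_ion = np.empty((n, config.n_ions, 3))
    frames_ion[0] = ion_pos
    free = np.ones(config.n_ions, dtype=bool)

    for i in range(1, n):
        for _ in range(substeps):
            if free.any():
                f = potential_forces(config, ion_pos[free])
                ion_pos[free] = step_langevin(
                    ion_pos[free], f, config.diffusion_coeff, h, rng
                )
                ion_pos[free] = _reflect(ion_pos[free], lo, hi)
        t = i * dt
        # absorbing capture at unoccupied deep sites
        for s in deep_sites:
            if s.name in bound_by:
                continue
            d = np.linalg.norm(ion_pos - site_xyz[s.name][None, :], axis=1)
            cand = np.where(free & (d < s.capture_radius))[0]
            if len(cand):
                j = int(cand[np.argmin(d[cand])])
                bound_by[s.name] = j
                capture_time[s.name] = t
                free[j] = False
                ion_pos[j] = site_xyz[s.name]
        # vestibule entry bookkeeping (plane + lateral radius, matching the
        # gate predicate used downstream)
        lateral = np.linalg.norm(ion_pos[:, :2] - cxy[None, :], axis=1)
        inside = (ion_pos[:, 2] < gz) & (lateral <= 1.2)
        new = inside & ~entered
        if new.any():
            entry_times.extend([t] * int(new.sum()))
            entered |= inside
        frames_ion[i] = ion_pos

    # pinned bound ions get a small jitter after capture (site vibration)
    for name, j in bound_by.items():
        i0 = int(round(capture_time[name] / dt))
        jit = _ou_jitter(rng, n - i0, dt, sigma=0.02)
        frames_ion[i0:, j, :] = site_xyz[name][None, :] + jit

    for name, idx in (("NA1", blocks["NA1"]), ("NA2", blocks["NA2"])):
        spec = config.geometry.get(name, GeometryProcessSpec(n_coordinating=len(idx)))
        t_b = capture_time.get(name)
        rel = evolve_site_geometry(spec, t_b, config.duration, dt, rng_geom)
        center = site_xyz.get(name)
        if center is None:
            center = np.array([config.box[0] / 2 + (0.35 if name == "NA1" else -0.35),
                               config.box[1] / 2, 2.0])
        pos[:, idx, :] = center[None, None, :] + rel

    if config.n_ions:
        pos[:, blocks["ions"], :] = frames_ion
    if config.chloride.enabled:
        pos[:, blocks["chloride"][0], :] = pos[:, blocks["NA1"][0], :]  # inert here

    entry_times.sort()
    truth = ReplicaGroundTruth(
        replica_id=replica_id,
        entry_times=entry_times,
        first_entry_time=entry_times[0] if entry_times else None,
        site_first_binding={"NA1": capture_time.get("NA1"),
                            "NA2": capture_time.get("NA2")},
    )
    return pos, truth


# ---------------------------------------------------------------------------
# Public generator
# ---------------------------------------------------------------------------

def generate_replica_set(
    config: SyntheticConfig,
) -> tuple[ReplicaSet, SyntheticGroundTruth]:
    """Generate the full replica set plus its exact ground truth.

    Deterministic: the same (config, seed) yields bit-identical output.
    The global seed is expanded into one ``SeedSequence`` child per replica,
    each split into schedule / geometry / path substreams, so any replica
    can be regenerated in isolation.
    """
    topology = build_topology(config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicas)
    times = config.times
    box = np.asarray(config.box, dtype=float)

    trajectories = []
    replica_truths = []
    for rid, ss in enumerate(seeds):
        if config.mode == "hybrid":
            pos, truth = _generate_hybrid_replica(config, rid, ss)
        else:
            pos, truth = _generate_spatial_replica(config, rid, ss)
        trajectories.append(
            Trajectory(replica_id=rid, times=times.copy(), positions=pos, box=box.copy())
        )
        replica_truths.append(truth)

    reference = trajectories[0].frame(0)
    replica_set = ReplicaSet(
        topology=topology,
        trajectories=trajectories,
        reference_frame=reference,
        ion_concentration=config.concentration,
    )
    return replica_set, _assemble_truth(config, replica_truths)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _mda_universe(topology: Topology, box: np.ndarray):
    import MDAnalysis as mda

    resnums = np.asarray(topology.residue_numbers)
    # consecutive identical residue numbers belong to one residue
    boundaries = np.concatenate([[True], np.diff(resnums) != 0])
    resindex = np.cumsum(boundaries) - 1
    n_res = int(resindex[-1]) + 1
    u = mda.Universe.empty(
        topology.n_atoms, n_residues=n_res, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.atom_names])
    u.add_TopologyAttr("resnames",
                       [str(topology.residue_names[i])
                        for i in range(topology.n_atoms) if boundaries[i]])
    u.add_TopologyAttr("resids", resnums[boundaries])
    u.dimensions = [box[0] * 10, box[1] * 10, box[2] * 10, 90, 90, 90]
    return u


def write_replica(
    trajectory: Trajectory,
    topology: Topology,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("GRO", "XTC"),
) -> list[Path]:
    """Write one replica as a GRO snapshot plus an XTC/DCD trajectory."""
    import MDAnalysis as mda

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for fmt in formats:
        if fmt.upper() not in {"GRO", "XTC", "DCD", "TRR"}:
            raise ConfigError(f"unsupported output format {fmt!r}")
    paths: list[Path] = []
    u = _mda_universe(topology, trajectory.box)
    tag = f"replica_{trajectory.replica_id:03d}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if "GRO" in [f.upper() for f in formats]:
            gro = out_dir / f"{tag}.gro"
            u.atoms.positions = trajectory.positions[0] * 10.0
            u.atoms.write(str(gro))
            paths.append(gro)
        for fmt in formats:
            fmt = fmt.upper()
            if fmt == "GRO":
                continue
            traj_path = out_dir / f"{tag}.{fmt.lower()}"
            with mda.Writer(str(traj_path), n_atoms=topology.n_atoms) as w:
                for i in range(trajectory.n_frames):
                    u.atoms.positions = trajectory.positions[i] * 10.0
                    u.trajectory.ts.frame = i
                    u.trajectory.ts.time = trajectory.times[i] * 1000.0
                    u.trajectory.ts.dimensions = u.dimensions
                    w.write(u.atoms)
            paths.append(traj_path)
    return paths


def write_replica_set(
    replica_set: ReplicaSet,
    ground_truth: SyntheticGroundTruth,
    out_dir: str | Path,
    traj_format: str = "XTC",
) -> dict[str, object]:
    """Write every replica plus the ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_paths = {}
    top_path = None
    for traj in replica_set.trajectories:
        formats = ("GRO", traj_format) if top_path is None else ("GRO", traj_format)
        paths = write_replica(traj, replica_set.topology, out_dir, formats=formats)
        if top_path is None:
            top_path = paths[0]
        all_paths[traj.replica_id] = [str(p) for p in paths]
    gt_path = ground_truth.to_json(out_dir / "ground_truth.json")
    return {"replicas": all_paths, "ground_truth": str(gt_path)}
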