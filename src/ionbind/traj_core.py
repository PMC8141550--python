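"""Topology/trajectory data model, atom selection and rigid-body superposition.

Internal unit convention: coordinates and distances in nm, time in ns,
masses in amu.  All unit conversion happens at the I/O boundary (MDAnalysis
works in Å/ps); nothing downstream ever rescales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "ReplicaSet",
    "AtomSelection",
    "FormatError",
    "IntegrityError",
    "SelectionError",
    "DegeneracyError",
    "read_topology",
    "read_trajectory",
    "select_atoms",
    "superpose",
    "kabsch_rotation",
    "rmsd",
]

A_PER_NM = 10.0
PS_PER_NS = 1000.0
DT_TOLERANCE_NS = 1e-6

#: element -> atomic mass (amu); enough for protein pseudo-atoms and the ions
#: this package handles.  Unknown elements fall back to carbon.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38,
}
_DEFAULT_MASS = 12.011

#: residue names treated as monatomic ions, where the atom name IS the element
_ION_RESNAMES = {"NA", "CL", "SOD", "CLA", "K", "MG", "CAL", "ZN", "NA+", "CL-"}


class FormatError(ValueError):
    """A file could not be parsed under its declared format."""


class IntegrityError(ValueError):
    """Parsed data violates a structural invariant (atom counts, spacing...)."""


class SelectionError(KeyError):
    """An atom-selection expression failed to resolve."""


class DegeneracyError(ValueError):
    """A geometric operation received degenerate input (e.g. collinear atoms)."""


@dataclass(frozen=True)
class Topology:
    """Named-atom table shared by every frame of a replica set.

    Parallel arrays indexed by ``atom_id`` (contiguous from 0).
    """

    atom_names: np.ndarray          # (n,) str
    residue_names: np.ndarray       # (n,) str
    residue_numbers: np.ndarray     # (n,) int
    elements: np.ndarray            # (n,) str
    masses: np.ndarray              # (n,) float, amu

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for arr in (self.residue_names, self.residue_numbers, self.elements, self.masses):
            if len(arr) != n:
                raise IntegrityError("topology arrays have inconsistent lengths")
        if n == 0:
            raise IntegrityError("topology has no atoms")
        if any(not str(name) for name in self.atom_names):
            raise IntegrityError("every atom needs a nonempty atom_name")
        if np.any(np.asarray(self.masses) <= 0):
            raise IntegrityError("atom masses must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)


@dataclass
class Frame:
    """One time point: positions in nm, orthorhombic box edges in nm."""

    time: float
    positions: np.ndarray           # (n, 3) nm
    box: np.ndarray                 # (3,) nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise IntegrityError("frame positions must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise IntegrityError("box must be 3 positive edge lengths (nm)")


@dataclass
class Trajectory:
    """Time-ordered frames of one replica with uniform spacing ``dt`` (ns)."""

    replica_id: int
    times: np.ndarray               # (n_frames,) ns
    positions: np.ndarray           # (n_frames, n_atoms, 3) nm
    box: np.ndarray                 # (3,) nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.n_frames < 2:
            raise IntegrityError("a trajectory needs at least 2 frames")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise IntegrityError("frame times must be strictly increasing")
        # XTC stores time as float32, so late frames of long runs carry
        # rounding of order t * 2^-23; widen the tolerance accordingly and
        # snap to the uniform grid once accepted.
        tol = max(DT_TOLERANCE_NS, abs(float(self.times[-1])) * 2.5e-7)
        if np.ptp(steps) > tol:
            raise IntegrityError(
                f"nonuniform frame spacing: ptp={np.ptp(steps):.3g} ns exceeds "
                f"tolerance {tol:.3g} ns"
            )
        dt = (self.times[-1] - self.times[0]) / (len(self.times) - 1)
        self.times = self.times[0] + dt * np.arange(len(self.times))

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), positions=self.positions[i], box=self.box)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass
class ReplicaSet:
    """A topology plus one trajectory per replica and a common reference frame."""

    topology: Topology
    trajectories: list[Trajectory]
    reference_frame: Frame
    ion_concentration: float        # molar

    def __post_init__(self) -> None:
        if self.ion_concentration <= 0:
            raise IntegrityError("ion_concentration must be > 0")
        ids = [t.replica_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise IntegrityError("replica_ids must be unique")
        for t in self.trajectories:
            if t.n_atoms != self.topology.n_atoms:
                raise IntegrityError(
                    f"replica {t.replica_id}: {t.n_atoms} atoms != topology "
                    f"{self.topology.n_atoms}"
                )

    @property
    def n_replicas(self) -> int:
        return len(self.trajectories)


@dataclass(frozen=True)
class AtomSelection:
    """A resolved selection: the expression plus the atom_ids it names."""

    expression: str
    indices: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# I/O (MDAnalysis behind the scenes; Å/ps converted to nm/ns here and only here)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip()
    if residue_name.strip().upper() in _ION_RESNAMES:
        return name.upper().rstrip("+-0123456789")
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_topology(path: str | Path, format: str | None = None) -> Topology:
    """Read a PDB or GRO file into a :class:`Topology`.

    Elements are taken from the file when present, otherwise inferred from
    atom names (monatomic-ion residues keep their full name as element).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in {"PDB", "GRO"}:
        raise FormatError(f"unsupported topology format: {fmt}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt, to_guess=())
    except Exception as exc:  # MDAnalysis raises assorted types on bad input
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc

    atoms = u.atoms
    names = np.array([a.name for a in atoms], dtype=object)
    resnames = np.array([a.resname for a in atoms], dtype=object)
    resnums = np.array([a.resid for a in atoms], dtype=int)

    elements: list[str] = []
    file_elements = getattr(atoms, "elements", None)
    for i in range(len(atoms)):
        el = ""
        if file_elements is not None:
            el = str(file_elements[i]).strip()
        if not el:
            el = _infer_element(names[i], resnames[i])
        elements.append(el.upper())
    masses = np.array([_MASSES.get(el, _DEFAULT_MASS) for el in elements])
    return Topology(
        atom_names=names,
        residue_names=resnames,
        residue_numbers=resnums,
        elements=np.array(elements, dtype=object),
        masses=masses,
    )


def read_trajectory(
    topology: Topology,
    path: str | Path,
    format: str | None = None,
    replica_id: int = 0,
    unwrap: bool = True,
) -> Trajectory:
    """Read an XTC/DCD/TRR coordinate trajectory, converting to nm/ns.

    Periodic jumps are unwrapped per atom (minimum-image on consecutive
    steps) so ion paths are continuous; disable with ``unwrap=False``.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in {"XTC", "DCD", "TRR"}:
        raise FormatError(f"unsupported trajectory format: {fmt}")

    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        u.load_new(str(path), format=fmt)
    except Exception as exc:
        msg = str(exc)
        if "atoms" in msg or "shape" in msg:
            raise IntegrityError(
                f"{path}: frame atom count does not match topology "
                f"({topology.n_atoms} atoms expected): {exc}"
            ) from exc
        raise FormatError(f"could not read {path} as {fmt}: {exc}") from exc

    n_frames = len(u.trajectory)
    if n_frames < 2:
        raise IntegrityError(f"{path}: trajectory has {n_frames} frame(s); >= 2 required")

    times = np.empty(n_frames)
    positions = np.empty((n_frames, topology.n_atoms, 3))
    box = None
    for i, ts in enumerate(u.trajectory):
        if ts.n_atoms != topology.n_atoms:
            raise IntegrityError(
                f"{path} frame {i}: {ts.n_atoms} atoms != topology {topology.n_atoms}"
            )
        times[i] = ts.time / PS_PER_NS
        positions[i] = ts.positions / A_PER_NM
        if box is None and ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float) / A_PER_NM
    if box is None:
        box = np.full(3, np.inf)  # replaced below; Trajectory requires finite > 0
        span = positions.reshape(-1, 3)
        box = span.max(axis=0) - span.min(axis=0) + 1.0

    if unwrap and np.all(np.isfinite(box)):
        steps = np.diff(positions, axis=0)
        steps -= box * np.round(steps / box)
        positions = np.concatenate(
            [positions[:1], positions[:1] + np.cumsum(steps, axis=0)], axis=0
        )

    return Trajectory(replica_id=replica_id, times=times, positions=positions, box=box)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_atoms(topology: Topology, expression: str) -> AtomSelection:
    """Resolve a ``"resnum:atom_name, ..."`` expression to atom ids.

    The grammar is deliberately minimal: comma-separated
    ``residue_number:atom_name`` pairs, each of which must match exactly one
    atom, plus the single built-in token ``"CA"`` selecting every atom named
    CA (the Cα fit set).  Order of the result follows the expression.
    """
    expr = expression.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    if expr.upper() == "CA":
        idx = np.where(np.asarray([n == "CA" for n in topology.atom_names]))[0]
        if len(idx) == 0:
            raise SelectionError("no CA atoms in topology")
        return AtomSelection(expression=expression, indices=idx)

    indices: list[int] = []
    for token in expr.split(","):
        token = token.strip()
        if not token:
            raise SelectionError(f"empty pair in expression {expression!r}")
        if ":" not in token:
            raise SelectionError(f"malformed pair {token!r} (expected resnum:atom_name)")
        res_str, _, name = token.partition(":")
        try:
            resnum = int(res_str.strip())
        except ValueError as exc:
            raise SelectionError(f"bad residue number in pair {token!r}") from exc
        name = name.strip()
        if not name:
            raise SelectionError(f"missing atom name in pair {token!r}")
        hits = np.where(
            (topology.residue_numbers == resnum)
            & (np.asarray([str(n) == name for n in topology.atom_names]))
        )[0]
        if len(hits) == 0:
            raise SelectionError(f"no atom matches pair {token!r}")
        if len(hits) > 1:
            raise SelectionError(
                f"pair {token!r} is ambiguous: matches atom ids {hits.tolist()}"
            )
        indices.append(int(hits[0]))
    return AtomSelection(expression=expression, indices=np.asarray(indices, dtype=int))


def select_ions(topology: Topology, ion_name: str = "NA") -> AtomSelection:
    """All atoms whose atom name and residue name both equal ``ion_name``
    (the convention for monatomic ions in GRO/PDB topologies)."""
    idx = np.where(
        np.asarray([str(n) == ion_name for n in topology.atom_names])
        & np.asarray([str(r) == ion_name for r in topology.residue_names])
    )[0]
    if len(idx) == 0:
        raise SelectionError(f"no {ion_name!r} ions in topology")
    return AtomSelection(expression=f"<ions {ion_name}>", indices=idx)


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimizing ||reference - mobile @ R.T||.

    Both inputs must already be centered.  Delegates to
    scipy's ``Rotation.align_vectors`` (the Kabsch/Wahba solution with the
    reflection case handled).
    """
    from scipy.spatial.transform import Rotation

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on rank-deficient input
        rot, _ = Rotation.align_vectors(reference, mobile)
    return rot.as_matrix()


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (nm), no fitting."""
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2, axis=1))))


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegeneracyError("superposition needs at least 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise DegeneracyError("fit atoms are collinear; rotation is underdetermined")


def superpose(
    mobile: Frame, reference: Frame, fit_selection: AtomSelection
) -> tuple[Frame, float]:
    """Rigid-body fit of ``mobile`` onto ``reference`` over ``fit_selection``.

    Mass-unweighted least squares; the returned frame has *all* atoms
    transformed, and the returned RMSD is over the fit selection only.
    """
    idx = fit_selection.indices
    if len(idx) == 0:
        raise SelectionError("fit selection is empty")
    mob = mobile.positions[idx]
    ref = reference.positions[idx]
    _check_fit_atoms(mob)
    _check_fit_atoms(ref)

    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    R = kabsch_rotation(mob - mob_c, ref - ref_c)
    transformed = (mobile.positions - mob_c) @ R.T + ref_c
    fitted = Frame(time=mobile.time, positions=transformed, box=mobile.box)
    return fitted, rmsd(transformed[idx], ref)


def superpose_trajectory(
    trajectory: Trajectory, reference: Frame, fit_selection: AtomSelection
) -> Trajectory:
    """Superpose every frame of a trajectory onto ``reference``."""
    out = np.empty_like(trajectory.positions)
    idx = fit_selection.indices
    ref = reference.positions[idx]
    ref_c = ref.mean(axis=0)
    ref0 = ref - ref_c
    for i in range(trajectory.n_frames):
        mob = trajectory.positions[i][idx]
        mob_c = mob.mean(axis=0)
        R = kabsch_rotation(mob - mob_c, ref0)
        out[i] = (trajectory.positions[i] - mob_c) @ R.T + ref_c
    return Trajectory(
        replica_id=trajectory.replica_id,
        times=trajectory.times.copy(),
        positions=out,
        box=trajectory.box.copy(),
    )
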