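"""Coordinate/trajectory containers and periodic-boundary geometry.

The data model is deliberately small: a :class:`FrameSet` holds an
(n_frames, n_beads, 3) position array in nm together with frame times in µs
and one orthorhombic box, a :class:`Selection` is an ordered set of bead
indices, and a :class:`DistanceSeries` is the pocket–ligand
center-of-geometry distance per frame, computed with the minimum-image
convention.  GRO/PDB/XTC I/O is delegated to MDAnalysis (imported lazily);
a plain-text "table" trajectory dialect is provided for lossless,
diff-friendly storage of synthetic runs.

Table trajectory dialect (one file per replica)::

    # cgtraj 1
    natoms <n>
    box <Lx> <Ly> <Lz>
    time <t in µs>
    <bead index> <x> <y> <z>        # one line per bead, nm
    ...
    time <t>
    ...

Floats are written with 17 significant digits so a write→read cycle is
bit-exact for float64 data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SelectionError, StructureParseError, TriclinicBoxError

__all__ = [
    "Topology",
    "FrameSet",
    "Selection",
    "DistanceSeries",
    "read_structure",
    "write_gro",
    "read_trajectory",
    "write_table_trajectory",
    "write_xtc",
    "center_of_geometry",
    "minimum_image_displacement",
    "minimum_image_distance",
    "distance_series",
]

_ANGLE_TOL = 1e-3


@dataclass
class Topology:
    """Bead metadata shared by all frames of a :class:`FrameSet`."""

    names: list[str]
    resids: np.ndarray
    resnames: list[str]

    @classmethod
    def default(cls, n_beads: int) -> "Topology":
        return cls(
            names=[f"B{i + 1}" for i in range(n_beads)],
            resids=np.arange(1, n_beads + 1),
            resnames=["BEAD"] * n_beads,
        )

    @property
    def n_beads(self) -> int:
        return len(self.names)


@dataclass
class FrameSet:
    """Frames of a trajectory (or a single structure) in nm / µs."""

    times: np.ndarray            # (n_frames,), µs
    positions: np.ndarray        # (n_frames, n_beads, 3), nm
    box: np.ndarray              # (3,) orthorhombic edges, nm
    topology: Topology | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_beads, 3)")
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if self.topology is not None and self.topology.n_beads != self.n_beads:
            raise ValueError("topology bead count does not match positions")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]


@dataclass
class Selection:
    """Named, ordered set of bead indices (0-based internally)."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1 or self.indices.size == 0:
            raise SelectionError(f"selection {self.name!r} is empty")
        if len(np.unique(self.indices)) != self.indices.size:
            raise SelectionError(f"selection {self.name!r} has duplicate indices")
        if np.any(self.indices < 0):
            raise SelectionError(f"selection {self.name!r} has negative indices")

    def validate_against(self, frames: FrameSet) -> None:
        if np.any(self.indices >= frames.n_beads):
            raise SelectionError(
                f"selection {self.name!r} indexes beyond {frames.n_beads} beads"
            )


@dataclass
class DistanceSeries:
    """Pocket-COG to ligand-COG minimum-image distance per frame."""

    replica_id: str
    times: np.ndarray      # µs, strictly increasing
    distances: np.ndarray  # nm
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances must align")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            half_diag = 0.5 * float(np.linalg.norm(self.box))
            if np.any(self.distances > half_diag + 1e-9):
                raise ValueError("distance exceeds half the box diagonal")

    @property
    def duration(self) -> float:
        """Time spanned by the series in µs (0 for a single frame)."""
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def center_of_geometry(positions: np.ndarray) -> np.ndarray:
    """Unweighted mean of a (…, n, 3) position array over its bead axis.

    The center of geometry — not of mass — is used everywhere in this
    package, matching the coarse-grained mapping convention.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[-2] == 0:
        raise SelectionError("cannot take the center of geometry of an empty set")
    return positions.mean(axis=-2)


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Component-wise displacement a − b wrapped into (−L/2, L/2] per axis."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    d = a - b
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Euclidean minimum-image distance for an orthorhombic box.

    Broadcasts over leading axes, so frame-wise distances come out of a
    single call.
    """
    return np.linalg.norm(minimum_image_displacement(a, b, box), axis=-1)


def distance_series(
    frames: FrameSet,
    pocket: Selection,
    ligand: Selection,
    replica_id: str = "replica-0",
) -> DistanceSeries:
    """Pocket-COG/ligand-COG minimum-image distance for every frame."""
    if frames.n_frames == 0:
        raise ValueError("empty FrameSet")
    pocket.validate_against(frames)
    ligand.validate_against(frames)
    pocket_cog = center_of_geometry(frames.positions[:, pocket.indices, :])
    ligand_cog = center_of_geometry(frames.positions[:, ligand.indices, :])
    r = minimum_image_distance(pocket_cog, ligand_cog, frames.box)
    return DistanceSeries(replica_id=replica_id, times=frames.times.copy(),
                          distances=r, box=frames.box.copy())


# ---------------------------------------------------------------------------
# structure I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _check_orthorhombic(dimensions: np.ndarray, path: str) -> np.ndarray:
    if dimensions is None or np.all(dimensions[:3] == 0):
        raise StructureParseError(f"{path}: no box information present")
    angles = dimensions[3:6]
    if np.any(np.abs(angles - 90.0) > _ANGLE_TOL):
        raise TriclinicBoxError(
            f"{path}: box angles {angles} — only orthorhombic boxes are supported"
        )
    return np.asarray(dimensions[:3], dtype=float) / 10.0  # Å → nm


def read_structure(path: str | Path, fmt: str | None = None) -> FrameSet:
    """Read a GRO or PDB file into a single-frame :class:`FrameSet`.

    Positions are converted to nm regardless of the source convention
    (MDAnalysis reports Å for both formats).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: file not found")
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in {"GRO", "PDB"}:
        raise StructureParseError(f"{path}: unsupported structure format {fmt!r}")
    try:
        u = mda.Universe(str(path), format=fmt)
        positions = u.atoms.positions.astype(float) / 10.0
        dims = u.dimensions
    except (TriclinicBoxError, StructureParseError):
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of parser errors
        raise StructureParseError(f"{path}: malformed {fmt} file ({exc})") from exc
    box = _check_orthorhombic(dims, str(path))
    topology = Topology(
        names=[str(n) for n in u.atoms.names],
        resids=np.asarray(u.atoms.resids, dtype=int),
        resnames=[str(r) for r in u.atoms.resnames],
    )
    return FrameSet(times=np.zeros(1), positions=positions[None, :, :],
                    box=box, topology=topology)


def _as_universe(frames: FrameSet, frame: int):
    import MDAnalysis as mda

    topo = frames.topology or Topology.default(frames.n_beads)
    n_res = int(np.max(topo.resids))
    u = mda.Universe.empty(
        frames.n_beads,
        n_residues=n_res,
        atom_resindex=np.asarray(topo.resids) - 1,
        trajectory=True,
    )
    u.add_TopologyAttr("names", topo.names)
    resnames = ["BEAD"] * n_res
    for resid, resname in zip(topo.resids, topo.resnames):
        resnames[int(resid) - 1] = resname
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.atoms.positions = frames.positions[frame] * 10.0  # nm → Å
    u.dimensions = np.concatenate([frames.box * 10.0, [90.0, 90.0, 90.0]])
    return u


def write_gro(frames: FrameSet, path: str | Path, frame: int = 0) -> None:
    """Write one frame as GRO (nm, standard dialect)."""
    u = _as_universe(frames, frame)
    u.atoms.write(str(path))


def write_xtc(frames: FrameSet, path: str | Path) -> None:
    """Write all frames to XTC (times stored in ps = µs × 1e6)."""
    import MDAnalysis as mda

    u = _as_universe(frames, 0)
    with mda.Writer(str(path), n_atoms=frames.n_beads) as w:
        for i in range(frames.n_frames):
            u.atoms.positions = frames.positions[i] * 10.0
            u.trajectory.ts.time = frames.times[i] * 1e6
            u.trajectory.ts.frame = i
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def write_table_trajectory(frames: FrameSet, path: str | Path) -> None:
    """Write the plain-text table dialect (bit-exact for float64)."""
    with open(path, "w") as fh:
        fh.write("# cgtraj 1\n")
        fh.write(f"natoms {frames.n_beads}\n")
        fh.write("box " + " ".join(f"{x:.17g}" for x in frames.box) + "\n")
        for t, frame in zip(frames.times, frames.positions):
            fh.write(f"time {t:.17g}\n")
            for i, (x, y, z) in enumerate(frame):
                fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")


def _read_table(path: Path, stride: int) -> FrameSet:
    times: list[float] = []
    frames: list[np.ndarray] = []
    n_beads = box = None
    current: list[list[float]] | None = None
    last_lineno = 0

    def finish_frame(lineno: int) -> None:
        if current is None:
            return
        if len(current) != n_beads:
            raise StructureParseError(
                f"{path}:{lineno}: frame has {len(current)} beads, expected {n_beads}"
            )
        frames.append(np.asarray(current, dtype=float))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            last_lineno = lineno
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if fields[0] == "natoms":
                    n_beads = int(fields[1])
                elif fields[0] == "box":
                    box = np.asarray([float(x) for x in fields[1:4]])
                elif fields[0] == "time":
                    finish_frame(lineno)
                    t = float(fields[1])
                    if times and t <= times[-1]:
                        raise StructureParseError(
                            f"{path}:{lineno}: non-monotone time {t}"
                        )
                    times.append(t)
                    current = []
                else:
                    if current is None or n_beads is None:
                        raise StructureParseError(
                            f"{path}:{lineno}: coordinate line before header/time"
                        )
                    current.append([float(fields[1]), float(fields[2]), float(fields[3])])
            except (ValueError, IndexError) as exc:
                raise StructureParseError(f"{path}:{lineno}: malformed line ({exc})") from exc
    finish_frame(last_lineno)
    if not frames or box is None:
        raise StructureParseError(f"{path}: no frames found")
    fs = FrameSet(
        times=np.asarray(times)[::stride],
        positions=np.stack(frames)[::stride],
        box=box,
        topology=Topology.default(n_beads),
    )
    return fs


def _read_xtc(path: Path, topology: Topology, stride: int) -> FrameSet:
    import MDAnalysis as mda

    u = mda.Universe.empty(topology.n_beads, trajectory=True)
    try:
        u.load_new(str(path))
    except Exception as exc:
        raise StructureParseError(f"{path}: cannot read XTC ({exc})") from exc
    times, positions = [], []
    box = None
    for ts in u.trajectory[::stride]:
        if box is None:
            box = _check_orthorhombic(ts.dimensions, str(path))
        times.append(ts.time / 1e6)  # ps → µs
        positions.append(u.atoms.positions.astype(float) / 10.0)
    fs = FrameSet(times=np.asarray(times), positions=np.stack(positions),
                  box=box, topology=topology)
    if fs.times.size > 1 and np.any(np.diff(fs.times) <= 0):
        raise StructureParseError(f"{path}: non-monotone frame times")
    return fs


def read_trajectory(
    path: str | Path,
    fmt: str | None = None,
    topology: Topology | None = None,
    stride: int = 1,
) -> FrameSet:
    """Read a trajectory in the table dialect or XTC.

    XTC carries no topology, so one (or at least a bead count via
    :meth:`Topology.default`) must be supplied; a bead-count mismatch is an
    error raised by the XTC reader itself.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: file not found")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if fmt in {"table", "traj", "txt"}:
        return _read_table(path, stride)
    if fmt == "xtc":
        if topology is None:
            raise StructureParseError(f"{path}: XTC requires a topology")
        return _read_xtc(path, topology, stride)
    raise StructureParseError(f"{path}: unsupported trajectory format {fmt!r}")
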