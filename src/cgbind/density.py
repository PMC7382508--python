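"""3D ligand occupancy grids and fold-over-bulk / free-energy fields.

The ligand center of geometry is binned into a regular voxel grid in the
reference-aligned frame.  Dividing each voxel count by the mean count in a
bulk shell far from the binding region gives the enrichment over bulk
solvent; −RT ln of that ratio is the local binding free energy, so a
10/100/1000/10000-fold isolevel set maps to roughly −5.7/−11.5/−17.2/−23
kJ/mol at 300 K.  Grids are written as OpenDX scalar fields (Å units) for
molecular viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import ANGSTROM_PER_NM, DEFAULT_TEMPERATURE, rt
from .errors import StructureParseError
from .pose import kabsch_superpose
from .trajectory import FrameSet, Selection, center_of_geometry

__all__ = [
    "DensityGrid",
    "accumulate",
    "fold_over_bulk",
    "density_to_free_energy",
    "write_dx",
    "read_dx",
    "DEFAULT_ISOLEVELS",
]

#: Conventional fold-over-bulk isolevels for visualisation.
DEFAULT_ISOLEVELS = (10.0, 100.0, 1000.0, 10000.0)


@dataclass
class DensityGrid:
    """Voxel counts with grid geometry and a bulk reference density."""

    origin: np.ndarray          # (3,), nm
    spacing: float              # nm
    counts: np.ndarray          # (nx, ny, nz)
    n_samples: int
    bulk_density: float | None = None   # counts per voxel
    clipped: int = 0                    # samples outside the grid

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            self.origin[d] + (np.arange(self.counts.shape[d]) + 0.5) * self.spacing
            for d in range(3)
        ]
        return tuple(axes)


def accumulate(
    frames: FrameSet | Sequence[FrameSet],
    ligand: Selection,
    alignment: Selection | None = None,
    reference_frame: np.ndarray | None = None,
    spacing: float = 0.1,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> DensityGrid:
    """Bin the ligand COG of every frame into a voxel grid.

    With an ``alignment`` selection each frame is first superposed onto
    ``reference_frame`` (default: the first frame) so the density lives in
    the protein-fixed frame; pass ``alignment=None`` for data already in a
    fixed frame (e.g. a static synthetic well).  The grid covers the box by
    default.  Counts are conserved: Σ counts + clipped = frames used.
    """
    frame_sets = [frames] if isinstance(frames, FrameSet) else list(frames)
    if not frame_sets:
        raise ValueError("no frames")
    box = frame_sets[0].box
    if origin is None:
        origin = np.zeros(3)
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        shape = tuple(int(np.ceil(b / spacing)) for b in box)
    counts = np.zeros(shape, dtype=np.int64)
    clipped = 0
    total = 0

    ref = reference_frame
    for fs in frame_sets:
        ligand.validate_against(fs)
        if alignment is not None:
            alignment.validate_against(fs)
            if ref is None:
                ref = fs.positions[0]
        for i in range(fs.n_frames):
            frame = fs.positions[i]
            if alignment is not None:
                _, _, frame = kabsch_superpose(frame, ref, alignment)
            cog = center_of_geometry(frame[ligand.indices])
            idx = np.floor((cog - origin) / spacing).astype(int)
            total += 1
            if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
                clipped += 1
                continue
            counts[idx[0], idx[1], idx[2]] += 1
    return DensityGrid(origin=origin, spacing=spacing, counts=counts,
                       n_samples=total - clipped, clipped=clipped)


def estimate_bulk_density(
    grid: DensityGrid,
    center: np.ndarray,
    bulk_min_r: float = 3.0,
    bulk_max_r: float | None = None,
) -> float:
    """Mean count per voxel over the shell farther than ``bulk_min_r`` from
    ``center`` (and, optionally, closer than ``bulk_max_r``, to stay clear of
    incompletely covered corners)."""
    xs, ys, zs = grid.voxel_centers()
    dx, dy, dz = np.meshgrid(xs - center[0], ys - center[1], zs - center[2],
                             indexing="ij")
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    sel = r > bulk_min_r
    if bulk_max_r is not None:
        sel &= r < bulk_max_r
    if not np.any(sel):
        raise ValueError("empty bulk shell")
    return float(grid.counts[sel].mean())


def fold_over_bulk(
    grid: DensityGrid,
    center: np.ndarray | None = None,
    bulk_min_r: float = 3.0,
    bulk_max_r: float | None = None,
) -> np.ndarray:
    """Per-voxel enrichment counts / bulk_density.

    Estimates (and stores) the bulk density from the far-field shell when
    it has not been set yet.  ``center`` defaults to the argmax voxel —
    with an attractive well that is the binding region.
    """
    if grid.bulk_density is None:
        if center is None:
            imax = np.unravel_index(np.argmax(grid.counts), grid.counts.shape)
            center = grid.origin + (np.asarray(imax) + 0.5) * grid.spacing
        grid.bulk_density = estimate_bulk_density(grid, np.asarray(center, dtype=float),
                                                  bulk_min_r, bulk_max_r)
    if grid.bulk_density <= 0:
        raise ValueError("bulk density is zero; cannot normalize")
    return grid.counts / grid.bulk_density


def density_to_free_energy(
    ratio: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """ΔG(x) = −RT ln(ratio(x)) in kJ/mol; NaN where the ratio is zero."""
    ratio = np.asarray(ratio, dtype=float)
    out = np.full_like(ratio, np.nan)
    ok = ratio > 0
    out[ok] = -rt(temperature) * np.log(ratio[ok])
    return out


# ---------------------------------------------------------------------------
# OpenDX I/O
# ---------------------------------------------------------------------------

def write_dx(
    field: np.ndarray,
    origin: np.ndarray,
    spacing: float,
    path: str | Path,
    name: str = "density",
) -> None:
    """Write a scalar field as OpenDX (coordinates in Å, z fastest)."""
    field = np.asarray(field, dtype=float)
    nx, ny, nz = field.shape
    o = np.asarray(origin, dtype=float) * ANGSTROM_PER_NM
    d = spacing * ANGSTROM_PER_NM
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
        fh.write(f"delta {d:.6f} 0 0\n")
        fh.write(f"delta 0 {d:.6f} 0\n")
        fh.write(f"delta 0 0 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {field.size} data follows\n"
        )
        flat = field.ravel(order="C")  # z varies fastest
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.9g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write(f'object "{name}" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read an OpenDX scalar field back as (field, origin_nm, spacing_nm)."""
    shape = origin = None
    deltas: list[float] = []
    values: list[float] = []
    n_items = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("object 1"):
                shape = tuple(int(x) for x in line.split()[-3:])
            elif line.startswith("origin"):
                origin = np.asarray([float(x) for x in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append(max(float(x) for x in line.split()[1:4]))
            elif line.startswith("object 3"):
                n_items = int(line.split()[-3])
            elif line.startswith(("object", "attribute", "component")):
                continue
            else:
                try:
                    values.extend(float(x) for x in line.split())
                except ValueError as exc:
                    raise StructureParseError(f"{path}:{lineno}: bad value") from exc
    if shape is None or origin is None or len(deltas) != 3:
        raise StructureParseError(f"{path}: incomplete DX header")
    if len(values) != n_items or n_items != int(np.prod(shape)):
        raise StructureParseError(
            f"{path}: expected {n_items} values, found {len(values)}"
        )
    if abs(deltas[0] - deltas[1]) > 1e-9 or abs(deltas[0] - deltas[2]) > 1e-9:
        raise StructureParseError(f"{path}: anisotropic spacing not supported")
    field = np.asarray(values).reshape(shape, order="C")
    return field, origin / ANGSTROM_PER_NM, deltas[0] / ANGSTROM_PER_NM
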