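"""Ligand pose RMSDs with pocket superposition and symmetry correction.

The reference ligand pose comes from a crystal structure mapped to bead
resolution by unweighted center-of-geometry averaging over each bead's
constituent atoms, hydrogens included (:func:`cog_map`).  For each bound
frame the binding-pocket selection is superposed onto the reference by the
optimal proper rotation (Kabsch), the transform is applied to the whole
frame, and the ligand RMSD is minimized over the ligand's symmetry
permutations — a threefold-symmetric ring read in a rotated bead order is
the same chemical pose, so only the lowest RMSD over the symmetry group is
meaningful.  RMSDs are reported in Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

from .constants import ANGSTROM_PER_NM
from .errors import SelectionError
from .events import BindingEvent
from .trajectory import FrameSet, Selection

__all__ = [
    "CGMapping",
    "SymmetricLigand",
    "PoseRMSD",
    "cog_map",
    "kabsch_superpose",
    "plain_rmsd",
    "symmetry_rmsd",
    "rmsd_series",
    "find_modes",
    "cyclic_group",
    "dihedral_group",
]


@dataclass
class CGMapping:
    """Atom-index groups defining each bead (hydrogens included)."""

    beads: list[list[int]]
    size_classes: list[str] | None = None  # informational: R/S/T

    def __post_init__(self) -> None:
        if not self.beads or any(len(b) == 0 for b in self.beads):
            raise ValueError("every bead needs at least one atom")

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class SymmetricLigand:
    """Reference bead coordinates with their symmetry permutation group."""

    coordinates: np.ndarray                       # (m, 3), nm
    symmetry_permutations: list[tuple[int, ...]]  # closed group incl. identity

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        m = self.coordinates.shape[0]
        perms = {tuple(range(m))}
        for p in self.symmetry_permutations:
            p = tuple(int(i) for i in p)
            if sorted(p) != list(range(m)):
                raise ValueError(f"{p} is not a permutation of {m} beads")
            perms.add(p)
        # close under composition and inverse (small groups only)
        changed = True
        while changed:
            changed = False
            for a in list(perms):
                inv = tuple(np.argsort(a))
                if inv not in perms:
                    perms.add(inv)
                    changed = True
                for b in list(perms):
                    c = tuple(a[i] for i in b)
                    if c not in perms:
                        perms.add(c)
                        changed = True
        self.symmetry_permutations = sorted(perms)


@dataclass
class PoseRMSD:
    """Per-bound-frame RMSD series in Å."""

    times: np.ndarray
    rmsd: np.ndarray            # Å
    alignment_selection: str
    reference_id: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.rmsd))

    @property
    def std(self) -> float:
        return float(np.std(self.rmsd, ddof=1)) if self.rmsd.size > 1 else 0.0

    def summary(self) -> str:
        """Mean ± SD in the conventional one-decimal style, e.g. '1.4 ± 0.2 Å'."""
        return f"{self.mean:.1f} ± {self.std:.1f} Å"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_us": self.times, "rmsd_A": self.rmsd})


def cyclic_group(n: int, offset: int = 0) -> list[tuple[int, ...]]:
    """Cyclic rotations of beads offset..offset+n−1 (identity included)."""
    base = list(range(offset, offset + n))
    return [tuple(base[k:] + base[:k]) for k in range(n)]


def dihedral_group(n: int) -> list[tuple[int, ...]]:
    """Rotations plus order reversals of an n-bead ring."""
    rots = cyclic_group(n)
    flips = [tuple(reversed(p)) for p in rots]
    return sorted(set(rots + flips))


def cog_map(atom_positions: np.ndarray, mapping: CGMapping) -> np.ndarray:
    """Bead positions as unweighted centroids of their atom groups."""
    atom_positions = np.asarray(atom_positions, dtype=float)
    n_atoms = atom_positions.shape[0]
    out = np.empty((mapping.n_beads, 3))
    for k, atoms in enumerate(mapping.beads):
        idx = np.asarray(atoms, dtype=int)
        if np.any(idx < 0) or np.any(idx >= n_atoms):
            raise SelectionError(f"bead {k} maps atoms outside 0..{n_atoms - 1}")
        out[k] = atom_positions[idx].mean(axis=0)
    return out


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    selection: Selection | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares proper superposition of ``mobile`` onto ``target``.

    The rotation/translation is fitted on ``selection`` (all beads when
    None) and applied to the whole mobile frame.  Returns (R, t,
    transformed) with ``transformed = mobile @ R.T + t`` and det(R) = +1
    always — reflections are never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if selection is None:
        idx = np.arange(mobile.shape[0])
    elif isinstance(selection, Selection):
        idx = selection.indices
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size < 3:
        raise SelectionError("superposition needs at least three positions")
    a = target[idx]
    b = mobile[idx]
    a_cog = a.mean(axis=0)
    b_cog = b.mean(axis=0)
    spread = np.linalg.svd(b - b_cog, compute_uv=False)
    if spread[1] < 1e-10 * max(spread[0], 1.0):
        raise SelectionError("superposition selection is (nearly) collinear")
    rot, _ = Rotation.align_vectors(a - a_cog, b - b_cog)
    r_mat = rot.as_matrix()
    t = a_cog - r_mat @ b_cog
    return r_mat, t, mobile @ r_mat.T + t


def plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two equally ordered bead sets, in the input unit."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("bead sets must have equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def symmetry_rmsd(pose: np.ndarray, reference: SymmetricLigand) -> float:
    """Minimum RMSD over the reference's symmetry permutations, in Å.

    No re-fitting is done here: both bead sets are assumed to already sit
    in the pocket-aligned frame.  The permutation reorders the *reference*
    beads; the lowest value over the group is the physically meaningful
    RMSD for a symmetric ligand.
    """
    pose = np.asarray(pose, dtype=float)
    ref = reference.coordinates
    if pose.shape != ref.shape:
        raise ValueError("pose and reference bead counts differ")
    best = np.inf
    for perm in reference.symmetry_permutations:
        val = plain_rmsd(pose, ref[list(perm)])
        best = min(best, val)
    return best * ANGSTROM_PER_NM


def rmsd_series(
    frames: FrameSet,
    events: Sequence[BindingEvent],
    reference: SymmetricLigand,
    pocket_selection: Selection,
    ligand_selection: Selection,
    reference_pocket: np.ndarray | None = None,
    reference_id: str = "",
) -> PoseRMSD:
    """Symmetry-corrected ligand RMSD for every bound frame.

    Each bound frame (per the event list) is superposed onto the reference
    via the pocket selection, then the ligand beads are compared to the
    reference ligand with symmetry minimization.  ``reference_pocket``
    gives the target pocket coordinates; when None the first bound frame
    serves as the target (useful for synthetic data with a rigid pocket).
    """
    pocket_selection.validate_against(frames)
    ligand_selection.validate_against(frames)
    bound = np.zeros(frames.n_frames, dtype=bool)
    t_end = frames.times[-1]
    for ev in events:
        stop = ev.t_unbind if ev.t_unbind is not None else t_end
        bound |= (frames.times >= ev.t_bind) & (frames.times <= stop)
    if not np.any(bound):
        raise ValueError("no bound frames to analyse")

    idx_bound = np.flatnonzero(bound)
    if reference_pocket is None:
        reference_pocket = frames.positions[idx_bound[0]][pocket_selection.indices]
    target = np.asarray(reference_pocket, dtype=float)

    values = np.empty(idx_bound.size)
    for j, i in enumerate(idx_bound):
        frame = frames.positions[i]
        full_target = np.zeros_like(frame)
        # Build a target array only for the fitted subset; kabsch_superpose
        # fits on the pocket indices of both arrays.
        full_target[pocket_selection.indices] = target
        _, _, moved = kabsch_superpose(frame, full_target, pocket_selection)
        values[j] = symmetry_rmsd(moved[ligand_selection.indices], reference)
    return PoseRMSD(
        times=frames.times[idx_bound].copy(), rmsd=values,
        alignment_selection=pocket_selection.name, reference_id=reference_id,
    )


def find_modes(
    values: np.ndarray,
    bandwidth: float = 0.2,
    prominence: float = 0.05,
    grid_points: int = 512,
) -> np.ndarray:
    """Peak positions of a Gaussian-KDE of an RMSD sample, sorted by density.

    ``bandwidth`` is absolute (same unit as the data, typically Å).
    Multi-modal RMSD histograms indicate distinct conformational families;
    the returned array lists their positions with the densest first.  An
    all-equal sample returns that single value.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("mode detection needs at least 10 values")
    if np.ptp(values) == 0:
        return np.array([values[0]])
    kde = gaussian_kde(values)
    kde.set_bandwidth(bandwidth / values.std(ddof=1))
    lo = values.min() - 3 * bandwidth
    hi = values.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, grid_points)
    density = kde(grid)
    peaks, _ = find_peaks(density, prominence=prominence * density.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(density))])
    order = np.argsort(density[peaks])[::-1]
    return grid[peaks][order]
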