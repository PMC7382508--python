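"""Synthetic data with known ground truth.

Every downstream stage of the pipeline (distance series → events → PMF →
ΔG, pose RMSDs, density maps, pathway labels) is validated against data
whose statistics are imposed by construction rather than inherited from a
force field:

* :func:`simulate_ligand_bd` — a single point-like ligand performing
  overdamped Langevin (Brownian) dynamics in a periodic cubic box with an
  optional localized attractive well.  At equilibrium the radial density
  around the well center is exactly Boltzmann in the imposed potential, so
  the binding constant — and hence the standard-state binding free energy
  — is known analytically (:func:`analytic_binding_constant`).
* :func:`generate_pose_set` — copies of a reference bead cloud subjected to
  recorded rotations, translations, symmetry permutations and noise, for
  testing pocket superposition and symmetry-aware RMSDs.
* :func:`generate_region_scene` — a BD scene whose approach directions are
  partitioned into labelled angular channels with marker beads, for testing
  first-contact pathway classification against geometric ground truth.

Default scales emulate the statistical structure of coarse-grained
ligand-binding runs: a 10 nm cubic box holding one ligand (≈1.66 mM),
30 µs replicas, well depths of 15–30 kJ/mol and widths of 0.3–0.5 nm, and
an effective diffusion coefficient of 10 nm²/µs, which yields a handful of
binding/unbinding events per 30 µs replica.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from . import _bd_kernel
from .constants import DEFAULT_TEMPERATURE, rt
from .errors import IntegrationError
from .trajectory import FrameSet, Selection, Topology

__all__ = [
    "SyntheticModel",
    "BDResult",
    "simulate_ligand_bd",
    "simulate_ensemble",
    "analytic_binding_constant",
    "square_well_binding_constant",
    "sample_boltzmann_radii",
    "SyntheticPoseSpec",
    "PoseSet",
    "generate_pose_set",
    "RegionScene",
    "generate_region_scene",
]

_POTENTIAL_CODES = {"flat": 0, "square_well": 1, "gaussian_well": 2}
_NOISE_CHUNK = 1 << 17  # fixed so the RNG draw pattern never depends on n_steps


@dataclass
class SyntheticModel:
    """Parameters of the Brownian-dynamics scene.

    ``well_width`` is the radius of the square well or the σ of the
    Gaussian well.  The square well is smoothed over ``ramp_width`` (see
    :mod:`cgbind._bd_kernel`).
    """

    box_edge: float = 10.0                 # nm
    potential_kind: str = "gaussian_well"
    well_depth: float = 20.0               # kJ/mol, >= 0
    well_width: float = 0.3                # nm
    well_center: np.ndarray | None = None  # defaults to the box center
    diffusion_coefficient: float = 10.0    # nm^2/µs
    timestep: float = 2e-5                 # µs
    n_steps: int = 1_500_000               # 30 µs at the default timestep
    sample_stride: int = 25
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 2021
    ramp_width: float = 0.1                # nm, square-well smoothing

    def __post_init__(self) -> None:
        if self.potential_kind not in _POTENTIAL_CODES:
            raise ValueError(f"unknown potential_kind {self.potential_kind!r}")
        if self.box_edge <= 0 or self.timestep <= 0 or self.diffusion_coefficient <= 0:
            raise ValueError("box_edge, timestep and diffusion_coefficient must be > 0")
        if self.well_depth < 0:
            raise ValueError("well_depth is a depth and must be >= 0")
        if self.well_width >= self.box_edge / 2:
            raise ValueError("well_width must be below half the box edge")
        if self.sample_stride < 1 or self.n_steps < 1:
            raise ValueError("n_steps and sample_stride must be >= 1")
        if self.well_center is None:
            self.well_center = np.full(3, self.box_edge / 2.0)
        self.well_center = np.asarray(self.well_center, dtype=float)

    # -- imposed potential -------------------------------------------------

    def potential(self, r: np.ndarray) -> np.ndarray:
        """U(r) in kJ/mol at radial distance r (nm) from the well center."""
        r = np.asarray(r, dtype=float)
        if self.potential_kind == "flat" or self.well_depth == 0:
            return np.zeros_like(r)
        if self.potential_kind == "gaussian_well":
            return -self.well_depth * np.exp(-0.5 * (r / self.well_width) ** 2)
        inside = r < self.well_width
        ramp = (r >= self.well_width) & (r < self.well_width + self.ramp_width)
        u = np.zeros_like(r)
        u[inside] = -self.well_depth
        theta = np.pi * (r[ramp] - self.well_width) / self.ramp_width
        u[ramp] = -0.5 * self.well_depth * (1.0 + np.cos(theta))
        return u

    def max_force(self) -> float:
        """Upper bound on |dU/dr| in kJ/mol/nm, for stability checks."""
        if self.potential_kind == "flat" or self.well_depth == 0:
            return 0.0
        if self.potential_kind == "gaussian_well":
            return self.well_depth / (self.well_width * np.sqrt(np.e))
        return 0.5 * self.well_depth * np.pi / self.ramp_width


@dataclass
class BDResult:
    """One Brownian-dynamics replica.

    ``frames`` holds two beads per frame: bead 0 is a static marker at the
    well center (the "pocket"), bead 1 the ligand (wrapped into the primary
    image).  ``unwrapped`` is the ligand path without periodic wrapping,
    needed for displacement statistics.
    """

    frames: FrameSet
    unwrapped: np.ndarray
    model: SyntheticModel
    replica_index: int

    @property
    def pocket(self) -> Selection:
        return Selection("pocket", np.array([0]))

    @property
    def ligand(self) -> Selection:
        return Selection("ligand", np.array([1]))


def _stability_check(model: SyntheticModel) -> None:
    rt_ = rt(model.temperature)
    sigma = np.sqrt(2.0 * model.diffusion_coefficient * model.timestep)
    drift = model.diffusion_coefficient * model.timestep / rt_ * model.max_force()
    if not np.isfinite(drift):
        raise IntegrationError("non-finite force: ill-formed potential")
    if drift + 4.0 * sigma > model.box_edge / 4.0:
        raise IntegrationError(
            f"per-step displacement {drift + 4 * sigma:.3g} nm exceeds a quarter "
            f"box edge; reduce the timestep"
        )


def simulate_ligand_bd(model: SyntheticModel, replica_index: int = 0) -> BDResult:
    """Run one replica of overdamped Langevin dynamics.

    Update rule: x ← x − (D/RT)∇U Δt + √(2DΔt)·𝒩(0,1)³, followed by a
    periodic wrap.  The replica's RNG is seeded ``model.seed +
    replica_index`` so replicas are independent yet reproducible.
    """
    _stability_check(model)
    rng = np.random.default_rng(model.seed + replica_index)
    rt_ = rt(model.temperature)
    sigma = np.sqrt(2.0 * model.diffusion_coefficient * model.timestep)
    code = _POTENTIAL_CODES[model.potential_kind]
    eps = 0.0 if code == 0 else model.well_depth
    lx = ly = lz = model.box_edge
    cx, cy, cz = model.well_center

    # uniform start: exact equilibrium for a flat potential and a
    # near-equilibrium bulk start otherwise (the well occupies ≪ box volume);
    # a deterministic far-corner start leaves a relaxation transient that
    # measurably skews p(r) over 30 µs replicas
    pos = rng.uniform(0.0, model.box_edge, size=3)
    upos = pos.copy()

    n_samples = model.n_steps // model.sample_stride
    wrapped = np.empty((n_samples + 1, 3))
    unwrapped = np.empty((n_samples + 1, 3))
    wrapped[0] = pos
    unwrapped[0] = upos
    k = 1

    done = 0
    mobility_dt = model.diffusion_coefficient * model.timestep / rt_
    while done < model.n_steps:
        n = min(_NOISE_CHUNK, model.n_steps - done)
        noise = rng.standard_normal((_NOISE_CHUNK, 3))[:n] * sigma
        k = _bd_kernel.advance_chunk(
            pos, upos, noise, code, eps, model.well_width, model.ramp_width,
            cx, cy, cz, lx, ly, lz, mobility_dt,
            model.sample_stride, done, wrapped, unwrapped, k,
        )
        done += n
        if not np.all(np.isfinite(pos)):
            raise IntegrationError("non-finite position: integration diverged")

    times = np.arange(n_samples + 1) * (model.sample_stride * model.timestep)
    positions = np.empty((n_samples + 1, 2, 3))
    positions[:, 0, :] = model.well_center
    positions[:, 1, :] = wrapped[: n_samples + 1]
    topo = Topology(names=["WELL", "LIG"], resids=np.array([1, 2]),
                    resnames=["WEL", "LIG"])
    frames = FrameSet(times=times, positions=positions,
                      box=np.full(3, model.box_edge), topology=topo)
    return BDResult(frames=frames, unwrapped=unwrapped[: n_samples + 1],
                    model=model, replica_index=replica_index)


def simulate_ensemble(model: SyntheticModel, n_replicas: int) -> list[BDResult]:
    """Independent replicas seeded ``model.seed + i`` for i in 0..n-1."""
    return [simulate_ligand_bd(model, i) for i in range(n_replicas)]


# ---------------------------------------------------------------------------
# analytic references
# ---------------------------------------------------------------------------

def analytic_binding_constant(model: SyntheticModel, r_c: float) -> float:
    """K_bind = ∫₀^{r_c} 4πr² e^(−U(r)/RT) dr for the imposed potential (nm³).

    Evaluated by adaptive quadrature of the potential actually simulated
    (including the square-well smoothing ramp); this is the ground truth the
    estimated PMF pipeline must recover.
    """
    if r_c > model.box_edge / 2.0:
        raise ValueError("r_c exceeds half the box edge; bulk not representable")
    rt_ = rt(model.temperature)

    def integrand(r: float) -> float:
        return 4.0 * np.pi * r * r * np.exp(-float(model.potential(r)) / rt_)

    pts = [model.well_width, model.well_width + model.ramp_width,
           3.0 * model.well_width]
    pts = sorted(p for p in pts if 0 < p < r_c)
    val, _ = quad(integrand, 0.0, r_c, points=pts or None, limit=200)
    return float(val)


def square_well_binding_constant(
    r_w: float, depth: float, temperature: float, r_c: float
) -> float:
    """Closed form for an ideal (unsmoothed) square well, nm³:

    K = (4π/3)[r_w³ e^(ε/RT) + (r_c³ − r_w³)]
    """
    rt_ = rt(temperature)
    return (4.0 * np.pi / 3.0) * (
        r_w**3 * np.exp(depth / rt_) + (r_c**3 - r_w**3)
    )


def sample_boltzmann_radii(
    model: SyntheticModel,
    n: int,
    r_max: float | None = None,
    seed: int | None = None,
    grid_points: int = 4096,
) -> np.ndarray:
    """Direct equilibrium samples of the radial distance by 1D inverse-CDF.

    Samples r with density ∝ 4πr² e^(−U(r)/RT) on [0, r_max].  This is an
    independent route to the same equilibrium the BD integrator should
    reach, and serves as its statistical oracle.
    """
    if r_max is None:
        r_max = model.box_edge / 2.0
    rng = np.random.default_rng(model.seed if seed is None else seed)
    r = np.linspace(0.0, r_max, grid_points)
    w = 4.0 * np.pi * r**2 * np.exp(-model.potential(r) / rt(model.temperature))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(r))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, r)


# ---------------------------------------------------------------------------
# pose fixtures
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPoseSpec:
    """Recipe for a set of perturbed copies of a reference bead cloud."""

    reference_beads: np.ndarray                     # (m, 3), nm
    symmetry_permutations: Sequence[Sequence[int]] = ()
    rotation_magnitude: float = 0.0                 # rad
    translation_magnitude: float = 0.0              # nm
    positional_noise: float = 0.0                   # nm, isotropic per bead
    n_poses: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference_beads = np.asarray(self.reference_beads, dtype=float)
        if self.reference_beads.ndim != 2 or self.reference_beads.shape[0] == 0:
            raise ValueError("reference_beads must be a non-empty (m, 3) array")
        m = self.reference_beads.shape[0]
        perms = [tuple(range(m))]
        for p in self.symmetry_permutations:
            p = tuple(int(i) for i in p)
            if sorted(p) != list(range(m)):
                raise ValueError(f"permutation {p} is not a bijection on {m} beads")
            if p not in perms:
                perms.append(p)
        self.symmetry_permutations = perms  # identity always present, first


@dataclass
class PoseSet:
    """Generated poses plus the exact transforms that produced them."""

    poses: np.ndarray                       # (n_poses, m, 3)
    reference: np.ndarray                   # (m, 3)
    rotations: np.ndarray                   # (n_poses, 3, 3)
    translations: np.ndarray                # (n_poses, 3)
    permutations: list[tuple[int, ...]]
    spec: SyntheticPoseSpec


def generate_pose_set(spec: SyntheticPoseSpec) -> PoseSet:
    """Perturbed copies of the reference with recorded ground truth.

    Each pose is ``R @ reference[π] + t + noise`` with a random proper
    rotation of angle ≤ rotation_magnitude, a random translation of norm ≤
    translation_magnitude, a symmetry permutation π drawn uniformly from the
    spec's group, and isotropic Gaussian bead noise.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference_beads
    poses = np.empty((spec.n_poses, *ref.shape))
    rotations = np.empty((spec.n_poses, 3, 3))
    translations = np.empty((spec.n_poses, 3))
    permutations: list[tuple[int, ...]] = []
    for i in range(spec.n_poses):
        if spec.rotation_magnitude > 0:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(0.0, spec.rotation_magnitude)
            rot = Rotation.from_rotvec(axis * angle).as_matrix()
        else:
            rot = np.eye(3)
        if spec.translation_magnitude > 0:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            t = direction * rng.uniform(0.0, spec.translation_magnitude)
        else:
            t = np.zeros(3)
        perm = spec.symmetry_permutations[rng.integers(len(spec.symmetry_permutations))]
        pose = ref[list(perm)] @ rot.T + t
        if spec.positional_noise > 0:
            pose = pose + rng.standard_normal(ref.shape) * spec.positional_noise
        poses[i] = pose
        rotations[i] = rot
        translations[i] = t
        permutations.append(perm)
    return PoseSet(poses=poses, reference=ref.copy(), rotations=rotations,
                   translations=translations, permutations=permutations, spec=spec)


# ---------------------------------------------------------------------------
# pathway scenes
# ---------------------------------------------------------------------------

@dataclass
class RegionScene:
    """A BD scene with labelled angular approach channels.

    The full solid angle around the well is partitioned into ``n_channels``
    azimuthal wedges (widths ∝ ``width_ratios``) and decorated with static
    marker beads on a sphere of radius ``marker_radius``.  The geometric
    ground-truth channel of a binding approach is the wedge containing the
    ligand's azimuth when it first enters the marker shell.
    """

    model: SyntheticModel
    marker_positions: np.ndarray          # (M, 3) static beads
    marker_channel: np.ndarray            # (M,) channel index per marker
    channel_edges: np.ndarray             # (n_channels + 1,) azimuth bounds, rad
    marker_radius: float
    contact_cutoff: float

    @property
    def n_channels(self) -> int:
        return len(self.channel_edges) - 1

    def channel_names(self) -> list[str]:
        return [f"channel_{i}" for i in range(self.n_channels)]

    def attach_markers(
        self,
        result: BDResult,
        t_min: float | None = None,
        t_max: float | None = None,
    ) -> FrameSet:
        """FrameSet with beads [markers..., WELL, LIG] for pathway analysis.

        Restrict to a time window to keep the materialized array small —
        marker beads are static, so only the window around each binding
        event is ever needed.
        """
        times = result.frames.times
        keep = np.ones(times.size, dtype=bool)
        if t_min is not None:
            keep &= times >= t_min
        if t_max is not None:
            keep &= times <= t_max
        idx = np.flatnonzero(keep)
        m = self.marker_positions.shape[0]
        positions = np.empty((idx.size, m + 2, 3))
        positions[:, :m, :] = self.marker_positions[None, :, :]
        positions[:, m, :] = self.model.well_center
        positions[:, m + 1, :] = result.frames.positions[idx, 1, :]
        names = [f"MK{i}" for i in range(m)] + ["WELL", "LIG"]
        topo = Topology(names=names, resids=np.arange(1, m + 3),
                        resnames=["MRK"] * m + ["WEL", "LIG"])
        return FrameSet(times=times[idx].copy(), positions=positions,
                        box=result.frames.box.copy(), topology=topo)

    def region_groups(self) -> dict[str, np.ndarray]:
        """Marker bead indices per channel, in attach_markers() ordering."""
        return {
            name: np.flatnonzero(self.marker_channel == i)
            for i, name in enumerate(self.channel_names())
        }

    def ligand_index(self) -> int:
        return self.marker_positions.shape[0] + 1

    def azimuth_channel(self, position: np.ndarray) -> int:
        """Wedge index for a ligand position (minimum-image, xy azimuth)."""
        d = position - self.model.well_center
        box = self.model.box_edge
        d = d - box * np.round(d / box)
        phi = float(np.arctan2(d[1], d[0])) % (2.0 * np.pi)
        idx = int(np.searchsorted(self.channel_edges, phi, side="right") - 1)
        return min(max(idx, 0), self.n_channels - 1)

    def true_channel_labels(
        self,
        result: BDResult,
        bind_times: Sequence[float],
        lookback: float = 1.0,
    ) -> list[str]:
        """Ground-truth channel per binding time.

        For each binding time, find the first frame of the look-back window
        [t_bind − lookback, t_bind] at which the ligand sits inside the
        marker contact shell (|r − marker_radius| ≤ cutoff); the azimuthal
        wedge at that frame is the label.  Purely geometric — no marker
        beads involved — so it is an independent oracle for the
        contact-based classifier, which sees the same crossing through
        discrete marker beads.
        """
        box = self.model.box_edge
        d = result.frames.positions[:, 1, :] - self.model.well_center
        d = d - box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        times = result.frames.times
        in_shell = np.abs(r - self.marker_radius) <= self.contact_cutoff
        labels = []
        names = self.channel_names()
        for t_bind in bind_times:
            window = np.flatnonzero(
                (times >= t_bind - lookback) & (times <= t_bind) & in_shell
            )
            i_entry = window[0] if window.size else int(
                min(np.searchsorted(times, t_bind), len(times) - 1))
            labels.append(names[self.azimuth_channel(
                result.frames.positions[i_entry, 1, :])])
        return labels


def generate_region_scene(
    n_channels: int,
    width_ratios: Sequence[float] | None = None,
    marker_radius: float = 1.0,
    marker_spacing: float = 0.05,
    contact_cutoff: float = 0.15,
    seed: int = 0,
    **model_kwargs,
) -> RegionScene:
    """Build a BD scene whose binding approaches carry channel labels.

    Markers are laid out on a Fibonacci sphere around the well center and
    assigned to azimuthal wedges whose widths are proportional to
    ``width_ratios`` (equal by default).  Because the imposed potential is
    isotropic, approach azimuths are uniform and the expected event
    fraction of each channel equals its fractional width.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if width_ratios is None:
        width_ratios = [1.0] * n_channels
    width_ratios = np.asarray(width_ratios, dtype=float)
    if width_ratios.size != n_channels or np.any(width_ratios <= 0):
        raise ValueError("width_ratios must give one positive weight per channel")
    edges = np.concatenate([[0.0], np.cumsum(width_ratios)])
    edges = edges / edges[-1] * 2.0 * np.pi

    model = SyntheticModel(seed=seed, **model_kwargs)
    if marker_radius + contact_cutoff >= model.box_edge / 2.0:
        raise ValueError("marker shell does not fit in the box")

    n_markers = max(int(np.ceil(4.0 * np.pi * marker_radius**2 / marker_spacing**2)), 16)
    i = np.arange(n_markers)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_markers
    rho = np.sqrt(1.0 - z**2)
    phi = (golden * i) % (2.0 * np.pi)
    unit = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    positions = model.well_center + marker_radius * unit
    channel = np.clip(np.searchsorted(edges, phi, side="right") - 1, 0, n_channels - 1)
    return RegionScene(model=model, marker_positions=positions,
                       marker_channel=channel, channel_edges=edges,
                       marker_radius=marker_radius, contact_cutoff=contact_cutoff)
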