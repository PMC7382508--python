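"""Binding/unbinding event detection and association kinetics.

Events are defined on the pocket–ligand distance series by a two-threshold
(hysteresis) state machine: the ligand becomes *bound* when the distance
stays below ``r_on`` for at least ``min_dwell``, and *unbound* again when
it stays above ``r_off`` for at least ``min_dwell``.  The gap between the
two thresholds suppresses rapid recrossing noise at the pocket mouth.  An
interval that is still bound when the trajectory ends is kept as an open
event: it contributes bound time but no unbinding count, which is the
correct bookkeeping when long-lived bound states outlast the replicas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import N_AVOGADRO, WATER_NUMBER_DENSITY, WATERS_PER_CG_BEAD
from .trajectory import DistanceSeries

__all__ = [
    "EventCriteria",
    "BindingEvent",
    "EventSummary",
    "detect_events",
    "summarize",
    "events_to_dataframe",
    "ligand_concentration",
    "water_beads_to_volume",
    "estimate_kon",
]


@dataclass(frozen=True)
class EventCriteria:
    """Hysteresis thresholds (nm) and minimum dwell time (µs)."""

    r_on: float = 0.7
    r_off: float = 1.5
    min_dwell: float = 0.01

    def __post_init__(self) -> None:
        if self.r_on >= self.r_off:
            raise ValueError("hysteresis requires r_on < r_off")
        if self.min_dwell < 0:
            raise ValueError("min_dwell must be >= 0")


@dataclass
class BindingEvent:
    """One bound interval.

    ``bound_at_start`` marks an interval already bound on the first frame
    (no binding transition was observed); ``t_unbind is None`` marks an
    interval still bound at the end of the trajectory.
    """

    replica_id: str
    t_bind: float
    t_unbind: float | None = None
    bound_at_start: bool = False
    pathway_label: str | None = None
    lipid_first: bool | None = None

    def __post_init__(self) -> None:
        if self.t_unbind is not None and self.t_unbind <= self.t_bind:
            raise ValueError("t_unbind must exceed t_bind")

    def duration(self, t_end: float) -> float:
        """Bound time in µs, closing an open event at ``t_end``."""
        return (self.t_unbind if self.t_unbind is not None else t_end) - self.t_bind


def _sustained_until(flags: np.ndarray, times: np.ndarray, start: int, dwell: float) -> bool:
    """True if ``flags`` stays set from ``start`` for at least ``dwell``."""
    t0 = times[start]
    i = start
    n = len(flags)
    while i < n and flags[i]:
        if times[i] - t0 >= dwell:
            return True
        i += 1
    # a run reaching the last frame counts as sustained (no evidence against)
    return i == n


def detect_events(series: DistanceSeries, criteria: EventCriteria) -> list[BindingEvent]:
    """Run the hysteresis automaton over one distance series.

    The initial state is taken from the first frame relative to ``r_off``:
    a trajectory starting inside the hysteresis band is treated as bound
    (flagged ``bound_at_start``, not counted as a binding transition).
    Guarantees |#bind − #unbind| ≤ 1 per series, with strict alternation.
    """
    r = series.distances
    t = series.times
    below_on = r < criteria.r_on
    above_off = r > criteria.r_off

    events: list[BindingEvent] = []
    bound = bool(r[0] < criteria.r_off)
    if bound:
        current = BindingEvent(series.replica_id, t_bind=float(t[0]), bound_at_start=True)
    i = 0
    n = len(r)
    while i < n:
        if not bound:
            if below_on[i] and _sustained_until(below_on, t, i, criteria.min_dwell):
                bound = True
                current = BindingEvent(series.replica_id, t_bind=float(t[i]))
                # jump past the confirming dwell window
                while i < n and below_on[i]:
                    i += 1
                continue
        else:
            if above_off[i] and _sustained_until(above_off, t, i, criteria.min_dwell):
                bound = False
                current.t_unbind = float(t[i])
                events.append(current)
                current = None
                while i < n and above_off[i]:
                    i += 1
                continue
        i += 1
    if bound:
        events.append(current)  # open-ended
    return events


@dataclass
class EventSummary:
    """Per-replica and aggregate event statistics."""

    bind_counts: dict[str, int]
    unbind_counts: dict[str, int]
    total_bind: int
    total_unbind: int
    min_bind: int
    max_bind: int
    min_unbind: int
    max_unbind: int
    bound_fraction: float
    total_time: float                 # µs
    replicas_without_unbinding: int   # replicas holding an open event

    def as_dict(self) -> dict:
        return {
            "total_bind": self.total_bind,
            "total_unbind": self.total_unbind,
            "min_bind": self.min_bind,
            "max_bind": self.max_bind,
            "min_unbind": self.min_unbind,
            "max_unbind": self.max_unbind,
            "bound_fraction": self.bound_fraction,
            "total_time_us": self.total_time,
            "replicas_without_unbinding": self.replicas_without_unbinding,
        }


def summarize(
    events_by_replica: dict[str, Sequence[BindingEvent]],
    replica_durations: dict[str, float],
) -> EventSummary:
    """Totals, per-replica min/max and the overall bound time fraction.

    ``replica_durations`` maps replica id → trajectory length in µs; open
    events are closed at that length when accumulating bound time.
    """
    bind_counts: dict[str, int] = {}
    unbind_counts: dict[str, int] = {}
    bound_time = 0.0
    open_replicas = 0
    for rid, duration in replica_durations.items():
        evs = list(events_by_replica.get(rid, ()))
        for ev in evs:
            end = ev.t_unbind if ev.t_unbind is not None else duration
            if ev.t_bind < 0 or end > duration + 1e-9:
                raise ValueError(
                    f"event [{ev.t_bind}, {end}] outside replica {rid!r} span"
                )
            bound_time += ev.duration(duration)
        bind_counts[rid] = sum(1 for ev in evs if not ev.bound_at_start)
        unbind_counts[rid] = sum(1 for ev in evs if ev.t_unbind is not None)
        if any(ev.t_unbind is None for ev in evs):
            open_replicas += 1
    total_time = float(sum(replica_durations.values()))
    binds = list(bind_counts.values()) or [0]
    unbinds = list(unbind_counts.values()) or [0]
    return EventSummary(
        bind_counts=bind_counts,
        unbind_counts=unbind_counts,
        total_bind=int(sum(binds)),
        total_unbind=int(sum(unbinds)),
        min_bind=int(min(binds)),
        max_bind=int(max(binds)),
        min_unbind=int(min(unbinds)),
        max_unbind=int(max(unbinds)),
        bound_fraction=bound_time / total_time if total_time > 0 else 0.0,
        total_time=total_time,
        replicas_without_unbinding=open_replicas,
    )


def events_to_dataframe(events: Iterable[BindingEvent]) -> pd.DataFrame:
    """Flat table of events (for CSV export)."""
    rows = [
        {
            "replica_id": ev.replica_id,
            "t_bind_us": ev.t_bind,
            "t_unbind_us": ev.t_unbind,
            "bound_at_start": ev.bound_at_start,
            "pathway_label": ev.pathway_label,
            "lipid_first": ev.lipid_first,
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=["replica_id", "t_bind_us", "t_unbind_us", "bound_at_start",
                 "pathway_label", "lipid_first"],
    )


# ---------------------------------------------------------------------------
# concentration and kinetics
# ---------------------------------------------------------------------------

def ligand_concentration(n_ligands: int, box: Sequence[float] | float) -> float:
    """Ligand concentration in mM for n ligands in an orthorhombic box (nm).

    c = n / (N_A V); one ligand in a 10 nm cube is 1.66 mM.
    """
    edges = np.atleast_1d(np.asarray(box, dtype=float))
    if edges.size == 1:
        edges = np.repeat(edges, 3)
    volume_nm3 = float(np.prod(edges))
    if volume_nm3 <= 0:
        raise ValueError("box volume must be positive")
    volume_l = volume_nm3 * 1e-24
    return n_ligands / (N_AVOGADRO * volume_l) * 1e3  # M → mM


def water_beads_to_volume(
    n_beads: int,
    waters_per_bead: int = WATERS_PER_CG_BEAD,
    number_density: float = WATER_NUMBER_DENSITY,
) -> float:
    """Approximate solvent volume (nm³) represented by CG water beads.

    Useful when a box edge is not reported but the water-bead count is:
    V ≈ n_beads · waters_per_bead / ρ_water.
    """
    if n_beads < 0:
        raise ValueError("bead count must be non-negative")
    return n_beads * waters_per_bead / number_density


def estimate_kon(
    n_bind: int,
    total_time: float,
    bound_fraction: float,
    concentration: float,
    correct_for_bound_time: bool = True,
) -> float:
    """Association rate constant in s⁻¹ µM⁻¹.

    k_on = n_bind / (T_unbound · c) with T_unbound = total_time·(1 − f_bound)
    in µs and c in mM.  Association can only occur from the unbound state,
    so the unbound-time correction is on by default; pass
    ``correct_for_bound_time=False`` for the naive total-time estimate.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    if not 0.0 <= bound_fraction < 1.0:
        raise ValueError("bound_fraction must lie in [0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    t_eff_us = total_time * (1.0 - bound_fraction) if correct_for_bound_time else total_time
    t_eff_s = t_eff_us * 1e-6
    conc_um = concentration * 1e3  # mM → µM
    return n_bind / (t_eff_s * conc_um)
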