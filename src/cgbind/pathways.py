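"""Binding-pathway classification from first contacts with labelled regions.

A binding event is assigned an approach route by watching which named
region (extracellular loop, helix pair, lipid headgroups, a synthetic
channel …) the ligand touches first in a look-back window before the
binding moment.  "Touch" means any ligand bead within ``contact_cutoff``
of any region bead under the minimum-image convention.  Lipid-tagged
regions additionally feed a ``lipid_first`` flag: the fraction of events
whose very first contact is with a lipid region quantifies membrane-
mediated binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import BindingEvent
from .trajectory import FrameSet, Selection, minimum_image_displacement

__all__ = [
    "RegionSet",
    "contact_sequence",
    "classify_events",
    "PathwaySummary",
]


@dataclass
class RegionSet:
    """Named bead groups with a contact cutoff and look-back window."""

    groups: dict[str, np.ndarray]          # name → bead indices
    contact_cutoff: float = 0.6            # nm
    lookback: float = 1.0                  # µs before t_bind
    lipid_regions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("RegionSet needs at least one region")
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}
        for name, idx in self.groups.items():
            if idx.size == 0:
                raise ValueError(f"region {name!r} is empty")
        all_idx = np.concatenate(list(self.groups.values()))
        if len(np.unique(all_idx)) != all_idx.size:
            warnings.warn("regions overlap; contacts will be multi-counted",
                          stacklevel=2)
        unknown = set(self.lipid_regions) - set(self.groups)
        if unknown:
            raise ValueError(f"lipid_regions {unknown} not defined in groups")


def contact_sequence(
    event: BindingEvent,
    frames: FrameSet,
    ligand: Selection,
    regions: RegionSet,
) -> list[tuple[str, float]]:
    """Ordered (region, first-contact time) pairs in the pre-binding window.

    The window is [t_bind − lookback, t_bind], clipped to the trajectory.
    Regions never touched are omitted.  When two regions are first touched
    on the same frame (a boundary approach), the closer region at that
    frame comes first; remaining ties break by name.
    """
    ligand.validate_against(frames)
    t_lo = event.t_bind - regions.lookback
    in_window = (frames.times >= t_lo) & (frames.times <= event.t_bind)
    idx = np.flatnonzero(in_window)
    if idx.size == 0:
        return []
    firsts: list[tuple[str, float, float]] = []
    for name in sorted(regions.groups):
        hit = _first_contact_frame(frames, idx, ligand.indices,
                                   regions.groups[name], regions.contact_cutoff)
        if hit is not None:
            frame, dist = hit
            firsts.append((name, float(frames.times[frame]), dist))
    firsts.sort(key=lambda nt: (nt[1], nt[2], nt[0]))
    return [(name, t) for name, t, _ in firsts]


_CHUNK = 256  # frames per distance block, bounds peak memory


def _contact_flags(frames, idx, lig_idx, reg_idx, cutoff):
    """Boolean per window frame: any ligand bead within cutoff of the region."""
    flags = np.empty(idx.size, dtype=bool)
    for s in range(0, idx.size, _CHUNK):
        block = idx[s : s + _CHUNK]
        lig = frames.positions[np.ix_(block, lig_idx)]      # (w, L, 3)
        reg = frames.positions[np.ix_(block, reg_idx)]      # (w, G, 3)
        d = minimum_image_displacement(
            lig[:, :, None, :], reg[:, None, :, :], frames.box
        )
        dist = np.linalg.norm(d, axis=-1)                   # (w, L, G)
        flags[s : s + block.size] = np.min(dist, axis=(1, 2)) <= cutoff
    return flags


def _first_contact_frame(frames, idx, lig_idx, reg_idx, cutoff):
    """(frame index, min distance at that frame) of the first contact."""
    for s in range(0, idx.size, _CHUNK):
        block = idx[s : s + _CHUNK]
        lig = frames.positions[np.ix_(block, lig_idx)]
        reg = frames.positions[np.ix_(block, reg_idx)]
        d = minimum_image_displacement(
            lig[:, :, None, :], reg[:, None, :, :], frames.box
        )
        dist = np.min(np.linalg.norm(d, axis=-1), axis=(1, 2))
        hits = np.flatnonzero(dist <= cutoff)
        if hits.size:
            return int(block[hits[0]]), float(dist[hits[0]])
    return None


@dataclass
class PathwaySummary:
    """Per-route counts/fractions plus the lipid-first fraction."""

    counts: dict[str, int]
    fractions: dict[str, float]
    lipid_first_fraction: float | None
    n_events: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"route": list(self.counts), "count": list(self.counts.values()),
             "fraction": [self.fractions[k] for k in self.counts]}
        )


def _dominant_contact(
    event: BindingEvent,
    frames: FrameSet,
    ligand: Selection,
    regions: RegionSet,
) -> str | None:
    """Region with the most contact frames in the window."""
    t_lo = event.t_bind - regions.lookback
    in_window = (frames.times >= t_lo) & (frames.times <= event.t_bind)
    idx = np.flatnonzero(in_window)
    if idx.size == 0:
        return None
    best_name, best_frames = None, 0
    for name in sorted(regions.groups):
        flags = _contact_flags(frames, idx, ligand.indices,
                               regions.groups[name], regions.contact_cutoff)
        n_contact = int(np.sum(flags))
        if n_contact > best_frames:
            best_name, best_frames = name, n_contact
    return best_name


def classify_events(
    events: Sequence[BindingEvent],
    frames: FrameSet | Sequence[FrameSet],
    ligand: Selection,
    regions: RegionSet,
    rule: str = "first_contact",
) -> PathwaySummary:
    """Label every event by its approach route and tally fractions.

    ``rule`` is ``first_contact`` (region touched first) or
    ``dominant_contact`` (region with most contact frames in the window).
    Events with no region contact are labelled ``unclassified`` and kept in
    the denominator, so fractions over all labels sum to 1.  When
    ``frames`` is a sequence it is indexed by each event's replica id
    (``replica-<i>`` or plain integer order).

    Side effects: each event's ``pathway_label`` and ``lipid_first`` fields
    are filled in.
    """
    if rule not in {"first_contact", "dominant_contact"}:
        raise ValueError(f"unknown rule {rule!r}")
    if not events:
        raise ValueError("no events to classify")
    frame_sets = [frames] if isinstance(frames, FrameSet) else list(frames)

    def frames_for(ev: BindingEvent) -> FrameSet:
        if len(frame_sets) == 1:
            return frame_sets[0]
        tag = ev.replica_id.rsplit("-", 1)[-1]
        return frame_sets[int(tag)]

    counts: dict[str, int] = {}
    n_lipid_first = 0
    n_with_contact = 0
    for ev in events:
        fs = frames_for(ev)
        seq = contact_sequence(ev, fs, ligand, regions)
        if rule == "first_contact":
            label = seq[0][0] if seq else None
        else:
            label = _dominant_contact(ev, fs, ligand, regions)
        ev.pathway_label = label or "unclassified"
        counts[ev.pathway_label] = counts.get(ev.pathway_label, 0) + 1
        if seq:
            n_with_contact += 1
            ev.lipid_first = seq[0][0] in regions.lipid_regions
            if ev.lipid_first:
                n_lipid_first += 1
        else:
            ev.lipid_first = None
    n = len(events)
    fractions = {k: v / n for k, v in counts.items()}
    lipid_first = (n_lipid_first / n_with_contact) if (
        regions.lipid_regions and n_with_contact
    ) else (0.0 if regions.lipid_regions else None)
    return PathwaySummary(counts=counts, fractions=fractions,
                          lipid_first_fraction=lipid_first, n_events=n)
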