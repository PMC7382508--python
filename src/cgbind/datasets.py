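"""Published benchmark numbers used as inputs to worked examples.

These are printed benchmark values for ligand binding to the L99A (and
L99A/M102Q) mutants of T4 lysozyme and to the c-Src kinase domain:
simulated standard-state binding free energies, the corresponding
experimental values (calorimetric first, NMR second where both exist), and
the event/sampling bookkeeping of the published runs.  They serve as fixed
inputs for the comparison and kinetics helpers, not as quantities this
package computes.
"""

from __future__ import annotations

__all__ = [
    "T4_LYSOZYME_DELTA_G",
    "T4_LYSOZYME_EVENTS",
    "T4_BOX_EDGE_NM",
    "T4_N_WATER_BEADS",
    "T4_N_REPLICAS",
    "T4_REPLICA_LENGTH_US",
    "CSRC_N_WATER_BEADS",
    "CSRC_N_BINDING_EVENTS",
    "CSRC_TOTAL_TIME_US",
    "CSRC_BOUND_FRACTION",
    "CSRC_CONCENTRATION_MM",
]

#: system → (ΔG_sim, ΔG_exp) in kJ/mol.  ΔG_exp is None for non-binders,
#: a tuple (calorimetric, NMR) where two experimental values exist.
T4_LYSOZYME_DELTA_G: dict[str, tuple[float, object]] = {
    "phenol": (-15.6, None),
    "thieno-pyridine": (-17.3, None),
    "benzene_M102Q": (-17.0, None),
    "benzene": (-18.6, (-21.7, -17.7)),
    "indole": (-20.2, (-20.5, -19.7)),
    "toluene_M102Q": (-19.6, -20.6),
    "toluene": (-21.2, -23.1),
    "ethylbenzene": (-23.1, -24.1),
    "n-propylbenzene": (-25.4, -27.4),
}

#: system → (total binding events, total unbinding events) over 30×30 µs.
T4_LYSOZYME_EVENTS: dict[str, tuple[int, int]] = {
    "phenol": (37, 37),
    "thieno-pyridine": (41, 29),
    "benzene_M102Q": (245, 238),
    "benzene": (156, 147),
    "indole": (59, 43),
    "toluene_M102Q": (148, 132),
    "toluene": (83, 60),
    "ethylbenzene": (67, 44),
    "n-propylbenzene": (68, 43),
}

T4_BOX_EDGE_NM = 10.0
T4_N_WATER_BEADS = 8850
T4_N_REPLICAS = 30
T4_REPLICA_LENGTH_US = 30.0

CSRC_N_WATER_BEADS = 14_500
CSRC_N_BINDING_EVENTS = 11
CSRC_TOTAL_TIME_US = 300.0
CSRC_BOUND_FRACTION = 0.08
CSRC_CONCENTRATION_MM = 0.96
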