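"""Shared fixtures: small Brownian-dynamics ensembles reused across tests."""

import numpy as np
import pytest

from cgbind.synthetic import SyntheticModel, simulate_ensemble
from cgbind.trajectory import distance_series


def make_series(results):
    return [
        distance_series(r.frames, r.pocket, r.ligand, replica_id=f"replica-{i}")
        for i, r in enumerate(results)
    ]


@pytest.fixture(scope="session")
def well_model():
    """Gaussian well, 20 kJ/mol, default study-scale box."""
    return SyntheticModel(potential_kind="gaussian_well", well_depth=20.0,
                          well_width=0.3, n_steps=1_500_000, seed=314)


@pytest.fixture(scope="session")
def well_ensemble(well_model):
    """Sixteen 30 µs replicas in the 20 kJ/mol Gaussian well.

    Bound dwell times are heavy-tailed, so the ensemble bound fraction
    converges slowly; 16 replicas keep its scatter near 15%.
    """
    return simulate_ensemble(well_model, 16)


@pytest.fixture(scope="session")
def well_series(well_ensemble):
    return make_series(well_ensemble)


@pytest.fixture(scope="session")
def flat_model():
    return SyntheticModel(potential_kind="flat", well_depth=0.0,
                          n_steps=1_500_000, seed=2718)


@pytest.fixture(scope="session")
def flat_ensemble(flat_model):
    # 12 replicas: the per-bin bootstrap band needs a well-estimated SD
    return simulate_ensemble(flat_model, 12)


@pytest.fixture(scope="session")
def flat_series(flat_ensemble):
    return make_series(flat_ensemble)


@pytest.fixture()
def rng():
    return np.random.default_rng(8675309)
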