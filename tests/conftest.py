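"""Shared fixtures.

The heavy study cells (N_e=500 with V_k in {2, 400} for three marker
classes) are simulated once per session and shared between the acceptance
tests and the property tests; every cell derives its replicate seeds from a
fixed master seed, so the suite is deterministic.
"""

import numpy as np
import pytest

from sweepstakes import experiment
from sweepstakes.coalescent import NullCache

MASTER_SEED = 20240917


@pytest.fixture(scope="session")
def null_cache():
    return NullCache(MASTER_SEED)


def _cell(ne, vk, marker, reps, cache):
    return experiment.run_cell(
        ne, vk, reps, marker_type=marker, seed=MASTER_SEED, cache=cache)


@pytest.fixture(scope="session")
def cell_ms_vk2(null_cache):
    """30 microsatellite replicates at N_e=500, Poisson reproduction."""
    return _cell(500, 2, "microsat", 30, null_cache)


@pytest.fixture(scope="session")
def cell_ms_vk400(null_cache):
    """30 microsatellite replicates at N_e=500, V_k=400 (census 50250)."""
    return _cell(500, 400, "microsat", 30, null_cache)


@pytest.fixture(scope="session")
def cell_constr_vk2(null_cache):
    return _cell(500, 2, "microsat_constrained", 30, null_cache)


@pytest.fixture(scope="session")
def cell_constr_vk400(null_cache):
    return _cell(500, 400, "microsat_constrained", 30, null_cache)


@pytest.fixture(scope="session")
def cell_seq_vk2(null_cache):
    """60 sequence replicates; extra replicates because S=0 datasets carry
    no Tajima information at theta=0.1."""
    return _cell(500, 2, "sequence", 60, null_cache)


@pytest.fixture(scope="session")
def cell_seq_vk400(null_cache):
    return _cell(500, 400, "sequence", 60, null_cache)


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)
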