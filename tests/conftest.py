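import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pgstransmit as pt

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_admissible_params(rng) -> pt.ModelParameters:
    """Draw one admissible parameter point, broad but numerically safe."""
    return pt.ModelParameters(
        v_pgs=float(rng.uniform(0.2, 3.0)),
        r_a=float(rng.uniform(-0.85, 0.85)),
        v_adhd=float(rng.uniform(0.2, 3.0)),
        r_mz=float(rng.uniform(-0.85, 0.85)),
        r_dz=float(rng.uniform(-0.85, 0.85)),
        g_tw=float(rng.uniform(-0.8, 0.8)),
        g_m=float(rng.uniform(-0.8, 0.8)),
        g_f=float(rng.uniform(-0.8, 0.8)),
        mu_pgs=float(rng.uniform(-1.0, 1.0)),
        mu_adhd=float(rng.uniform(-1.0, 1.0)),
    )


@pytest.fixture(scope="session")
def study_params():
    return pt.STUDY_PARAMS


@pytest.fixture(scope="session")
def complete_data():
    """Moderate complete dataset simulated from the study parameters."""
    return pt.simulate_families(
        pt.SimulationConfig(n_mz=400, n_dz=500, seed=2024))


@pytest.fixture(scope="session")
def missing_data():
    """Dataset with 25% MCAR cell-wise missingness."""
    return pt.simulate_families(
        pt.SimulationConfig(n_mz=400, n_dz=500, seed=2024, missingness=0.25))


@pytest.fixture(scope="session")
def fitted(complete_data):
    """One converged full-model fit, shared across tests."""
    res = pt.fit_transmission(complete_data)
    assert res.converged
    return res
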