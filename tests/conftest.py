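import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from circlin import simdata

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One small discovery-design simulation shared across tests."""
    params = simdata.SimParams(seed=7, m_circ=300, m_genes=60)
    assay, truth = simdata.simulate_counts(params)
    return params, assay, truth


@pytest.fixture(scope="session")
def network_inputs(default_sim):
    params, assay, truth = default_sim
    return simdata.simulate_network_inputs(truth, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_evidence(rng, n_circ=1000, n_samples=10, n_methods=9, density=0.25):
    """Random multi-method detection evidence for oracle comparisons."""
    rows = []
    for i in range(n_circ):
        cid = f"chr{(i % 5) + 1}:{1000 + i * 10}-{2000 + i * 10}:+"
        for j in range(n_samples):
            for k in range(n_methods):
                if rng.random() < density:
                    rows.append((cid, f"m{k + 1}", f"S{j + 1}", int(rng.integers(1, 30))))
    return pd.DataFrame(rows, columns=["circ_id", "method", "sample", "reads"])
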