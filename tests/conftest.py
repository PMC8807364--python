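import numpy as np
import pandas as pd
import pytest

from methylscreen import SimulationConfig


@pytest.fixture
def small_config():
    """A fast simulator configuration for unit tests."""
    return SimulationConfig(n_genes=40, n_background_probes=30, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_beta_inputs():
    """Two genes x four probes x two conditions with known delta-beta."""
    beta = pd.DataFrame(
        {
            "parental": [0.1, 0.2, 0.5, 0.5],
            "derivative_1": [0.5, 0.6, 0.5, 0.4],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id"),
    )
    probe_to_genes = {"p1": {"gA"}, "p2": {"gA"}, "p3": {"gB"}, "p4": {"gB"}}
    return beta, probe_to_genes
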