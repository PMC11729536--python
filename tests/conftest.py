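import numpy as np
import pytest

from stormsurv import synthdata as syn
from stormsurv.encounters import build_marray, histories_to_matrix


@pytest.fixture(scope="session")
def sim_dataset():
    """Medium trap-dependent dataset reused by several test modules."""
    config = syn.SimConfig(
        n_occasions=8, releases_per_occasion=60,
        phi=0.88, p_seen=0.85, p_unseen=0.45, seed=42,
    )
    histories, truth = syn.simulate_histories(config)
    return {
        "config": config,
        "histories": histories,
        "matrix": histories_to_matrix(histories),
        "marray": build_marray(histories),
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
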