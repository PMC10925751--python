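import numpy as np
import pytest

from headwave import compute_results, generate_matrix


@pytest.fixture(scope="session")
def factorial_table():
    """Default 81-scenario factorial results table (noise off, deterministic)."""
    scenarios = generate_matrix(master_seed=7)
    table = compute_results(scenarios)
    assert len(table) == 81
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
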