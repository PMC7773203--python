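import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _reference oracle module

from gcn4scope.synthetic_data import simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study shared across tests (seed 0)."""
    return simulate_all(seed=0)


@pytest.fixture(scope="session")
def null_sim():
    """Null study: planted enrichment 1, i.e. IP exchangeable with mock."""
    return simulate_all(seed=0, enrichment=1.0)
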