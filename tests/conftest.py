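import pytest
from hypothesis import settings

import nolscan as n

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark_records():
    return n.load_benchmark()


@pytest.fixture(scope="session")
def trained_model():
    """A small scorer trained on the synthetic corpus, shared across tests."""
    ts = n.generate_training_set(500, 500, seed=42)
    tp, tn, _, _ = ts.split()
    return n.train(tp, tn, seed=42)
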