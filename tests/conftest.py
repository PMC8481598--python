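import numpy as np
import pytest

from dbsloop.model import default_network, simulate


@pytest.fixture(scope="session")
def short_pd_run():
    """One 1.5 s Parkinsonian simulation shared across read-only tests."""
    cfg = default_network(pd=1.0, seed=0)
    return simulate(cfg, 1500.0, rec_every=40)  # 1 kHz sampling


@pytest.fixture(scope="session")
def short_healthy_run():
    cfg = default_network(pd=0.0, seed=0)
    return simulate(cfg, 1500.0, rec_every=40)
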