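from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120504)


@pytest.fixture(scope="session")
def aah_like():
    """The 27-gene synthetic contig with one planted foreign gene."""
    from amelio import synthetic_data
    return synthetic_data.aah_like_contig(seed=11)


@pytest.fixture(scope="session")
def protein_family():
    """A simulated 8-taxon protein family with its true tree and alignment."""
    from amelio import synthetic_data
    spec = synthetic_data.TreeSpec(n_taxa=8, mean_branch_length=0.08,
                                   rate=1.0, seq_length=600, seed=5)
    return synthetic_data.simulate_protein_family(spec)
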