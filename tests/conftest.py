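"""Shared fixtures: hand-built toy networks and session-scoped synthetic
benchmark draws (heavier ones are computed once and reused)."""

from __future__ import annotations

import pytest

from netspectrum.containers import TieredGeneSet, WeightedGeneNetwork
from netspectrum.model import GenePrioritizationModel
from netspectrum.synthetic import generate_network, medium_config, small_config


@pytest.fixture
def toy_network() -> WeightedGeneNetwork:
    """4-gene network with hand-known weights.

    Edges: APP-PSEN1 0.8, APP-GRIN2A 0.4, PSEN1-GRIN2A 0.3, APOE isolated.
    """
    net = WeightedGeneNetwork()
    net.add_edge("APP", "PSEN1", 0.8)
    net.add_edge("APP", "GRIN2A", 0.4)
    net.add_edge("PSEN1", "GRIN2A", 0.3)
    net.add_gene("APOE")
    return net


@pytest.fixture
def toy_training() -> TieredGeneSet:
    return TieredGeneSet({"APP": "C1", "PSEN1": "C2", "APOE": "C5"})


@pytest.fixture(scope="session")
def small_fixture():
    """200-gene strong-effect draw (module 40 = 30 positives + 10 hidden)."""
    config = small_config(seed=7)
    network, truth = generate_network(config)
    return config, network, truth


@pytest.fixture(scope="session")
def medium_fixture():
    """2,000-gene draw (module 150 = 100 positives + 50 hidden)."""
    config = medium_config(seed=7)
    network, truth = generate_network(config)
    return config, network, truth


@pytest.fixture(scope="session")
def medium_results(medium_fixture):
    """Fitted model on the medium fixture's training genes."""
    _, network, truth = medium_fixture
    model = GenePrioritizationModel(network, truth.tier_of)
    return model.fit(cv_folds=5, seed=7)
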