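import numpy as np
import pytest

import multibym as mb


@pytest.fixture(scope="session")
def path_graph3():
    """3-node path graph, scaled."""
    return mb.scale_icar(mb.adjacency_from_pairs([(1, 2), (2, 3)], 3))


@pytest.fixture(scope="session")
def edge_graph():
    """Single-edge graph on 2 nodes, scaled."""
    return mb.scale_icar(mb.adjacency_from_pairs([(1, 2)], 2))


@pytest.fixture(scope="session")
def grid_graph100():
    graph, _ = mb.make_geometry(100, "grid", seed=0)
    return graph


@pytest.fixture(scope="session")
def small_scenario():
    """A 36-district synthetic study at the default (study-level) parameters."""
    spec = mb.ScenarioSpec(m=36, seed=11)
    table, graph, geoms = mb.simulate_scenario(spec)
    return spec, table, graph, geoms


@pytest.fixture(scope="session")
def small_fit(small_scenario):
    """One fitted posterior on the 36-district scenario (shared across tests)."""
    spec, table, graph, _ = small_scenario
    return mb.fit_model(table, graph, spec.model_spec(),
                        chains=2, draws=300, warmup=300, seed=7)
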