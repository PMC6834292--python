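import numpy as np
import pytest

import sourceset as ss
from sourceset import synthetic_sim as sim
from sourceset.graph_engine import PathwayGraph


@pytest.fixture(scope="session")
def fixture_dg():
    return ss.fixture_graph()


@pytest.fixture(scope="session")
def fixture_pg(fixture_dg):
    return PathwayGraph(
        nodes=fixture_dg.nodes,
        edges=tuple(tuple(sorted(e)) for e in fixture_dg.edges),
    )


@pytest.fixture(scope="session")
def ref_spec(fixture_dg):
    return sim.random_ggm(fixture_dg, seed=7)


@pytest.fixture
def null_data(ref_spec):
    def make(n=25, seed=0):
        return sim.sample(ref_spec, ref_spec, n, n, seed=seed)

    return make


@pytest.fixture
def tiny_data():
    """One gene, two samples per condition: hand-computable covariances."""
    return ss.TwoSampleData(
        matrix=np.array([[0.0, 2.0, 0.0, -2.0]]),
        genes=("g",),
        condition=np.array([0, 0, 1, 1]),
    )
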