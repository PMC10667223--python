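import numpy as np
import pytest

from phenomapper import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort at n=1000 (shared across tests)."""
    return generate_cohort(SimulationConfig(n_patients=1000, seed=20260924 % 2**16))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def canonical_graph(nodes, edges):
    """Order-independent form of a Mapper graph for equality checks.

    Nodes are identified by (cover cell, member set) — unique, since the
    clusters of one cell partition it.  Edges become pairs of those keys.
    """
    keys = [(tuple(cell), tuple(sorted(members))) for cell, members in nodes]
    assert len(set(keys)) == len(keys)
    edge_keys = {tuple(sorted((keys[u], keys[v]))) for u, v in edges}
    return sorted(keys), edge_keys
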