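import numpy as np
import pytest

from chiralwalk import PhasedGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20240815)


def random_phased_graph(rng, n_sites=6, extra_edges=2, weight_range=(0.5, 1.5)):
    """Connected random graph: a random spanning tree plus chords, with
    random weights and phases.  Deterministic given the rng state."""
    g = PhasedGraph(range(n_sites))
    order = rng.permutation(n_sites)
    for k in range(1, n_sites):
        a = order[k]
        b = order[rng.integers(0, k)]
        g.add_edge(int(a), int(b), rng.uniform(*weight_range), rng.uniform(-np.pi, np.pi))
    added = 0
    attempts = 0
    while added < extra_edges and attempts < 50 * extra_edges:
        attempts += 1
        a, b = rng.integers(0, n_sites, size=2)
        if a != b and not g.has_edge(int(a), int(b)):
            g.add_edge(int(a), int(b), rng.uniform(*weight_range), rng.uniform(-np.pi, np.pi))
            added += 1
    return g
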