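import networkx as nx
import numpy as np
import pytest

from activemod.bum_model import BumFit, scoring_scheme
from activemod.module_detection import NodeWeightedGraph


def make_nwg(edges, weights, scheme=None):
    """Assemble a NodeWeightedGraph from explicit edges and weights."""
    G = nx.Graph()
    G.add_nodes_from(weights)
    G.add_edges_from(edges)
    return NodeWeightedGraph(graph=G, weights=dict(weights), scheme=scheme)


def random_nwg(seed, n_max=12, p=0.3, w_lo=-2.0, w_hi=2.0):
    """Seeded random instance: ER graph with U(w_lo, w_hi) node weights."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    G = nx.erdos_renyi_graph(n, p, seed=int(seed))
    G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G.nodes})
    weights = {v: float(rng.uniform(w_lo, w_hi)) for v in sorted(G.nodes)}
    return make_nwg(G.edges, weights)


@pytest.fixture
def path_nwg():
    """The worked path instance a(-1) - b(5) - c(-1) - d(3); optimum {b,c,d}."""
    return make_nwg(
        [("a", "b"), ("b", "c"), ("c", "d")],
        {"a": -1.0, "b": 5.0, "c": -1.0, "d": 3.0},
    )


@pytest.fixture
def example_scheme():
    """Scheme with alpha = 0.5 and tau forced to 0.01 for hand arithmetic."""
    fit = BumFit(lambda_=0.6, alpha=0.5, n=1000, log_likelihood=0.0)
    scheme = scoring_scheme(fit, 0.05)
    return scheme.__class__(fit=fit, fdr=scheme.fdr, tau=0.01)
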