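import networkx as nx
import pytest

from dupnet.homology import HomologyHit, build_homology_network


@pytest.fixture
def complete_family_network():
    """Complete 4-gene family a-b-c-d plus an isolated duplicate pair x-y."""
    genes = ["a", "b", "c", "d"]
    hits = []
    for i in range(4):
        for j in range(4):
            if i != j:
                hits.append(HomologyHit(genes[i], genes[j], 1e-60))
    hits.append(HomologyHit("x", "y", 1e-45))
    hits.append(HomologyHit("y", "x", 1e-45))
    return build_homology_network(hits)


@pytest.fixture
def chain_ppi():
    """PPI chain a-b-c-d-e."""
    g = nx.Graph()
    nx.add_path(g, ["a", "b", "c", "d", "e"])
    return g
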