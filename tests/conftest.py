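import networkx as nx
import pytest

from netarch import DMCParams, FFParams, PAParams, grow_dmc, grow_ff, grow_pa


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "u"), ("a", "v"), ("u", "v")])
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("a", "u"), ("u", "v")])
    return g


@pytest.fixture(params=["dmc", "ff", "pa"])
def grown(request):
    """A small grown (graph, history, model) triple for each simulator."""
    model = request.param
    if model == "dmc":
        g, h = grow_dmc(30, DMCParams(0.3, 0.7), 11)
    elif model == "ff":
        g, h = grow_ff(30, FFParams(0.3), 11)
    else:
        g, h = grow_pa(30, PAParams(3), 11)
    return g, h, model
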