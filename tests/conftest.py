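import networkx as nx
import numpy as np
import pytest

from dissipnet import contact_network, synthetic_structure

# Minimal two-residue PDB: two alanines with one CA each, 5 Å apart.
MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       5.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def small_structure():
    return synthetic_structure(30, seed=11)


@pytest.fixture(scope="session")
def small_contacts(small_structure):
    return contact_network(small_structure)


def random_time_dag(n_nodes: int, seed: int, p: float = 0.08) -> nx.DiGraph:
    """Random DAG shaped like an Initial network: a connected random
    graph whose edges are directed from earlier to later 'response
    times' drawn without ties."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    times = rng.permutation(n_nodes).astype(float)
    dag = nx.DiGraph()
    for v in g.nodes:
        dag.add_node(f"N{v}", response_time=float(times[v]), order=v)
    for u, v in g.edges:
        a, b = (u, v) if times[u] < times[v] else (v, u)
        dag.add_edge(f"N{a}", f"N{b}")
    return dag


@pytest.fixture
def dag_factory():
    return random_time_dag


def path_contacts(n: int) -> nx.Graph:
    """Contact-network-shaped path graph P1-P2-...-Pn."""
    g = nx.Graph()
    for i in range(n):
        g.add_node(f"P{i + 1}", order=i, seq_index=i)
    for i in range(n - 1):
        g.add_edge(f"P{i + 1}", f"P{i + 2}")
    return g
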