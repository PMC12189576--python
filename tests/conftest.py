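import numpy as np
import pandas as pd
import pytest

from pgxgraph import SimConfig, simulate
from pgxgraph.kg import KGEdge, KGNode, KnowledgeGraph

REL_COLUMNS = [
    "Entity1_id", "Entity1_name", "Entity1_type",
    "Entity2_id", "Entity2_name", "Entity2_type", "Association",
]


def make_relationships(rows, path):
    """Write a relationships TSV from (id1, type1, id2, type2, status) tuples."""
    records = [
        (a, f"name_{a}", ta, b, f"name_{b}", tb, status)
        for a, ta, b, tb, status in rows
    ]
    df = pd.DataFrame(records, columns=REL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def toy_graph():
    """variant-gene-chemical chain plus a disconnected disease."""
    g = KnowledgeGraph()
    g.add_node(KGNode("rs1", "rs1", "variant"))
    g.add_node(KGNode("g1", "GENE1", "gene"))
    g.add_node(KGNode("PA1", "metformin", "chemical", atc="A10BA02"))
    g.add_node(KGNode("d1", "diabetes", "disease"))
    g.add_edge(KGEdge("rs1", "g1"))
    g.add_edge(KGEdge("g1", "PA1"))
    g.add_edge(KGEdge("PA1", "d1"))
    return g


def random_graph(rng, n_nodes=15, p_edge=0.2):
    """Erdos-Renyi-ish typed graph for property tests."""
    g = KnowledgeGraph()
    types = ["variant", "gene", "chemical", "disease"]
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    for i, nid in enumerate(ids):
        g.add_node(KGNode(nid, nid, types[i % len(types)]))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(KGEdge(ids[i], ids[j]))
    return g


@pytest.fixture(scope="session")
def small_sim():
    """One shared default-condition simulation (graph, features, labels, beta)."""
    return simulate(SimConfig(n_patients=1200, seed=11))
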