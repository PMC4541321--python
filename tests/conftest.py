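import numpy as np
import pandas as pd
import pytest

from drwgm.diffstats import LabeledMatrix
from drwgm.graph_core import GlobalGraph, add_ground_node, build_global_graph
from drwgm.pathway_io import (
    GENE,
    METABOLITE,
    PathwayGraph,
    ReactionRecord,
    build_gene_gene_graph,
    build_pathway_graph,
)
from drwgm.synthetic import benchmark_spec, simulate


def make_records(pathway_id="path1", reversible=False):
    """A 3-reaction chain C0 -> G0 -> C1 -> G1 -> C2 -> G2 -> C3."""
    return [
        ReactionRecord(
            pathway_id=pathway_id,
            reaction_id=f"R{k}",
            gene_ids=(f"G{k}",),
            substrate_ids=(f"C{k}",),
            product_ids=(f"C{k + 1}",),
            reversible=reversible,
        )
        for k in range(3)
    ]


def random_global_graph(rng: np.random.Generator, n_nodes: int) -> GlobalGraph:
    """A random directed graph with gene/metabolite kinds and a ground node."""
    g = GlobalGraph()
    kinds = [GENE, METABOLITE]
    for i in range(n_nodes):
        g.graph.add_node(f"N{i:03d}", kind=kinds[int(rng.integers(2))])
    n_edges = max(n_nodes, int(rng.integers(n_nodes, 3 * n_nodes)))
    nodes = list(g.graph.nodes)
    for _ in range(n_edges):
        u, v = rng.choice(nodes, 2, replace=False)
        g.graph.add_edge(u, v)
    return add_ground_node(g)


def random_w0(rng: np.random.Generator, graph: GlobalGraph) -> pd.Series:
    from drwgm.graph_core import GROUND_ID

    w = pd.Series(rng.random(len(graph.node_order)), index=graph.node_order)
    w[GROUND_ID] = 0.0
    return w / w.sum()


def labeled(values: dict[str, list[float]], labels: list[str]) -> LabeledMatrix:
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return LabeledMatrix(values=df, labels=pd.Series(labels, index=df.columns))


@pytest.fixture(scope="session")
def chain_records():
    return make_records()


@pytest.fixture(scope="session")
def benchmark_sim():
    return simulate(benchmark_spec(seed=0))


def build_graphs(sim, gene_only=False):
    by: dict[str, list] = {}
    for r in sim.records:
        by.setdefault(r.pathway_id, []).append(r)
    builder = build_gene_gene_graph if gene_only else build_pathway_graph
    return build_global_graph([builder(rs) for rs in by.values()])


@pytest.fixture(scope="session")
def benchmark_graph(benchmark_sim):
    return build_graphs(benchmark_sim)
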