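"""Global graph assembly and the row-stochastic transition matrix.

Per-pathway graphs are merged into one global directed graph (shared
identifiers collapse to a single node), all edges are reversed so that walk
mass flows toward upstream nodes, and a ground node is attached with
bidirectional edges to every node.  The ground node guarantees that every
row of the transition matrix is stochastic and that the restart walk
converges.

Node order is fixed — (kind, id) lexicographic with the ground node last —
so weight vectors and matrices are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .pathway_io import GENE, GROUND, METABOLITE, PathwayGraph

GROUND_ID = "__GROUND__"

_KIND_ORDER = {GENE: 0, METABOLITE: 1, GROUND: 2}


class MergeError(ValueError):
    """Node-kind conflict or reserved-id collision while merging."""


@dataclass
class GlobalGraph:
    """Merged directed gene-metabolite graph with pathway membership index."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    pathway_index: dict[str, set[str]] = field(default_factory=dict)

    @property
    def node_order(self) -> list[str]:
        return sorted(
            self.graph.nodes,
            key=lambda n: (_KIND_ORDER[self.graph.nodes[n]["kind"]], n),
        )

    @property
    def has_ground(self) -> bool:
        return GROUND_ID in self.graph

    def node_kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n in self.node_order if self.graph.nodes[n]["kind"] == kind]


@dataclass
class TransitionMatrix:
    """Sparse row-stochastic matrix M with M[i,j] = 1/outdeg(i) per edge."""

    matrix: sp.csr_matrix
    node_order: list[str]
    row_stochastic: bool = True

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def index_of(self, node_id: str) -> int:
        # cached lazily; graphs are built once and queried many times
        if not hasattr(self, "_index"):
            self._index = {n: i for i, n in enumerate(self.node_order)}
        return self._index[node_id]


def merge_graphs(pathways: list[PathwayGraph]) -> GlobalGraph:
    """Union of node and edge sets; each identifier appears once."""
    gg = GlobalGraph()
    for pw in pathways:
        for n, kind in pw.graph.nodes(data="kind"):
            existing = gg.graph.nodes[n].get("kind") if n in gg.graph else None
            if existing is not None and existing != kind:
                raise MergeError(
                    f"node {n!r} is {existing} in one pathway, {kind} in another"
                )
            gg.graph.add_node(n, kind=kind)
        gg.graph.add_edges_from(pw.graph.edges())
        gg.pathway_index.setdefault(pw.pathway_id, set()).update(pw.member_genes)
    return gg


def reverse_edges(g: GlobalGraph) -> GlobalGraph:
    """Reverse every edge; bidirectional pairs map to themselves."""
    if g.has_ground:
        raise MergeError("reverse_edges must run before add_ground_node")
    out = GlobalGraph(pathway_index={k: set(v) for k, v in g.pathway_index.items()})
    for n, kind in g.graph.nodes(data="kind"):
        out.graph.add_node(n, kind=kind)
    out.graph.add_edges_from((v, u) for u, v in g.graph.edges())
    return out


def add_ground_node(g: GlobalGraph) -> GlobalGraph:
    """Attach the ground node bidirectionally to every node."""
    if GROUND_ID in g.graph:
        raise MergeError(f"reserved ground id {GROUND_ID!r} already present")
    out = GlobalGraph(pathway_index={k: set(v) for k, v in g.pathway_index.items()})
    out.graph = g.graph.copy()
    out.graph.add_node(GROUND_ID, kind=GROUND)
    for n in g.graph.nodes:
        out.graph.add_edge(GROUND_ID, n)
        out.graph.add_edge(n, GROUND_ID)
    return out


def build_global_graph(pathways: list[PathwayGraph]) -> GlobalGraph:
    """merge -> reverse -> ground, the full assembly pipeline."""
    return add_ground_node(reverse_edges(merge_graphs(pathways)))


def transition_matrix(g: GlobalGraph) -> TransitionMatrix:
    """Row-normalized adjacency matrix over the fixed node order."""
    if not g.has_ground:
        raise MergeError("transition_matrix requires the ground node")
    order = g.node_order
    index = {n: i for i, n in enumerate(order)}
    rows, cols = [], []
    for u, v in g.graph.edges():
        rows.append(index[u])
        cols.append(index[v])
    n = len(order)
    data = np.ones(len(rows))
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    outdeg = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(outdeg == 0):
        raise AssertionError("zero out-degree row despite ground node")
    m = sp.diags(1.0 / outdeg) @ adj
    return TransitionMatrix(matrix=m.tocsr(), node_order=order)


def write_global_graph(g: GlobalGraph, path) -> None:
    gml = g.graph.copy()
    gml.graph["pathway_memberships"] = json.dumps(
        {k: sorted(v) for k, v in g.pathway_index.items()}, sort_keys=True
    )
    nx.write_graphml(gml, str(path))


def read_global_graph(path) -> GlobalGraph:
    gml = nx.read_graphml(str(path))
    memberships = json.loads(gml.graph.pop("pathway_memberships", "{}"))
    g = GlobalGraph(pathway_index={k: set(v) for k, v in memberships.items()})
    for n, data in gml.nodes(data=True):
        g.graph.add_node(n, kind=data["kind"])
    g.graph.add_edges_from(gml.edges())
    return g
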