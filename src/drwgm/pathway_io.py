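"""Pathway definitions and per-pathway directed gene-metabolite graphs.

Metabolic pathways are described as reaction records: an enzyme (a set of
genes) converts substrate compounds into product compounds, optionally
reversibly.  Each pathway becomes a directed bipartite graph whose nodes are
genes and metabolites: a substrate points at every gene implementing the
enzyme, and every such gene points at each product.  Reversible reactions
contribute both directions.  Enzymes mapping to several genes yield one gene
node per gene, each with the full connectivity of the enzyme.

Graphs are exchanged as GraphML with a ``kind`` node attribute
(``gene``/``metabolite``) and a JSON-encoded graph attribute recording
pathway gene membership.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

GENE = "gene"
METABOLITE = "metabolite"
GROUND = "ground"

_REQUIRED_COLUMNS = (
    "pathway_id",
    "reaction_id",
    "gene_ids",
    "substrate_ids",
    "product_ids",
    "reversible",
)


class ReactionTableError(ValueError):
    """Malformed reaction table (missing column or bad row)."""


class GraphConstructionError(ValueError):
    """Inconsistent node kinds or otherwise unbuildable graph."""


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction row: genes implementing the enzyme plus its compounds."""

    pathway_id: str
    reaction_id: str
    gene_ids: tuple[str, ...]
    substrate_ids: tuple[str, ...]
    product_ids: tuple[str, ...]
    reversible: bool

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ReactionTableError("pathway_id must be non-empty")
        for name in ("gene_ids", "substrate_ids", "product_ids"):
            ids = getattr(self, name)
            if not ids:
                raise ReactionTableError(
                    f"reaction {self.reaction_id!r}: {name} must be non-empty"
                )
            if len(set(ids)) != len(ids):
                raise ReactionTableError(
                    f"reaction {self.reaction_id!r}: duplicate ids in {name}"
                )


@dataclass
class PathwayGraph:
    """Directed graph of one pathway plus its gene membership."""

    pathway_id: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def member_genes(self) -> set[str]:
        return {n for n, k in self.graph.nodes(data="kind") if k == GENE}

    def node_kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]


def _split_ids(cell: str, column: str, line_no: int) -> tuple[str, ...]:
    parts = tuple(p.strip() for p in cell.split(";") if p.strip())
    if not parts:
        raise ReactionTableError(
            f"line {line_no}: empty identifier cell in column {column!r}"
        )
    return parts


def read_reaction_table(path: str | Path) -> list[ReactionRecord]:
    """Read a reaction-table TSV into records, preserving file order.

    Columns: pathway_id, reaction_id, gene_ids, substrate_ids, product_ids,
    reversible (0/1); list cells use ``;`` separators.
    """
    records: list[ReactionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise ReactionTableError(f"missing required column {col!r}")
        for line_no, row in enumerate(reader, start=2):
            rev_cell = (row["reversible"] or "").strip()
            if rev_cell not in {"0", "1"}:
                raise ReactionTableError(
                    f"line {line_no}: reversible must be 0 or 1, got {rev_cell!r}"
                )
            pathway_id = (row["pathway_id"] or "").strip()
            if not pathway_id:
                raise ReactionTableError(f"line {line_no}: empty pathway_id")
            records.append(
                ReactionRecord(
                    pathway_id=pathway_id,
                    reaction_id=(row["reaction_id"] or "").strip(),
                    gene_ids=_split_ids(row["gene_ids"], "gene_ids", line_no),
                    substrate_ids=_split_ids(
                        row["substrate_ids"], "substrate_ids", line_no
                    ),
                    product_ids=_split_ids(
                        row["product_ids"], "product_ids", line_no
                    ),
                    reversible=rev_cell == "1",
                )
            )
    return records


def write_reaction_table(records: list[ReactionRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REQUIRED_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.pathway_id,
                    r.reaction_id,
                    ";".join(r.gene_ids),
                    ";".join(r.substrate_ids),
                    ";".join(r.product_ids),
                    "1" if r.reversible else "0",
                ]
            )


def _add_node(g: nx.DiGraph, node_id: str, kind: str) -> None:
    existing = g.nodes[node_id].get("kind") if node_id in g else None
    if existing is not None and existing != kind:
        raise GraphConstructionError(
            f"identifier {node_id!r} used both as {existing} and {kind}"
        )
    g.add_node(node_id, kind=kind)


def build_pathway_graph(
    records: list[ReactionRecord],
    exclude_compounds: set[str] | frozenset[str] = frozenset(),
) -> PathwayGraph:
    """Build one pathway's directed gene-metabolite graph.

    For each reaction and each gene g implementing it: substrate -> g and
    g -> product edges; reversible reactions add the opposite directions.
    ``exclude_compounds`` drops the listed compound ids (e.g. currency
    metabolites) before construction; empty by default.
    """
    if not records:
        raise GraphConstructionError("no records given")
    pathway_ids = {r.pathway_id for r in records}
    if len(pathway_ids) != 1:
        raise GraphConstructionError(
            f"records span multiple pathways: {sorted(pathway_ids)}"
        )
    pw = PathwayGraph(pathway_id=records[0].pathway_id)
    g = pw.graph
    for rec in records:
        for gene in rec.gene_ids:
            _add_node(g, gene, GENE)
        for compound in set(rec.substrate_ids) | set(rec.product_ids):
            if compound in exclude_compounds:
                continue
            _add_node(g, compound, METABOLITE)
        for gene in rec.gene_ids:
            for sub in rec.substrate_ids:
                if sub in exclude_compounds:
                    continue
                g.add_edge(sub, gene)
                if rec.reversible:
                    g.add_edge(gene, sub)
            for prod in rec.product_ids:
                if prod in exclude_compounds:
                    continue
                g.add_edge(gene, prod)
                if rec.reversible:
                    g.add_edge(prod, gene)
    return pw


def build_gene_gene_graph(records: list[ReactionRecord]) -> PathwayGraph:
    """Gene-only graph with metabolites contracted out.

    Edge g1 -> g2 iff some product of a reaction catalyzed by g1 is a
    substrate of a reaction catalyzed by g2 (reversibility expands each
    reaction's substrate/product roles in both directions first).  Used only
    by the gene-expression-only walk baseline.
    """
    if not records:
        raise GraphConstructionError("no records given")
    pathway_ids = {r.pathway_id for r in records}
    if len(pathway_ids) != 1:
        raise GraphConstructionError(
            f"records span multiple pathways: {sorted(pathway_ids)}"
        )
    pw = PathwayGraph(pathway_id=records[0].pathway_id)
    g = pw.graph
    # (gene, compound) roles after expanding reversible reactions
    produces: list[tuple[str, str]] = []
    consumes: list[tuple[str, str]] = []
    for rec in records:
        for gene in rec.gene_ids:
            _add_node(g, gene, GENE)
            subs = list(rec.substrate_ids)
            prods = list(rec.product_ids)
            if rec.reversible:
                subs, prods = subs + prods, prods + subs
            for c in subs:
                consumes.append((gene, c))
            for c in prods:
                produces.append((gene, c))
    consumers: dict[str, set[str]] = {}
    for gene, c in consumes:
        consumers.setdefault(c, set()).add(gene)
    for g1, c in produces:
        for g2 in consumers.get(c, ()):  # includes g1 -> g1 loops; skip
            if g1 != g2:
                g.add_edge(g1, g2)
    return pw


def write_graph(pw: PathwayGraph | "object", path: str | Path) -> None:
    """Serialize a pathway graph (or a merged global graph) as GraphML."""
    g = pw.graph.copy()
    if isinstance(pw, PathwayGraph):
        memberships = {pw.pathway_id: sorted(pw.member_genes)}
    else:  # GlobalGraph duck-typed: has .pathway_index
        memberships = {k: sorted(v) for k, v in pw.pathway_index.items()}
    g.graph["pathway_memberships"] = json.dumps(memberships, sort_keys=True)
    nx.write_graphml(g, str(path))


def read_graph(path: str | Path) -> PathwayGraph:
    """Read a GraphML pathway graph written by :func:`write_graph`.

    Multi-pathway (global) files are read back via
    :func:`drwgm.graph_core.read_global_graph` instead.
    """
    g = nx.read_graphml(str(path))
    memberships = json.loads(g.graph.pop("pathway_memberships", "{}"))
    if len(memberships) != 1:
        raise GraphConstructionError(
            f"expected one pathway in {path}, found {len(memberships)}"
        )
    pw = PathwayGraph(pathway_id=next(iter(memberships)))
    pw.graph = nx.DiGraph()
    for n, data in g.nodes(data=True):
        pw.graph.add_node(n, kind=data["kind"])
    pw.graph.add_edges_from(g.edges())
    return pw
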