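"""Pharmacogenomic knowledge graph: parsing, filtering, adjacency, randomization.

The graph is an undirected, typed multipartite graph over variants, haplotypes,
genes, chemicals (medications) and diseases, built from a curated relationships
table in the PharmGKB TSV dialect.  Only edges whose association status is
"associated" are retained; ad-hoc feature-to-gene edges can be appended for
genotype features that are absent from the curated table but whose gene is not.

The graph-convolution propagation operator is the symmetric normalization
``S = D_hat^{-1/2} (A + I) D_hat^{-1/2}`` where ``A`` is the binary adjacency in
the graph's recorded node order and ``D_hat`` is the diagonal degree matrix of
``A + I``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

ENTITY_TYPES = frozenset({"variant", "haplotype", "gene", "chemical", "disease"})
ASSOCIATION_STATUSES = frozenset({"associated", "ambiguous", "not associated"})

RELATIONSHIP_COLUMNS = (
    "Entity1_id",
    "Entity1_name",
    "Entity1_type",
    "Entity2_id",
    "Entity2_name",
    "Entity2_type",
    "Association",
)


class GraphFormatError(ValueError):
    """Raised for malformed relationship tables or graph files."""


@dataclass(frozen=True)
class KGNode:
    """A typed graph node keyed by its accession id."""

    id: str
    name: str
    type: str
    atc: str | None = None  # optional ATC annotation, chemical nodes only

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.type!r} for node {self.id!r}")


@dataclass(frozen=True)
class KGEdge:
    """An undirected association edge, stored once in canonical id order."""

    source: str
    target: str
    association: str = "associated"
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r} not permitted")

    @property
    def key(self) -> tuple[str, str]:
        a, b = self.source, self.target
        return (a, b) if a <= b else (b, a)


class KnowledgeGraph:
    """Undirected typed graph with a stable, recorded node ordering.

    Nodes are ordered by ``(type, id)`` so adjacency matrices and downstream
    embeddings are reproducible across runs. Each undirected edge is stored
    once under its canonical ``(min_id, max_id)`` key; duplicate insertions
    collapse, with "curated" provenance winning over ad-hoc provenance.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, KGNode] = {}
        self._edges: dict[tuple[str, str], KGEdge] = {}
        self._order: list[str] | None = None

    # -- construction ------------------------------------------------------

    def add_node(self, node: KGNode) -> None:
        existing = self._nodes.get(node.id)
        if existing is not None:
            if existing.type != node.type:
                raise ValueError(
                    f"node {node.id!r} redeclared with type {node.type!r}"
                    f" (was {existing.type!r})"
                )
            # keep the richer record (name/ATC may arrive on a later row)
            if existing.atc is None and node.atc is not None:
                self._nodes[node.id] = node
            return
        self._nodes[node.id] = node
        self._order = None

    def add_edge(self, edge: KGEdge) -> None:
        for end in (edge.source, edge.target):
            if end not in self._nodes:
                raise ValueError(f"edge endpoint {end!r} is not a node")
        prev = self._edges.get(edge.key)
        if prev is None or (prev.provenance != "curated" and edge.provenance == "curated"):
            self._edges[edge.key] = edge

    # -- views -------------------------------------------------------------

    @property
    def nodes(self) -> list[KGNode]:
        return [self._nodes[i] for i in self.node_order]

    @property
    def node_order(self) -> list[str]:
        if self._order is None:
            self._order = sorted(self._nodes, key=lambda i: (self._nodes[i].type, i))
        return self._order

    @property
    def node_index(self) -> dict[str, int]:
        return {nid: k for k, nid in enumerate(self.node_order)}

    @property
    def edges(self) -> list[KGEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def node(self, node_id: str) -> KGNode:
        return self._nodes[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a <= b else (b, a)) in self._edges

    def nodes_of_type(self, entity_type: str) -> list[KGNode]:
        return [n for n in self.nodes if n.type == entity_type]

    def neighbors(self, node_id: str) -> list[str]:
        out = []
        for a, b in self._edges:
            if a == node_id:
                out.append(b)
            elif b == node_id:
                out.append(a)
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def degree_sequence(self) -> dict[str, int]:
        deg = {nid: 0 for nid in self._nodes}
        for a, b in self._edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph()
        g._nodes = dict(self._nodes)
        g._edges = dict(self._edges)
        return g

    # -- I/O ---------------------------------------------------------------

    def to_files(self, node_path, edge_path) -> None:
        nodes = pd.DataFrame(
            [(n.id, n.name, n.type, n.atc or "") for n in self.nodes],
            columns=["id", "name", "type", "atc"],
        )
        nodes.to_csv(node_path, sep="\t", index=False)
        edges = pd.DataFrame(
            [(e.source, e.target, e.association, e.provenance) for e in self.edges],
            columns=["source_id", "target_id", "association", "provenance"],
        )
        edges.to_csv(edge_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, node_path, edge_path) -> "KnowledgeGraph":
        g = cls()
        nodes = pd.read_csv(node_path, sep="\t", dtype=str, keep_default_na=False)
        for row in nodes.itertuples(index=False):
            g.add_node(KGNode(row.id, row.name, row.type, row.atc or None))
        edges = pd.read_csv(edge_path, sep="\t", dtype=str, keep_default_na=False)
        for row in edges.itertuples(index=False):
            g.add_edge(KGEdge(row.source_id, row.target_id, row.association, row.provenance))
        return g


# ---------------------------------------------------------------------------
# relationship-table parsing and filtering


def load_relationships(path) -> pd.DataFrame:
    """Parse a PharmGKB-style relationships TSV into a candidate-edge table.

    Required columns: Entity1_id/name/type, Entity2_id/name/type, Association
    (header matching is case-insensitive). Entity types must belong to the
    closed vocabulary; a row with an unknown type raises a
    :class:`GraphFormatError` naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for col in RELATIONSHIP_COLUMNS:
        if col.lower() not in lower:
            raise GraphFormatError(f"relationships table is missing column {col!r}")
        rename[lower[col.lower()]] = col
    df = df.rename(columns=rename)[list(RELATIONSHIP_COLUMNS)]

    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        for ent in (1, 2):
            etype = getattr(row, f"Entity{ent}_type").strip().lower()
            if etype not in ENTITY_TYPES:
                raise GraphFormatError(
                    f"line {line}: unknown entity type {etype!r}"
                )
            if not getattr(row, f"Entity{ent}_id").strip():
                raise GraphFormatError(f"line {line}: empty Entity{ent}_id")
    return df


def filter_associations(table: pd.DataFrame) -> KnowledgeGraph:
    """Keep only rows whose association status is "associated" and build the graph.

    Status matching is case-insensitive and whitespace-trimmed; "ambiguous",
    "not associated" and any unrecognized status are discarded (the latter
    with a warning). The returned graph contains exactly the nodes incident
    to at least one kept edge.
    """
    g = KnowledgeGraph()
    statuses = table["Association"].str.strip().str.lower()
    unknown = sorted(set(statuses) - ASSOCIATION_STATUSES)
    if unknown:
        warnings.warn(
            f"unrecognized association statuses treated as non-associated: {unknown}",
            stacklevel=2,
        )
    kept = table.loc[statuses == "associated"]
    if kept.empty:
        warnings.warn("no 'associated' rows; returning an empty graph", stacklevel=2)
        return g
    for row in kept.itertuples(index=False):
        if row.Entity1_id.strip() == row.Entity2_id.strip():
            continue  # curated self-relations carry no adjacency information
        g.add_node(
            KGNode(row.Entity1_id.strip(), row.Entity1_name.strip(),
                   row.Entity1_type.strip().lower())
        )
        g.add_node(
            KGNode(row.Entity2_id.strip(), row.Entity2_name.strip(),
                   row.Entity2_type.strip().lower())
        )
        g.add_edge(KGEdge(row.Entity1_id.strip(), row.Entity2_id.strip(),
                          "associated", "curated"))
    return g


def add_adhoc_edges(
    graph: KnowledgeGraph,
    variant_to_gene: dict[str, str] | None = None,
    haplotype_to_gene: dict[str, str] | None = None,
) -> tuple[KnowledgeGraph, list[str]]:
    """Attach genotype features to the graph via their genes.

    For each mapped variant/haplotype whose gene node exists in the graph, a
    feature node is created if absent and an undirected feature-gene edge with
    ad-hoc provenance is added (unless a curated edge already connects them).
    Features whose gene is not in the graph are returned in the skipped list.
    """
    g = graph.copy()
    skipped: list[str] = []
    for mapping, ftype, prov in (
        (variant_to_gene or {}, "variant", "adhoc-variant-gene"),
        (haplotype_to_gene or {}, "haplotype", "adhoc-haplotype-gene"),
    ):
        for feat_id, gene_id in sorted(mapping.items()):
            if not g.has_node(gene_id) or g.node(gene_id).type != "gene":
                skipped.append(feat_id)
                continue
            if not g.has_node(feat_id):
                g.add_node(KGNode(feat_id, feat_id, ftype))
            if not g.has_edge(feat_id, gene_id):
                g.add_edge(KGEdge(feat_id, gene_id, "associated", prov))
    return g, skipped


# ---------------------------------------------------------------------------
# adjacency and normalization


def build_adjacency(graph: KnowledgeGraph) -> sp.csr_matrix:
    """Binary N x N adjacency in the graph's recorded node order (zero diagonal)."""
    if graph.n_nodes == 0:
        raise ValueError("cannot build adjacency of an empty graph")
    index = graph.node_index
    n = graph.n_nodes
    rows, cols = [], []
    for e in graph.edges:
        i, j = index[e.source], index[e.target]
        rows += [i, j]
        cols += [j, i]
    data = np.ones(len(rows), dtype=np.float64)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


@dataclass
class NormalizedAdjacency:
    """The symmetric GCN propagation operator S = D_hat^{-1/2}(A+I)D_hat^{-1/2}."""

    S: sp.csr_matrix
    node_order: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def toarray(self) -> np.ndarray:
        return self.S.toarray()


def normalize_adjacency(A, node_order: list[str] | None = None) -> NormalizedAdjacency:
    """Symmetrically normalize a binary adjacency with self-loops added.

    Accepts a dense array or scipy sparse matrix; validates squareness and
    symmetry. The result agrees elementwise with the dense closed form.
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    n, m = A.shape
    if n != m:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if (A != A.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    A_hat = A + sp.identity(n, format="csr")
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    S = sp.csr_matrix(d_inv_sqrt @ A_hat @ d_inv_sqrt)
    return NormalizedAdjacency(S=S, node_order=list(node_order or []))


def graph_operator(graph: KnowledgeGraph) -> NormalizedAdjacency:
    """Convenience: adjacency + normalization in one step."""
    return normalize_adjacency(build_adjacency(graph), node_order=graph.node_order)


# ---------------------------------------------------------------------------
# randomized control graphs


def randomize_graph(
    graph: KnowledgeGraph,
    mode: str = "degree-preserving",
    n_swaps: int | None = None,
    seed: int | None = None,
) -> KnowledgeGraph:
    """Rewire the graph for the randomized-graph ablation control.

    ``degree-preserving`` applies double-edge swaps, keeping every node's
    degree exactly; ``uniform-rewire`` redraws the same number of edges
    uniformly over node pairs. Node set and edge count are preserved in
    both modes; the result is reproducible under a fixed seed.
    """
    if graph.n_edges < 2:
        raise ValueError("need at least 2 edges to randomize")
    rng = np.random.default_rng(seed)
    order = graph.node_order
    if n_swaps is None:
        n_swaps = 10 * graph.n_edges

    out = KnowledgeGraph()
    for node in graph.nodes:
        out.add_node(node)

    if mode == "degree-preserving":
        G = nx.Graph()
        G.add_nodes_from(range(len(order)))
        index = graph.node_index
        G.add_edges_from((index[e.source], index[e.target]) for e in graph.edges)
        nx_seed = int(rng.integers(0, 2**31 - 1))
        try:
            nx.double_edge_swap(G, nswap=n_swaps, max_tries=100 * n_swaps, seed=nx_seed)
        except nx.NetworkXAlgorithmError:
            pass  # swap budget exhausted; partial randomization is still valid
        for i, j in G.edges():
            out.add_edge(KGEdge(order[i], order[j], "associated", "curated"))
    elif mode == "uniform-rewire":
        n, target = len(order), graph.n_edges
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < target:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            chosen.add((min(i, j), max(i, j)))
        for i, j in chosen:
            out.add_edge(KGEdge(order[int(i)], order[int(j)], "associated", "curated"))
    else:
        raise ValueError(f"unknown randomization mode {mode!r}")
    return out
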