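"""Typed heterogeneous molecular network: data model, TSV I/O, subnetworks.

The network mixes five node types (protein, lncRNA, miRNA, disease, drug)
connected by nine undirected association types.  Edges are de-duplicated on
load and stored with a canonical endpoint order, so the container behaves as
a set of typed, undirected edges.  Sub-network extraction and edge removal
support the leakage-controlled evaluation protocol: removing a fold's PPI
edges keeps every node in place so each protein can still be embedded.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

NODE_TYPES: tuple[str, ...] = ("protein", "lncRNA", "miRNA", "disease", "drug")

#: The nine association types and the node types their endpoints must carry.
RELATION_ENDPOINTS: dict[str, frozenset[str]] = {
    "miRNA-lncRNA": frozenset({"miRNA", "lncRNA"}),
    "miRNA-disease": frozenset({"miRNA", "disease"}),
    "miRNA-protein": frozenset({"miRNA", "protein"}),
    "lncRNA-disease": frozenset({"lncRNA", "disease"}),
    "protein-protein": frozenset({"protein"}),
    "protein-disease": frozenset({"protein", "disease"}),
    "drug-protein": frozenset({"drug", "protein"}),
    "drug-disease": frozenset({"drug", "disease"}),
    "lncRNA-protein": frozenset({"lncRNA", "protein"}),
}
RELATIONS: tuple[str, ...] = tuple(RELATION_ENDPOINTS)

_NODE_TYPE_LOOKUP = {t.lower(): t for t in NODE_TYPES}
_RELATION_LOOKUP = {r.lower(): r for r in RELATIONS}


class EdgeTableError(ValueError):
    """Malformed edge-table content; message names the offending line."""


class SelfLoopError(ValueError):
    """Edge whose two endpoints are the same node."""


def normalize_node_type(value: str) -> str:
    try:
        return _NODE_TYPE_LOOKUP[value.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown node type {value!r}; expected one of {NODE_TYPES}"
        ) from None


def normalize_relation(value: str, aliases: Mapping[str, str] | None = None) -> str:
    key = value.strip().lower()
    if aliases:
        alias_map = {k.lower(): v for k, v in aliases.items()}
        key = alias_map.get(key, key).lower()
    try:
        return _RELATION_LOOKUP[key]
    except KeyError:
        raise ValueError(
            f"unknown relation {value!r}; expected one of {RELATIONS}"
        ) from None


@dataclass(frozen=True, order=True)
class NodeRef:
    """A node identified by (id, ntype); the same string id under two types
    is two distinct nodes."""

    id: str
    ntype: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.ntype not in NODE_TYPES:
            raise ValueError(
                f"unknown node type {self.ntype!r}; expected one of {NODE_TYPES}"
            )


@dataclass(frozen=True)
class TypedEdge:
    """Undirected relation-typed edge; endpoints are stored in canonical
    (lexicographic) order so (u, v, rel) and (v, u, rel) compare equal."""

    u: NodeRef
    v: NodeRef
    relation: str

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise SelfLoopError(f"self-loop on {self.u.id!r} is not allowed")
        if self.relation not in RELATION_ENDPOINTS:
            raise ValueError(
                f"unknown relation {self.relation!r}; expected one of {RELATIONS}"
            )
        expected = RELATION_ENDPOINTS[self.relation]
        actual = {self.u.ntype, self.v.ntype}
        if actual != set(expected):
            raise ValueError(
                f"relation {self.relation!r} incompatible with endpoint types "
                f"{sorted(actual)}"
            )
        if self.v < self.u:  # canonical order: smaller (id, ntype) first
            u, v = self.u, self.v
            object.__setattr__(self, "u", v)
            object.__setattr__(self, "v", u)

    @property
    def nodes(self) -> tuple[NodeRef, NodeRef]:
        return (self.u, self.v)


class HeteroNetwork:
    """Set-of-nodes / set-of-edges container with an adjacency index.

    Nodes may be isolated (retained deliberately by :func:`remove_edges`).
    Adding an edge adds its endpoints; duplicate edges are ignored, which
    gives the de-redundancy guarantee of the loaders.
    """

    def __init__(
        self,
        nodes: Iterable[NodeRef] = (),
        edges: Iterable[TypedEdge] = (),
    ) -> None:
        self.nodes: set[NodeRef] = set()
        self.edges: set[TypedEdge] = set()
        self._adj: dict[NodeRef, set[NodeRef]] = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    def add_node(self, node: NodeRef) -> None:
        if node not in self.nodes:
            self.nodes.add(node)
            self._adj[node] = set()

    def add_edge(self, edge: TypedEdge) -> None:
        if edge in self.edges:
            return
        self.add_node(edge.u)
        self.add_node(edge.v)
        self.edges.add(edge)
        self._adj[edge.u].add(edge.v)
        self._adj[edge.v].add(edge.u)

    @property
    def adjacency(self) -> Mapping[NodeRef, set[NodeRef]]:
        return self._adj

    def neighbors(self, node: NodeRef) -> set[NodeRef]:
        return self._adj[node]

    def degree(self, node: NodeRef) -> int:
        return len(self._adj[node])

    def nodes_of_type(self, ntype: str) -> list[NodeRef]:
        return sorted(n for n in self.nodes if n.ntype == ntype)

    def proteins(self) -> list[NodeRef]:
        return self.nodes_of_type("protein")

    def edges_of_relation(self, relation: str) -> set[TypedEdge]:
        return {e for e in self.edges if e.relation == relation}

    def ppi_edges(self) -> set[TypedEdge]:
        return self.edges_of_relation("protein-protein")

    def copy(self) -> "HeteroNetwork":
        return HeteroNetwork(self.nodes, self.edges)

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeteroNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"HeteroNetwork(|V|={len(self.nodes)}, |E|={len(self.edges)})"


@dataclass(frozen=True)
class NetworkStats:
    """Node counts per type and edge counts per relation."""

    node_counts: Mapping[str, int]
    edge_counts: Mapping[str, int]

    @property
    def n_nodes(self) -> int:
        return sum(self.node_counts.values())

    @property
    def n_edges(self) -> int:
        return sum(self.edge_counts.values())

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            {"node_type": list(self.node_counts), "count": list(self.node_counts.values())}
        )
        edges = pd.DataFrame(
            {"relation": list(self.edge_counts), "count": list(self.edge_counts.values())}
        )
        return nodes, edges


def stats(net: HeteroNetwork) -> NetworkStats:
    """Count nodes per type and edges per relation (all categories reported,
    zeros included, so row sums always equal |V| and |E|)."""
    node_counter = Counter(n.ntype for n in net.nodes)
    edge_counter = Counter(e.relation for e in net.edges)
    return NetworkStats(
        node_counts={t: node_counter.get(t, 0) for t in NODE_TYPES},
        edge_counts={r: edge_counter.get(r, 0) for r in RELATIONS},
    )


@dataclass(frozen=True)
class EdgeTableDialect:
    """Column mapping for delimited edge tables.

    Defaults match the package's own five-column TSV; remap the column names
    (and optionally relation spellings) to ingest third-party layouts.
    """

    u_id: str = "u_id"
    u_type: str = "u_type"
    v_id: str = "v_id"
    v_type: str = "v_type"
    relation: str = "relation"
    delimiter: str = "\t"
    relation_aliases: Mapping[str, str] = field(default_factory=dict)


DEFAULT_DIALECT = EdgeTableDialect()


def read_edge_table(
    path: str | Path, dialect: EdgeTableDialect = DEFAULT_DIALECT
) -> HeteroNetwork:
    """Load a delimited edge table into a de-duplicated undirected network.

    Self-loops are skipped with a warning; any other malformed row raises
    :class:`EdgeTableError` naming the line number.
    """
    net = HeteroNetwork()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise EdgeTableError(f"{path}: empty file, expected a header row")
        colnames = [dialect.u_id, dialect.u_type, dialect.v_id, dialect.v_type, dialect.relation]
        try:
            cols = [header.index(c) for c in colnames]
        except ValueError as exc:
            raise EdgeTableError(f"{path}: header {header!r} missing column: {exc}")
        n_loops = 0
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise EdgeTableError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            try:
                u = NodeRef(row[cols[0]].strip(), normalize_node_type(row[cols[1]]))
                v = NodeRef(row[cols[2]].strip(), normalize_node_type(row[cols[3]]))
                rel = normalize_relation(row[cols[4]], dialect.relation_aliases)
                edge = TypedEdge(u, v, rel)
            except SelfLoopError:
                n_loops += 1
                logger.warning("%s:%d: skipping self-loop on %r", path, lineno, row[cols[0]])
                continue
            except ValueError as exc:
                raise EdgeTableError(f"{path}:{lineno}: {exc}") from exc
            net.add_edge(edge)
    st = stats(net)
    logger.info(
        "read %s: %d nodes %s, %d edges %s (%d self-loops skipped)",
        path, st.n_nodes, dict(st.node_counts), st.n_edges, dict(st.edge_counts), n_loops,
    )
    return net


def write_edge_table(
    net: HeteroNetwork, path: str | Path, dialect: EdgeTableDialect = DEFAULT_DIALECT
) -> Path:
    """Write the five-column TSV; sorted rows so output is deterministic.

    Round-trips through :func:`read_edge_table`, up to isolated nodes (the
    table format records edges only).
    """
    path = Path(path)
    rows = sorted(
        (e.u.id, e.u.ntype, e.v.id, e.v.ntype, e.relation) for e in net.edges
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow([dialect.u_id, dialect.u_type, dialect.v_id, dialect.v_type, dialect.relation])
        writer.writerows(rows)
    return path


@dataclass(frozen=True)
class SubnetworkSpec:
    """Allowed node types and relations of a named sub-network."""

    name: str
    node_types: frozenset[str]
    relations: frozenset[str]


#: PP is the protein-protein core; each other named sub-network adds exactly
#: one non-protein node type and its protein-touching relation; ALL keeps
#: everything.
SUBNETWORK_SPECS: dict[str, SubnetworkSpec] = {
    "PP": SubnetworkSpec("PP", frozenset({"protein"}), frozenset({"protein-protein"})),
    "MiPP": SubnetworkSpec(
        "MiPP",
        frozenset({"protein", "miRNA"}),
        frozenset({"protein-protein", "miRNA-protein"}),
    ),
    "LncPP": SubnetworkSpec(
        "LncPP",
        frozenset({"protein", "lncRNA"}),
        frozenset({"protein-protein", "lncRNA-protein"}),
    ),
    "DiPP": SubnetworkSpec(
        "DiPP",
        frozenset({"protein", "disease"}),
        frozenset({"protein-protein", "protein-disease"}),
    ),
    "DrPP": SubnetworkSpec(
        "DrPP",
        frozenset({"protein", "drug"}),
        frozenset({"protein-protein", "drug-protein"}),
    ),
    "ALL": SubnetworkSpec("ALL", frozenset(NODE_TYPES), frozenset(RELATIONS)),
}


def extract_subnetwork(
    net: HeteroNetwork, spec: SubnetworkSpec | str
) -> HeteroNetwork:
    """Restrict to the spec's relations; keeps the nodes of allowed types
    that touch at least one allowed edge."""
    if isinstance(spec, str):
        try:
            spec = SUBNETWORK_SPECS[spec]
        except KeyError:
            raise ValueError(
                f"unknown subnetwork {spec!r}; expected one of {sorted(SUBNETWORK_SPECS)}"
            ) from None
    edges = {e for e in net.edges if e.relation in spec.relations}
    nodes = {n for e in edges for n in e.nodes}
    return HeteroNetwork(nodes, edges)


def remove_edges(net: HeteroNetwork, drop: Iterable[TypedEdge]) -> HeteroNetwork:
    """Copy of ``net`` without the ``drop`` edges; the node set is unchanged,
    so nodes isolated by the removal still receive embeddings."""
    drop = set(drop)
    missing = drop - net.edges
    if missing:
        raise ValueError(f"{len(missing)} edge(s) to drop are not in the network")
    return HeteroNetwork(net.nodes, net.edges - drop)
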