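"""Core data types and I/O for categorically attributed networks.

An attributed network is an undirected simple graph whose nodes carry a
fixed-length vector of categorical values (one value per attribute).  The
types here are thin, validated wrappers around a :class:`networkx.Graph`
and a :class:`pandas.DataFrame`, plus the plain-text readers/writers the
rest of the package consumes:

* edge list        — two whitespace-separated node ids per line
* attribute table  — delimited text, header row naming the attributes,
                     first column the node id
* partition        — two-column TSV ``node<TAB>community`` with header
* weighted edges   — three-column TSV ``u<TAB>v<TAB>weight`` with header

Node ids are opaque strings externally; a stable dense index 0..|V|-1
(insertion order of the attribute table) backs all matrix computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("cnsnet")

__all__ = [
    "AttributedGraph",
    "WeightedGraph",
    "Partition",
    "GraphValidationError",
    "load_attributed_network",
    "load_partition",
    "write_partition",
    "write_weighted_edges",
    "load_weighted_edges",
    "write_graphml",
    "simplify_to_undirected",
]


class GraphValidationError(ValueError):
    """Raised when an input violates the attributed-graph contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class AttributedGraph:
    """Undirected simple graph with one categorical vector per node.

    Parameters
    ----------
    graph:
        Undirected simple graph.  Self-loops and multi-edges are rejected.
    attributes:
        DataFrame indexed by node id, one column per attribute, all cells
        non-empty categorical values (stored as strings).

    Notes
    -----
    Attribute value domains are derived from the data, so every domain
    value is carried by at least one node by construction.
    """

    def __init__(self, graph: nx.Graph, attributes: pd.DataFrame):
        if graph.is_directed() or graph.is_multigraph():
            raise GraphValidationError("graph must be undirected and simple")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise GraphValidationError(f"self-loops not allowed: {loops[:3]}")
        attributes = attributes.astype(str)
        if attributes.index.has_duplicates:
            dups = attributes.index[attributes.index.duplicated()].tolist()
            raise GraphValidationError(f"duplicate node ids in attribute table: {dups[:3]}")
        if attributes.isin(["", "nan", "None"]).any().any():
            raise GraphValidationError("attribute table contains empty cells")
        missing = [n for n in graph.nodes if n not in attributes.index]
        if missing:
            raise GraphValidationError(
                f"nodes missing from attribute table: {sorted(missing)[:5]}"
            )
        # nodes appearing only in the attribute table become isolated nodes
        g = nx.Graph()
        g.add_nodes_from(attributes.index)
        g.add_edges_from(graph.edges)
        self._graph = g
        self._attributes = attributes
        self.nodes: list[str] = list(attributes.index)
        self.node_index: dict[str, int] = {u: i for i, u in enumerate(self.nodes)}
        self._groups_cache: dict[str, dict[str, frozenset[str]]] = {}

    # -- basic accessors ----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def attributes(self) -> pd.DataFrame:
        return self._attributes

    @property
    def attribute_names(self) -> list[str]:
        return list(self._attributes.columns)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    @property
    def n_attributes(self) -> int:
        return self._attributes.shape[1]

    def value(self, node: str, attribute: str) -> str:
        """F_m(i): the value of `node` on `attribute`."""
        return self._attributes.at[node, attribute]

    def domain(self, attribute: str) -> list[str]:
        """Distinct values of an attribute, in sorted order."""
        return sorted(self.value_groups(attribute))

    def value_groups(self, attribute: str) -> dict[str, frozenset[str]]:
        """g_m: value -> set of nodes carrying that value (partitions V)."""
        if attribute not in self._groups_cache:
            if attribute not in self._attributes.columns:
                raise KeyError(f"unknown attribute {attribute!r}")
            grouped = self._attributes.groupby(attribute).groups
            self._groups_cache[attribute] = {
                v: frozenset(idx) for v, idx in grouped.items()
            }
        return self._groups_cache[attribute]

    def neighbors(self, node: str) -> set[str]:
        return set(self._graph.neighbors(node))

    def has_edge(self, u: str, v: str) -> bool:
        return self._graph.has_edge(u, v)

    def edges(self) -> Iterable[tuple[str, str]]:
        return self._graph.edges()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AttributedGraph(|V|={self.n_nodes}, |E|={self.n_edges}, "
            f"M={self.n_attributes})"
        )


class WeightedGraph:
    """Symmetric nonnegative edge weights supported on an adjacency.

    W(i,j) = W(j,i) >= 0 and W(i,j) > 0 only where an edge exists.  Edges
    with weight exactly 0 are kept (a degenerate but legal weighting).
    """

    def __init__(self, nodes: Sequence[str], weights: Mapping[tuple[str, str], float]):
        self.nodes: list[str] = list(nodes)
        node_set = set(self.nodes)
        self._graph = nx.Graph()
        self._graph.add_nodes_from(self.nodes)
        for (u, v), w in weights.items():
            if u == v:
                raise GraphValidationError("self-loop weight not allowed")
            if u not in node_set or v not in node_set:
                raise GraphValidationError(f"weight on unknown node pair ({u}, {v})")
            if w < 0:
                raise GraphValidationError(f"negative weight on ({u}, {v})")
            self._graph.add_edge(u, v, weight=float(w))

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "WeightedGraph":
        return cls(list(g.nodes), {(u, v): d.get("weight", 1.0) for u, v, d in g.edges(data=True)})

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def weight(self, u: str, v: str) -> float:
        if self._graph.has_edge(u, v):
            return self._graph[u][v]["weight"]
        return 0.0

    def weighted_degree(self, u: str) -> float:
        """d_i^w = sum of weights of edges incident to u."""
        return sum(d["weight"] for _, _, d in self._graph.edges(u, data=True))

    @property
    def total_weight(self) -> float:
        """m_w: the ordered-pair total, i.e. twice the sum of edge weights."""
        return 2.0 * sum(d["weight"] for _, _, d in self._graph.edges(data=True))

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for u, v, d in self._graph.edges(data=True):
            yield u, v, d["weight"]

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedGraph(|V|={len(self.nodes)}, |E|={self._graph.number_of_edges()})"


@dataclass(frozen=True)
class Partition:
    """Disjoint assignment of every node to exactly one community.

    Community labels are opaque; all evaluation metrics are invariant to
    relabeling.
    """

    assignment: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def nodes(self) -> list[str]:
        return list(self.assignment)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, label: str) -> frozenset[str]:
        return frozenset(n for n, c in self.assignment.items() if c == label)

    def communities(self) -> list[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for n, c in self.assignment.items():
            groups.setdefault(c, set()).add(n)
        return [frozenset(groups[label]) for label in sorted(groups)]

    def __getitem__(self, node: str) -> str:
        return self.assignment[node]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_edge_list(path: Path, strict: bool) -> nx.Graph:
    g = nx.Graph()
    seen: set[frozenset[str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphValidationError(
                    f"{path}:{lineno}: expected two node ids, got {len(parts)} tokens"
                )
            u, v = parts
            if u == v:
                if strict:
                    raise GraphValidationError(f"{path}:{lineno}: self-loop on {u!r}")
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                continue
            key = frozenset((u, v))
            if key in seen:
                if strict:
                    raise GraphValidationError(f"{path}:{lineno}: duplicate edge {u}-{v}")
                logger.warning("%s:%d: dropping duplicate edge %s-%s", path, lineno, u, v)
                continue
            seen.add(key)
            g.add_edge(u, v)
    return g


def _read_attribute_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, index_col=0)
    if df.shape[1] < 1:
        raise GraphValidationError(f"{path}: attribute table has no attribute columns")
    if df.isna().any().any():
        bad = df[df.isna().any(axis=1)].index.tolist()
        raise GraphValidationError(
            f"{path}: empty attribute cell for node(s) {bad[:5]}"
        )
    df.index = df.index.astype(str)
    return df


def load_attributed_network(
    edge_list_path: str | Path,
    attribute_table_path: str | Path,
    strict: bool = True,
) -> AttributedGraph:
    """Read an edge list and an attribute table into an AttributedGraph.

    In strict mode (default) self-loops and duplicate edges are errors; in
    lenient mode they are dropped with a logged warning.  An edge endpoint
    absent from the attribute table is always an error; a node present only
    in the attribute table becomes an isolated node.
    """
    graph = _read_edge_list(Path(edge_list_path), strict=strict)
    attrs = _read_attribute_table(Path(attribute_table_path))
    unknown = [n for n in graph.nodes if n not in attrs.index]
    if unknown:
        raise GraphValidationError(
            f"edge list references node(s) absent from attribute table: {sorted(unknown)[:5]}"
        )
    return AttributedGraph(graph, attrs)


def write_partition(p: Partition, path: str | Path) -> None:
    """Write ``node<TAB>community`` lines (with header), sorted by node id."""
    with open(path, "w") as fh:
        fh.write("node\tcommunity\n")
        for node in sorted(p.assignment):
            fh.write(f"{node}\t{p.assignment[node]}\n")


def load_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return Partition(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_weighted_edges(w: WeightedGraph, path: str | Path, precision: int = 6) -> None:
    """Write ``u<TAB>v<TAB>weight``, each unordered pair once, sorted."""
    rows = sorted((min(u, v), max(u, v), wt) for u, v, wt in w.edges())
    with open(path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for u, v, wt in rows:
            fh.write(f"{u}\t{v}\t{wt:.{precision}f}\n")


def load_weighted_edges(path: str | Path, nodes: Sequence[str] | None = None) -> WeightedGraph:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    weights = {
        (str(r.u), str(r.v)): float(r.weight) for r in df.itertuples(index=False)
    }
    if nodes is None:
        nodes = sorted({n for pair in weights for n in pair})
    return WeightedGraph(nodes, weights)


def write_graphml(w: WeightedGraph, path: str | Path) -> None:
    """GraphML export of a weighted graph, for interoperability."""
    nx.write_graphml(w.graph, path)


def simplify_to_undirected(g: nx.Graph | nx.DiGraph) -> nx.Graph:
    """Collapse a (possibly directed, weighted) graph to unweighted undirected.

    Direction is dropped, parallel edges collapse to one, input weights are
    discarded, and self-loops are removed.  This mirrors the usual
    preprocessing of directed weighted social networks before structural
    community detection.
    """
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for u, v in g.edges():
        if u != v:
            out.add_edge(u, v)
    return out
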