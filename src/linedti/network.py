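"""Typed heterogeneous association network.

The network joins five molecule classes -- drugs, proteins, lncRNAs, miRNAs
and diseases -- through undirected, weighted association edges grouped into
a small closed set of association classes (miRNA-disease, drug-disease,
protein-protein, ...).  It is the object the embedding module trains
against: it owns the edge weights :math:`w_{ij}`, the total weight
:math:`W` and the weighted degrees :math:`d_i` that define the empirical
first- and second-order edge distributions.

Edges are stored undirected; for second-order (conditional) probabilities
each undirected edge is read as two directed arcs, so the "out-degree" of a
node equals its weighted degree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ConfigError, DegenerateNodeError, ParseError, TypeConflictError

NODE_TYPES: tuple[str, ...] = ("drug", "protein", "lncRNA", "miRNA", "disease")

#: Association classes and the node type of their (source, target) columns.
#: The first eight are the classes the multi-molecule network is built from;
#: ``drug-protein`` is additionally accepted so that known interaction edges
#: can be placed in (and stripped from) the graph for ranking experiments.
ASSOCIATION_CLASSES: dict[str, tuple[str, str]] = {
    "miRNA-lncRNA": ("miRNA", "lncRNA"),
    "miRNA-disease": ("miRNA", "disease"),
    "miRNA-protein": ("miRNA", "protein"),
    "lncRNA-disease": ("lncRNA", "disease"),
    "drug-disease": ("drug", "disease"),
    "lncRNA-protein": ("lncRNA", "protein"),
    "protein-protein": ("protein", "protein"),
    "protein-disease": ("protein", "disease"),
    "drug-protein": ("drug", "protein"),
}

#: The eight classes generated for the multi-molecule association network.
NETWORK_CLASSES: tuple[str, ...] = tuple(
    c for c in ASSOCIATION_CLASSES if c != "drug-protein"
)

_TYPE_PAIR_TO_CLASS = {
    frozenset(types): name for name, types in ASSOCIATION_CLASSES.items()
}


@dataclass(frozen=True)
class NodeId:
    """A graph vertex: a molecule (or disease) name plus its type."""

    name: str
    node_type: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("node name must be non-empty")
        if self.node_type not in NODE_TYPES:
            raise ConfigError(
                f"unknown node type {self.node_type!r}; expected one of {NODE_TYPES}"
            )


@dataclass
class EdgeTable:
    """Rows of one association class: ``(source, target, weight)`` triples."""

    association_class: str
    rows: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.association_class not in ASSOCIATION_CLASSES:
            raise ConfigError(
                f"unknown association class {self.association_class!r}; "
                f"expected one of {sorted(ASSOCIATION_CLASSES)}"
            )

    @property
    def source_type(self) -> str:
        return ASSOCIATION_CLASSES[self.association_class][0]

    @property
    def target_type(self) -> str:
        return ASSOCIATION_CLASSES[self.association_class][1]


def load_edge_table(path: str | Path, association_class: str) -> EdgeTable:
    """Parse a TSV/CSV edge list into an :class:`EdgeTable`.

    Columns are ``source<TAB>target[<TAB>weight]`` (comma also accepted);
    ``#``-prefixed lines and blank lines are ignored.  A missing weight
    defaults to 1.0.  Duplicate rows are removed under *unordered* pair
    identity -- ``(a, b)`` and ``(b, a)`` are the same undirected edge and
    the first occurrence wins.
    """
    table = EdgeTable(association_class)
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            fields = [f.strip() for f in fields]
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"{path}: line {lineno}: expected 2-3 fields, got {len(fields)}"
                )
            src, dst = fields[0], fields[1]
            if not src or not dst:
                raise ParseError(f"{path}: line {lineno}: empty node name")
            if len(fields) == 3:
                try:
                    weight = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: bad weight {fields[2]!r}"
                    ) from exc
                if weight <= 0:
                    raise ParseError(
                        f"{path}: line {lineno}: weight must be positive"
                    )
            else:
                weight = 1.0
            key = (src, dst) if src <= dst else (dst, src)
            if key in seen:
                continue
            seen.add(key)
            table.rows.append((src, dst, weight))
    return table


class HeteroGraph:
    """Undirected, weighted, typed multi-molecule association network.

    Invariants: no self-loops, no duplicate undirected edges, all weights
    positive, every edge endpoint registered with exactly one node type.
    """

    def __init__(self) -> None:
        self._types: dict[str, str] = {}
        self._adj: dict[str, dict[str, float]] = {}
        self._W: float = 0.0
        self.self_loops_rejected: int = 0
        self.duplicates_skipped: int = 0

    # -- construction -------------------------------------------------

    def add_node(self, name: str, node_type: str) -> None:
        NodeId(name, node_type)  # validate
        existing = self._types.get(name)
        if existing is None:
            self._types[name] = node_type
            self._adj[name] = {}
        elif existing != node_type:
            raise TypeConflictError(
                f"node {name!r} registered as both {existing!r} and {node_type!r}"
            )

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> bool:
        """Add an undirected edge; returns False if it already exists."""
        if a == b:
            self.self_loops_rejected += 1
            return False
        for n in (a, b):
            if n not in self._types:
                raise ConfigError(f"edge endpoint {n!r} is not a registered node")
        if weight <= 0:
            raise ConfigError(f"edge weight must be positive, got {weight}")
        if b in self._adj[a]:
            self.duplicates_skipped += 1
            return False
        self._adj[a][b] = weight
        self._adj[b][a] = weight
        self._W += weight
        return True

    def copy(self) -> "HeteroGraph":
        g = HeteroGraph()
        g._types = dict(self._types)
        g._adj = {n: dict(nbrs) for n, nbrs in self._adj.items()}
        g._W = self._W
        return g

    def remove_edge(self, a: str, b: str) -> None:
        w = self._adj[a].pop(b)
        self._adj[b].pop(a)
        self._W -= w

    # -- queries ------------------------------------------------------

    @property
    def W(self) -> float:
        """Total edge weight, each undirected edge counted once."""
        return self._W

    @property
    def num_nodes(self) -> int:
        return len(self._types)

    @property
    def num_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def __contains__(self, name: str) -> bool:
        return name in self._types

    def node_type(self, name: str) -> str:
        return self._types[name]

    def node_names(self) -> list[str]:
        """All node names in a deterministic (type, name) order."""
        return sorted(self._types, key=lambda n: (self._types[n], n))

    def nodes(self) -> Iterator[NodeId]:
        for name in self.node_names():
            yield NodeId(name, self._types[name])

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self._types.items() if t == node_type)

    def neighbors(self, name: str) -> Mapping[str, float]:
        return self._adj[name]

    def has_edge(self, a: str, b: str) -> bool:
        return a in self._adj and b in self._adj[a]

    def edge_weight(self, a: str, b: str) -> float:
        return self._adj[a].get(b, 0.0)

    def degree(self, name: str) -> float:
        """Weighted degree d_i (equals out-degree under arc expansion)."""
        return sum(self._adj[name].values())

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Undirected edges, each once, endpoints sorted, deterministic order."""
        for a in sorted(self._adj):
            for b, w in sorted(self._adj[a].items()):
                if a < b:
                    yield a, b, w

    def edge_class(self, a: str, b: str) -> str:
        return _TYPE_PAIR_TO_CLASS[frozenset((self._types[a], self._types[b]))]

    # -- reporting / round-trip ---------------------------------------

    def summary(self) -> dict:
        """Per-type node counts and per-class edge counts plus totals."""
        node_counts = {t: 0 for t in NODE_TYPES}
        for t in self._types.values():
            node_counts[t] += 1
        edge_counts: dict[str, int] = {}
        for a, b, _ in self.edges():
            cls = self.edge_class(a, b)
            edge_counts[cls] = edge_counts.get(cls, 0) + 1
        return {
            "nodes": node_counts,
            "total_nodes": self.num_nodes,
            "edges": dict(sorted(edge_counts.items())),
            "total_edges": self.num_edges,
            "total_weight": self._W,
        }

    def to_edge_tables(self) -> list[EdgeTable]:
        """Decompose the graph back into one table per association class."""
        tables: dict[str, EdgeTable] = {}
        for a, b, w in self.edges():
            cls = self.edge_class(a, b)
            table = tables.setdefault(cls, EdgeTable(cls))
            src_t = ASSOCIATION_CLASSES[cls][0]
            row = (a, b, w) if self._types[a] == src_t else (b, a, w)
            table.rows.append(row)
        return [tables[c] for c in sorted(tables)]


def build_graph(tables: Iterable[EdgeTable]) -> HeteroGraph:
    """Assemble a :class:`HeteroGraph` from per-class edge tables.

    Node types are assigned from the table columns; a name appearing with
    two types across tables is a hard error (a silent merge would destroy
    the heterogeneous five-type partition).  Self-loop rows are rejected
    and counted, duplicate undirected edges (within or across tables) are
    skipped and counted.
    """
    tables = list(tables)
    g = HeteroGraph()
    # first pass: register nodes so cross-table type conflicts surface early
    assigned: dict[str, str] = {}
    conflicts: set[str] = set()
    for table in tables:
        st, tt = table.source_type, table.target_type
        for src, dst, _ in table.rows:
            for name, t in ((src, st), (dst, tt)):
                prev = assigned.get(name)
                if prev is None:
                    assigned[name] = t
                elif prev != t:
                    conflicts.add(name)
    if conflicts:
        raise TypeConflictError(
            "node name(s) appear with two node types: " + ", ".join(sorted(conflicts))
        )
    for name in sorted(assigned):
        g.add_node(name, assigned[name])
    for table in tables:
        for src, dst, w in table.rows:
            g.add_edge(src, dst, w)
    return g


def empirical_first_order(g: HeteroGraph, i: str, j: str) -> float:
    """Empirical joint edge probability ``w_ij / W`` (0 for non-edges)."""
    if g.W == 0:
        return 0.0
    return g.edge_weight(i, j) / g.W


def empirical_second_order(g: HeteroGraph, i: str, j: str) -> float:
    """Empirical conditional neighbour probability ``w_ij / d_i``.

    Undirected edges are read as two directed arcs, so ``d_i`` is the
    weighted degree of ``i``.  Raises for isolated ``i`` (the conditional
    distribution is undefined there).
    """
    d_i = g.degree(i)
    if d_i == 0:
        raise DegenerateNodeError(
            f"node {i!r} is isolated; its conditional distribution is undefined"
        )
    return g.edge_weight(i, j) / d_i


def write_edge_tables(g: HeteroGraph, out_dir: str | Path) -> list[Path]:
    """Write one ``<class>.tsv`` per association class; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for table in g.to_edge_tables():
        path = out_dir / f"{table.association_class}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# {table.association_class}\n")
            for src, dst, w in table.rows:
                fh.write(f"{src}\t{dst}\t{w:g}\n")
        paths.append(path)
    return paths


def write_summary(g: HeteroGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(g.summary(), fh, indent=2)
        fh.write("\n")
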