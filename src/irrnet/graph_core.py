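"""Graph container, degree census and edge-partition extraction.

Degree-based irregularity indices depend on a graph only through the
multiset of endpoint-degree pairs of its edges.  This module provides the
simple-graph container, the degree census, and the *edge partition* — the
map from an unordered degree pair ``(d1, d2)`` with ``d1 <= d2`` to the
number of edges whose endpoints carry those degrees.  Indices of very large
networks are then evaluated from the partition alone, without touching a
concrete adjacency structure.

Storage is a :class:`networkx.Graph`; vertex labels are opaque (strings or
integers), and no geometry is kept.  Isolated vertices are permitted — they
carry degree 0 and never contribute edges.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Graph",
    "GraphValidationError",
    "ValidationReport",
    "degrees",
    "edge_partition",
    "validate",
    "read_edgelist",
    "write_edgelist",
    "read_partition_json",
    "write_partition_json",
    "check_partition_consistency",
]


class GraphValidationError(ValueError):
    """Raised when an input violates the simple-graph contract."""


class Graph:
    """An undirected simple graph: no self-loops, no duplicate edges.

    Parameters
    ----------
    edges : iterable of vertex-label pairs
    vertices : iterable of vertex labels, optional
        Extra vertices (possibly isolated) beyond the edge endpoints.
    """

    def __init__(self, edges: Iterable[tuple] = (), vertices: Iterable = ()):
        g = nx.Graph()
        g.add_nodes_from(vertices)
        for u, v in edges:
            if u == v:
                raise GraphValidationError(f"self-loop at vertex {u!r}")
            if g.has_edge(u, v):
                raise GraphValidationError(f"duplicate edge ({u!r}, {v!r})")
            g.add_edge(u, v)
        self._g = g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        """Wrap a networkx graph (validating the simple-graph contract)."""
        out = cls(g.edges(), g.nodes())
        return out

    # -- basic accessors -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._g.nodes())

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self._g.edges())

    def degree(self, v) -> int:
        return self._g.degree(v)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n_vertices={self.n_vertices}, n_edges={self.n_edges})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.vertices == other.vertices and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.vertices, self.edges))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of a vertex/edge count check; ``failures`` lists violations."""

    passed: bool
    failures: tuple[str, ...] = field(default_factory=tuple)


def degrees(g: Graph) -> dict[int, int]:
    """Degree census: mapping degree -> number of vertices with that degree.

    Satisfies the handshake lemma: ``sum(d * c) == 2 * g.n_edges``.
    """
    census = Counter(d for _, d in g.to_networkx().degree())
    return dict(sorted(census.items()))


def edge_partition(g: Graph) -> dict[tuple[int, int], int]:
    """Classify edges by the unordered degree pair of their endpoints.

    Returns a mapping ``(d1, d2) -> count`` with ``d1 <= d2``; the counts
    sum to ``g.n_edges``.
    """
    gx = g.to_networkx()
    deg = dict(gx.degree())
    part: Counter = Counter()
    for u, v in gx.edges():
        du, dv = deg[u], deg[v]
        part[(min(du, dv), max(du, dv))] += 1
    return dict(sorted(part.items()))


def validate(g: Graph, expected_vertices: int, expected_edges: int) -> ValidationReport:
    """Check a graph against expected vertex and edge counts.

    Used to pin generated networks to their closed-form counts, e.g.
    ``5n + 1`` vertices and ``12n`` edges for the octahedral chain.
    """
    failures = []
    if g.n_vertices != expected_vertices:
        failures.append(
            f"vertex count: expected {expected_vertices}, got {g.n_vertices}"
        )
    if g.n_edges != expected_edges:
        failures.append(f"edge count: expected {expected_edges}, got {g.n_edges}")
    return ValidationReport(passed=not failures, failures=tuple(failures))


def check_partition_consistency(
    partition: Mapping[tuple[int, int], int],
    census: Mapping[int, int],
    n_edges: int | None = None,
) -> ValidationReport:
    """Verify a partition against a degree census.

    Checks (i) counts sum to ``n_edges`` when given, and (ii) incidence
    consistency: for each degree ``d`` of ``c`` vertices, the number of
    edge-slots on degree-``d`` vertices, ``d * c``, equals the partition's
    incidences ``sum(count * multiplicity of d in the pair)``.
    """
    failures = []
    total = sum(partition.values())
    if n_edges is not None and total != n_edges:
        failures.append(f"partition total {total} != edge count {n_edges}")
    incid: Counter = Counter()
    for (d1, d2), c in partition.items():
        incid[d1] += c
        incid[d2] += c
    for d, c in census.items():
        if d == 0:
            continue
        if incid.get(d, 0) != d * c:
            failures.append(
                f"degree {d}: incidences {incid.get(d, 0)} != d*count {d * c}"
            )
    for d in incid:
        if d not in census:
            failures.append(f"degree {d} appears in partition but not in census")
    return ValidationReport(passed=not failures, failures=tuple(failures))


# -- file formats --------------------------------------------------------


def read_edgelist(path: str | Path) -> Graph:
    """Read a whitespace-separated edge list; lines starting with '#' are
    ignored.  Labels are kept as strings."""
    g = nx.read_edgelist(str(path), comments="#", data=False)
    return Graph.from_networkx(g)


def write_edgelist(g: Graph, path: str | Path) -> None:
    """Write one edge per line, two whitespace-separated labels."""
    nx.write_edgelist(g.to_networkx(), str(path), data=False)


def read_partition_json(path: str | Path) -> tuple[dict[tuple[int, int], int], dict]:
    """Read an edge-partition JSON document.

    Schema: ``{"pairs": [{"d1": int, "d2": int, "count": int}, ...],
    "n_vertices": int (optional), "n_edges": int (optional)}``.

    Returns the partition mapping plus a metadata dict with whatever of
    ``n_vertices``/``n_edges`` the document carried.
    """
    doc = json.loads(Path(path).read_text())
    part: dict[tuple[int, int], int] = {}
    for row in doc["pairs"]:
        d1, d2 = int(row["d1"]), int(row["d2"])
        key = (min(d1, d2), max(d1, d2))
        if key in part:
            raise GraphValidationError(f"duplicate degree pair {key} in {path}")
        count = int(row["count"])
        if count < 0:
            raise GraphValidationError(f"negative count for pair {key}")
        part[key] = count
    meta = {k: doc[k] for k in ("n_vertices", "n_edges") if k in doc}
    return dict(sorted(part.items())), meta


def write_partition_json(
    partition: Mapping[tuple[int, int], int],
    path: str | Path,
    n_vertices: int | None = None,
    n_edges: int | None = None,
) -> None:
    doc: dict = {
        "pairs": [
            {"d1": d1, "d2": d2, "count": c}
            for (d1, d2), c in sorted(partition.items())
        ]
    }
    if n_vertices is not None:
        doc["n_vertices"] = n_vertices
    if n_edges is not None:
        doc["n_edges"] = n_edges
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
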