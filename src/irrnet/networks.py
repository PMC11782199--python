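"""Polyhedral networks: platonic solids, corner-sharing chains, and the
octahedral/icosahedral sheet families.

Four network types are covered:

* the octahedron (6 vertices, 12 edges, 4-regular) and icosahedron
  (12 vertices, 30 edges, 5-regular) platonic graphs;
* the linear chains ``CHO_n`` / ``CHI_n``: n copies of the solid in a row,
  consecutive copies sharing one corner vertex, so each shared corner
  reaches twice the base degree (8, resp. 10);
* the two-dimensional sheet families ``OT_n`` / ``IS_n``, parameterised by
  a circumscribing order n.  The sheets are represented by their degree-pair
  edge partitions — quadratic polynomials in n — rather than by explicit
  adjacency: the partition determines every degree-based index, and it is
  the partition, together with the vertex/edge count formulas
  (OT_n: 27n^2 + 3n and 72n^2; IS_n: 63n^2 + 3n and 180n^2), that pins the
  families down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import networkx as nx

from .graph_core import Graph
from .indices import PartitionFamily

__all__ = [
    "NetworkSpec",
    "NETWORK_SPECS",
    "OT_FAMILY",
    "IS_FAMILY",
    "CHO_FAMILY",
    "CHI_FAMILY",
    "platonic",
    "chain",
    "partition_family",
    "degree_census_family",
    "fixture_graphs",
]

#: Seed for the random fixture graphs; fixed so fixtures are reproducible.
FIXTURE_SEED = 42

OT_FAMILY = PartitionFamily.from_dict(
    "OT",
    {
        (4, 4): (18, 12, 0),
        (4, 8): (36, 0, 0),
        (8, 8): (18, -12, 0),
    },
)

IS_FAMILY = PartitionFamily.from_dict(
    "IS",
    {
        (5, 5): (108, 18, 0),
        (5, 10): (54, -6, 0),
        (10, 10): (18, -12, 0),
    },
)

# Chain partitions follow from the construction: each of the n-1 shared
# corners carries 2*base_degree edges to ordinary corners.
CHO_FAMILY = PartitionFamily.from_dict(
    "CHO",
    {
        (4, 4): (0, 4, 8),
        (4, 8): (0, 8, -8),
    },
)

CHI_FAMILY = PartitionFamily.from_dict(
    "CHI",
    {
        (5, 5): (0, 20, 10),
        (5, 10): (0, 10, -10),
    },
)


@dataclass(frozen=True)
class NetworkSpec:
    """Counts and partition data for one network type.

    ``vertex_poly`` / ``edge_poly`` are ``(a2, a1, a0)`` coefficients in the
    dimension parameter n (constant for the solids, with n ignored).
    ``constructor`` builds the concrete graph where one is defined.
    """

    name: str
    vertex_poly: tuple[int, int, int]
    edge_poly: tuple[int, int, int]
    family: Optional[PartitionFamily] = None
    constructor: Optional[Callable[[int], Graph]] = None

    def n_vertices(self, n: int = 1) -> int:
        a2, a1, a0 = self.vertex_poly
        return a2 * n * n + a1 * n + a0

    def n_edges(self, n: int = 1) -> int:
        a2, a1, a0 = self.edge_poly
        return a2 * n * n + a1 * n + a0


def _octahedron_nx() -> nx.Graph:
    return nx.octahedral_graph()

def _icosahedron_nx() -> nx.Graph:
    return nx.icosahedral_graph()


_BASE_NX = {"OCTAHEDRON": _octahedron_nx, "ICOSAHEDRON": _icosahedron_nx}


def platonic(kind: str) -> Graph:
    """The octahedron or icosahedron platonic graph."""
    try:
        base = _BASE_NX[kind]()
    except KeyError:
        raise ValueError(
            f"unknown platonic solid {kind!r}; expected OCTAHEDRON or ICOSAHEDRON"
        ) from None
    return Graph.from_networkx(base)


def _antipodal_pair(g: nx.Graph) -> tuple:
    """A deterministic pair of vertices at maximum distance (non-adjacent).

    In the octahedron this is the unique non-neighbour of the entry vertex;
    in the icosahedron the unique vertex at distance 3.  Non-adjacency is
    what matters: it keeps the two shared corners of a middle chain copy
    from forming a doubled-degree edge.
    """
    entry = min(g.nodes())
    dist = nx.single_source_shortest_path_length(g, entry)
    far = max(dist.values())
    exits = sorted(v for v, d in dist.items() if d == far)
    return entry, exits[0]


_CHAIN_BASE = {"CHO": "OCTAHEDRON", "CHI": "ICOSAHEDRON"}


def chain(kind: str, n: int) -> Graph:
    """Corner-sharing chain of n octahedra (CHO) or icosahedra (CHI).

    Copy i's exit corner is identified with copy i+1's entry corner; entry
    and exit are antipodal in each copy.  CHO_n has 5n + 1 vertices and 12n
    edges; CHI_n has 11n + 1 vertices and 30n edges.
    """
    if kind not in _CHAIN_BASE:
        raise ValueError(f"unknown chain kind {kind!r}; expected CHO or CHI")
    if n < 1:
        raise ValueError(f"chain length must be >= 1, got {n}")
    base = _BASE_NX[_CHAIN_BASE[kind]]()
    entry, exit_ = _antipodal_pair(base)
    labels: dict[tuple[int, object], str] = {}
    for i in range(n):
        for v in base.nodes():
            if i > 0 and v == entry:
                labels[(i, v)] = labels[(i - 1, exit_)]
            else:
                labels[(i, v)] = f"c{i}v{v}"
    edges = [
        (labels[(i, u)], labels[(i, v)])
        for i in range(n)
        for u, v in base.edges()
    ]
    return Graph(edges)


def _ot_constructor(n: int) -> Graph:
    raise NotImplementedError(
        "OT_n sheets are represented by their edge partition, not built as "
        "explicit graphs"
    )


NETWORK_SPECS: dict[str, NetworkSpec] = {
    "OCTAHEDRON": NetworkSpec(
        "OCTAHEDRON", (0, 0, 6), (0, 0, 12), constructor=lambda n: platonic("OCTAHEDRON")
    ),
    "ICOSAHEDRON": NetworkSpec(
        "ICOSAHEDRON",
        (0, 0, 12),
        (0, 0, 30),
        constructor=lambda n: platonic("ICOSAHEDRON"),
    ),
    "CHO": NetworkSpec(
        "CHO", (0, 5, 1), (0, 12, 0), family=CHO_FAMILY,
        constructor=lambda n: chain("CHO", n),
    ),
    "CHI": NetworkSpec(
        "CHI", (0, 11, 1), (0, 30, 0), family=CHI_FAMILY,
        constructor=lambda n: chain("CHI", n),
    ),
    "OT": NetworkSpec("OT", (27, 3, 0), (72, 0, 0), family=OT_FAMILY),
    "IS": NetworkSpec("IS", (63, 3, 0), (180, 0, 0), family=IS_FAMILY),
}


def partition_family(kind: str) -> PartitionFamily:
    """The edge-partition family of a parametric network (OT, IS, CHO, CHI)."""
    spec = NETWORK_SPECS.get(kind)
    if spec is None or spec.family is None:
        raise ValueError(f"no partition family for network kind {kind!r}")
    return spec.family


#: Degree-class counts of the sheet families as quadratics in n, solved from
#: the vertex-count polynomial together with the handshake and incidence
#: identities.  OT: 4a + 8b = 2*72n^2, a + b = 27n^2 + 3n;
#: IS: 5a + 10b = 2*180n^2, a + b = 63n^2 + 3n.
_CENSUS_FAMILIES: dict[str, dict[int, tuple[int, int, int]]] = {
    "OT": {4: (18, 6, 0), 8: (9, -3, 0)},
    "IS": {5: (54, 6, 0), 10: (9, -3, 0)},
}


def degree_census_family(kind: str) -> dict[int, tuple[int, int, int]]:
    """Degree -> (a2, a1, a0) vertex-count coefficients for OT or IS."""
    try:
        return dict(_CENSUS_FAMILIES[kind])
    except KeyError:
        raise ValueError(
            f"no degree-census family for network kind {kind!r}; expected OT or IS"
        ) from None


def evaluate_poly_map(
    polys: dict, n: int
) -> dict:
    """Evaluate a mapping of (a2, a1, a0) coefficient triples at integer n."""
    return {k: a2 * n * n + a1 * n + a0 for k, (a2, a1, a0) in polys.items()}


def fixture_graphs() -> dict[str, Graph]:
    """A deterministic suite of small labelled graphs for testing.

    Paths, cycles, stars, complete graphs, the two platonic solids, chains
    up to n = 4, and seeded Erdos-Renyi random graphs.  Fully reproducible:
    the random graphs use fixed seeds.
    """
    out: dict[str, Graph] = {}
    for k in range(2, 6):
        out[f"P{k}"] = Graph.from_networkx(nx.path_graph(k))
    for k in range(3, 7):
        out[f"C{k}"] = Graph.from_networkx(nx.cycle_graph(k))
    for k in range(3, 7):
        out[f"S{k}"] = Graph.from_networkx(nx.star_graph(k))
    for k in range(2, 7):
        out[f"K{k}"] = Graph.from_networkx(nx.complete_graph(k))
    out["octahedron"] = platonic("OCTAHEDRON")
    out["icosahedron"] = platonic("ICOSAHEDRON")
    for n in range(1, 5):
        out[f"CHO_{n}"] = chain("CHO", n)
        out[f"CHI_{n}"] = chain("CHI", n)
    for i, (nv, p) in enumerate([(10, 0.4), (12, 0.3), (8, 0.5)]):
        g = nx.gnp_random_graph(nv, p, seed=FIXTURE_SEED + i)
        out[f"ER_{nv}_{int(p * 10)}"] = Graph.from_networkx(g)
    return out
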