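"""The twelve degree-based irregularity indices.

An irregularity index is a topological invariant that vanishes exactly on
regular graphs.  Each index here is an edge sum

    I(G) = prefactor * sum over edges uv of h(d_u, d_v)

with a symmetric kernel ``h`` satisfying ``h(d, d) = 0``.  The twelve
kernels (natural logarithms throughout):

    IRDIF  |du/dv - dv/du|                      prefactor 1
    AL     |du - dv|                (Albertson) prefactor 1
    IRL    |ln du - ln dv|                      prefactor 1
    IRLU   |du - dv| / min(du, dv)              prefactor 1
    IRLF   |du - dv| / sqrt(du dv)              prefactor 1
    IRF    (du - dv)^2                          prefactor 1
    IRLA   |du - dv| / (du + dv)                prefactor 2
    IRD1   ln(1 + |du - dv|)                    prefactor 1
    IRA    (du^-1/2 - dv^-1/2)^2                prefactor 1
    IRGA   ln((du + dv) / (2 sqrt(du dv)))      prefactor 2
    IRB    (sqrt(du) - sqrt(dv))^2              prefactor 1
    IRRt   |du - dv|                            prefactor 1/2

Indices may be computed from a concrete graph (edge iteration, float
arithmetic), from an edge partition (exact symbolic arithmetic), or from a
*partition family* — a parametric family of networks whose edge-class
counts are quadratic polynomials in a dimension parameter ``n`` — in which
case the index itself is recovered as a closed-form quadratic in ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
import sympy as sp

from .graph_core import Graph, edge_partition

__all__ = [
    "INDEX_IDS",
    "IndexDefinition",
    "IndexDomainError",
    "PartitionFamily",
    "ClosedForm",
    "kernel_table",
    "get_index",
    "compute_from_graph",
    "compute_from_partition",
    "symbolic_from_partition",
    "closed_form",
    "index_table",
    "compare_families",
    "ComparisonResult",
]

#: Canonical ordering of the twelve indices (presentation order of the tables).
INDEX_IDS: tuple[str, ...] = (
    "IRDIF",
    "AL",
    "IRL",
    "IRLU",
    "IRLF",
    "IRF",
    "IRLA",
    "IRD1",
    "IRA",
    "IRGA",
    "IRB",
    "IRRt",
)

#: Kernels that divide by a degree or take its logarithm; these reject
#: degree-0 endpoints at computation time.
_POSITIVE_DEGREE_ONLY = frozenset({"IRDIF", "IRL", "IRLU", "IRLF", "IRA", "IRGA"})


class IndexDomainError(ValueError):
    """A kernel was evaluated on a degree outside its domain (degree 0)."""


@dataclass(frozen=True)
class IndexDefinition:
    """One irregularity index: a symmetric per-edge kernel plus a prefactor.

    ``kernel`` evaluates in floating point (for edge iteration over concrete
    graphs); ``kernel_sym`` returns an exact sympy expression (for partition
    and closed-form computation).
    """

    id: str
    prefactor: Fraction
    kernel_float: Callable[[int, int], float]
    kernel_symbolic: Callable[[int, int], sp.Expr]
    description: str

    def _check_domain(self, du: int, dv: int) -> None:
        if self.id in _POSITIVE_DEGREE_ONLY and min(du, dv) < 1:
            raise IndexDomainError(
                f"index {self.id}: kernel undefined for degree pair "
                f"({du}, {dv}) — degrees must be >= 1"
            )

    def kernel(self, du: int, dv: int) -> float:
        """Float kernel value h(du, dv); symmetric, zero on the diagonal."""
        self._check_domain(du, dv)
        return self.kernel_float(du, dv)

    def kernel_sym(self, du: int, dv: int) -> sp.Expr:
        """Exact symbolic kernel value."""
        self._check_domain(du, dv)
        return self.kernel_symbolic(du, dv)


def _sym_irdif(a: int, b: int) -> sp.Expr:
    return abs(sp.Rational(a, b) - sp.Rational(b, a))


def _sym_irl(a: int, b: int) -> sp.Expr:
    # |ln a - ln b| = ln(max/min)
    return sp.log(sp.Rational(max(a, b), min(a, b)))


def _sym_irlf(a: int, b: int) -> sp.Expr:
    return sp.Integer(abs(a - b)) / sp.sqrt(sp.Integer(a * b))


def _sym_ira(a: int, b: int) -> sp.Expr:
    return (1 / sp.sqrt(sp.Integer(a)) - 1 / sp.sqrt(sp.Integer(b))) ** 2


def _sym_irga(a: int, b: int) -> sp.Expr:
    return sp.log(sp.Rational(a + b, 2) / sp.sqrt(sp.Integer(a * b)))


def _sym_irb(a: int, b: int) -> sp.Expr:
    return (sp.sqrt(sp.Integer(a)) - sp.sqrt(sp.Integer(b))) ** 2


_DEFINITIONS: tuple[IndexDefinition, ...] = (
    IndexDefinition(
        "IRDIF",
        Fraction(1),
        lambda a, b: abs(a / b - b / a),
        _sym_irdif,
        "sum of |du/dv - dv/du| over edges",
    ),
    IndexDefinition(
        "AL",
        Fraction(1),
        lambda a, b: float(abs(a - b)),
        lambda a, b: sp.Integer(abs(a - b)),
        "Albertson index: sum of |du - dv| over edges",
    ),
    IndexDefinition(
        "IRL",
        Fraction(1),
        lambda a, b: abs(math.log(a) - math.log(b)),
        _sym_irl,
        "sum of |ln du - ln dv| over edges",
    ),
    IndexDefinition(
        "IRLU",
        Fraction(1),
        lambda a, b: abs(a - b) / min(a, b),
        lambda a, b: sp.Rational(abs(a - b), min(a, b)),
        "sum of |du - dv| / min(du, dv) over edges",
    ),
    IndexDefinition(
        "IRLF",
        Fraction(1),
        lambda a, b: abs(a - b) / math.sqrt(a * b),
        _sym_irlf,
        "sum of |du - dv| / sqrt(du dv) over edges",
    ),
    IndexDefinition(
        "IRF",
        Fraction(1),
        lambda a, b: float((a - b) ** 2),
        lambda a, b: sp.Integer((a - b) ** 2),
        "sum of (du - dv)^2 over edges",
    ),
    IndexDefinition(
        "IRLA",
        Fraction(2),
        lambda a, b: abs(a - b) / (a + b),
        lambda a, b: sp.Rational(abs(a - b), a + b),
        "2 x sum of |du - dv| / (du + dv) over edges",
    ),
    IndexDefinition(
        "IRD1",
        Fraction(1),
        lambda a, b: math.log1p(abs(a - b)),
        lambda a, b: sp.log(1 + abs(a - b)),
        "sum of ln(1 + |du - dv|) over edges",
    ),
    IndexDefinition(
        "IRA",
        Fraction(1),
        lambda a, b: (a ** -0.5 - b ** -0.5) ** 2,
        _sym_ira,
        "sum of (du^-1/2 - dv^-1/2)^2 over edges",
    ),
    IndexDefinition(
        "IRGA",
        Fraction(2),
        lambda a, b: math.log((a + b) / (2 * math.sqrt(a * b))),
        _sym_irga,
        "2 x sum of ln((du + dv) / (2 sqrt(du dv))) over edges",
    ),
    IndexDefinition(
        "IRB",
        Fraction(1),
        lambda a, b: (math.sqrt(a) - math.sqrt(b)) ** 2,
        _sym_irb,
        "sum of (sqrt(du) - sqrt(dv))^2 over edges",
    ),
    IndexDefinition(
        "IRRt",
        Fraction(1, 2),
        lambda a, b: float(abs(a - b)),
        lambda a, b: sp.Integer(abs(a - b)),
        "total irregularity: half the sum of |du - dv| over edges",
    ),
)

_BY_ID: dict[str, IndexDefinition] = {d.id: d for d in _DEFINITIONS}


def kernel_table() -> tuple[IndexDefinition, ...]:
    """The twelve index definitions, in canonical order."""
    return _DEFINITIONS


def get_index(index_id: str) -> IndexDefinition:
    try:
        return _BY_ID[index_id]
    except KeyError:
        raise KeyError(
            f"unknown index {index_id!r}; expected one of {', '.join(INDEX_IDS)}"
        ) from None


@lru_cache(maxsize=4096)
def _kernel_value(index_id: str, d1: int, d2: int) -> float:
    return _BY_ID[index_id].kernel(d1, d2)


def _to_number(expr: sp.Expr) -> int | float:
    """Render an exact sympy value as int (when integral) or float."""
    expr = sp.nsimplify(expr) if expr.free_symbols else expr
    if expr.is_Integer:
        return int(expr)
    return float(expr.evalf(30))


def compute_from_graph(g: Graph, index_id: str) -> float:
    """Evaluate an index by iterating over the edges of a concrete graph."""
    defn = get_index(index_id)
    gx = g.to_networkx()
    deg = dict(gx.degree())
    total = 0.0
    for u, v in gx.edges():
        du, dv = deg[u], deg[v]
        total += _kernel_value(index_id, min(du, dv), max(du, dv))
    return float(defn.prefactor) * total


def symbolic_from_partition(
    partition: Mapping[tuple[int, int], int], index_id: str
) -> sp.Expr:
    """Exact symbolic value of an index from an edge partition."""
    defn = get_index(index_id)
    total = sp.Integer(0)
    for (d1, d2), count in partition.items():
        if count < 0:
            raise ValueError(f"negative edge count for pair ({d1}, {d2})")
        if count:
            total += sp.Integer(count) * defn.kernel_sym(d1, d2)
    return sp.Rational(defn.prefactor.numerator, defn.prefactor.denominator) * total


def compute_from_partition(
    partition: Mapping[tuple[int, int], int], index_id: str
) -> int | float:
    """Evaluate an index from an edge partition (exact arithmetic inside).

    Integer-valued results are returned as exact ints; irrational results as
    floats.
    """
    return _to_number(symbolic_from_partition(partition, index_id))


# -- parametric families -------------------------------------------------


@dataclass(frozen=True)
class PartitionFamily:
    """Edge partition of a parametric network family.

    Each degree pair maps to integer coefficients ``(a2, a1, a0)`` giving
    its edge count as ``a2 n^2 + a1 n + a0``; valid for integer ``n >= 1``.
    """

    name: str
    pairs: tuple[tuple[tuple[int, int], tuple[int, int, int]], ...]

    @classmethod
    def from_dict(
        cls,
        name: str,
        pairs: Mapping[tuple[int, int], tuple[int, int, int]],
    ) -> "PartitionFamily":
        return cls(name, tuple(sorted((k, tuple(v)) for k, v in pairs.items())))

    def as_dict(self) -> dict[tuple[int, int], tuple[int, int, int]]:
        return {k: v for k, v in self.pairs}

    def evaluate(self, n: int) -> dict[tuple[int, int], int]:
        """Concrete edge partition at dimension ``n``."""
        out = {}
        for (d1, d2), (a2, a1, a0) in self.pairs:
            count = a2 * n * n + a1 * n + a0
            if count < 0:
                raise ValueError(
                    f"family {self.name}: negative count {count} for pair "
                    f"({d1}, {d2}) at n={n}"
                )
            out[(d1, d2)] = count
        return out

    def edge_count_poly(self) -> tuple[int, int, int]:
        """Coefficient-wise total of the pair polynomials."""
        a2 = sum(c[0] for _, c in self.pairs)
        a1 = sum(c[1] for _, c in self.pairs)
        a0 = sum(c[2] for _, c in self.pairs)
        return (a2, a1, a0)


@dataclass(frozen=True)
class ClosedForm:
    """Quadratic closed form ``a2 n^2 + a1 n + a0`` of an index of a family.

    Coefficients are exact sympy expressions (rational combinations of
    logarithms and square roots where the kernel produces them).
    """

    index_id: str
    a2: sp.Expr
    a1: sp.Expr
    a0: sp.Expr

    def coefficients(self) -> tuple[float, float, float]:
        return (float(self.a2), float(self.a1), float(self.a0))

    def evaluate_exact(self, n: int) -> sp.Expr:
        return self.a2 * n * n + self.a1 * n + self.a0

    def __call__(self, n: int) -> int | float:
        return _to_number(self.evaluate_exact(n))

    def __str__(self) -> str:
        def fmt(c: sp.Expr) -> str:
            return str(_to_number(c))

        return (
            f"{self.index_id}(n) = {fmt(self.a2)}*n^2 + {fmt(self.a1)}*n"
            f" + {fmt(self.a0)}"
        )


def closed_form(family: PartitionFamily, index_id: str) -> ClosedForm:
    """Closed form of an index over a partition family.

    Because the index is linear in the edge-class counts and each count is a
    quadratic in ``n``, the index is the quadratic whose coefficients are
    kernel-weighted sums of the count coefficients, scaled by the prefactor.
    """
    defn = get_index(index_id)
    pref = sp.Rational(defn.prefactor.numerator, defn.prefactor.denominator)
    a2 = sp.Integer(0)
    a1 = sp.Integer(0)
    a0 = sp.Integer(0)
    for (d1, d2), (c2, c1, c0) in family.pairs:
        k = defn.kernel_sym(d1, d2)
        a2 += c2 * k
        a1 += c1 * k
        a0 += c0 * k
    return ClosedForm(
        index_id,
        sp.nsimplify(pref * a2),
        sp.nsimplify(pref * a1),
        sp.nsimplify(pref * a0),
    )


def index_table(
    family: PartitionFamily,
    n_values: Sequence[int],
    indices: Iterable[str] = INDEX_IDS,
) -> pd.DataFrame:
    """Grid of index values for a family: one row per index, one column per n.

    Integer-valued cells are exact ints; irrational cells are rounded to six
    decimal places.
    """
    indices = tuple(indices)
    for n in n_values:
        if n < 1:
            raise ValueError(f"dimension parameter must be >= 1, got {n}")
    data: dict[int, list] = {}
    for n in n_values:
        part = family.evaluate(n)
        col = []
        for idx in indices:
            v = compute_from_partition(part, idx)
            col.append(v if isinstance(v, int) else round(v, 6))
        data[n] = col
    df = pd.DataFrame(data, index=list(indices), dtype=object)
    df.index.name = "index"
    return df


@dataclass(frozen=True)
class ComparisonResult:
    """Per-n comparison of one index across two families."""

    index_id: str
    family_1: str
    family_2: str
    table: pd.DataFrame  # columns: n, value_1, value_2, difference
    verdict: str  # family_2_dominates | family_1_dominates | tie | mixed

    @property
    def differences(self) -> list:
        return list(self.table["difference"])


def compare_families(
    family_1: PartitionFamily,
    family_2: PartitionFamily,
    index_id: str,
    n_max: int,
) -> ComparisonResult:
    """Compare an index across two families for n = 1..n_max.

    The per-n difference is evaluated exactly; a difference of exactly zero
    is a tie.  The verdict is ``family_2_dominates`` when family 2 is
    strictly larger at every n (symmetrically for family 1), ``tie`` when
    every n ties, and ``mixed`` otherwise.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    rows = []
    signs = set()
    for n in range(1, n_max + 1):
        v1 = symbolic_from_partition(family_1.evaluate(n), index_id)
        v2 = symbolic_from_partition(family_2.evaluate(n), index_id)
        diff = sp.nsimplify(v2 - v1)
        if diff.is_zero:
            sign = 0
        else:
            sign = 1 if float(diff) > 0 else -1
        signs.add(sign)
        rows.append(
            {
                "n": n,
                "value_1": _to_number(v1),
                "value_2": _to_number(v2),
                "difference": _to_number(diff),
            }
        )
    if signs == {0}:
        verdict = "tie"
    elif signs == {1}:
        verdict = "family_2_dominates"
    elif signs == {-1}:
        verdict = "family_1_dominates"
    else:
        verdict = "mixed"
    return ComparisonResult(
        index_id, family_1.name, family_2.name, pd.DataFrame(rows), verdict
    )
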