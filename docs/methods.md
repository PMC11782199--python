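# Methods

## Model

An irregularity index of a simple undirected graph G is an edge sum

    I(G) = c · Σ_{uv ∈ E} h(d_u, d_v)

with a rational prefactor c and a symmetric kernel h satisfying
h(d, d) = 0. The twelve kernels implemented are listed in the README;
all logarithms are natural. Two consequences shape the whole package:

1. **Partition sufficiency.** I(G) depends on G only through its edge
   partition — the multiset of unordered endpoint-degree pairs (d1, d2),
   d1 ≤ d2, with edge counts. Indices of networks too large (or too
   under-specified) to build as concrete graphs can be computed from the
   partition alone.
2. **Closed forms.** For a parametric family whose class counts are
   quadratics a2·n² + a1·n + a0 in a dimension parameter n, linearity in
   the counts makes every index the quadratic whose coefficients are the
   kernel-weighted sums of the count coefficients, times the prefactor.
   This is how the closed forms for OT_n and IS_n are recovered.

Degree pairs are stored unordered (all kernels are symmetric). Vertex
labels are opaque; no geometry is kept.

## Networks

* **Platonic solids.** The octahedron (6 vertices, 12 edges, 4-regular)
  and icosahedron (12 vertices, 30 edges, 5-regular), via networkx.
* **Chains CHO_n / CHI_n.** n copies of the solid, consecutive copies
  sharing one corner, so shared corners reach degree 8 (resp. 10). The
  construction identifies each copy's *exit* corner with the next copy's
  *entry* corner, taking the antipodal (maximum-distance) vertex as the
  exit. Any non-adjacent entry/exit pair yields the same degree census —
  which is all the indices see — and non-adjacency is required so that the
  two shared corners of a middle copy never form an edge of doubled
  degrees. Counts: CHO_n has 5n + 1 vertices and 12n edges; CHI_n has
  11n + 1 and 30n.
* **Sheets OT_n / IS_n.** The two-dimensional sheet families are
  represented by their published degree-pair edge partitions
  (OT: {(4,4): 18n²+12n, (4,8): 36n², (8,8): 18n²−12n};
  IS: {(5,5): 108n²+18n, (5,10): 54n²−6n, (10,10): 18n²−12n}) together
  with the count polynomials (27n²+3n vertices / 72n² edges, and 63n²+3n /
  180n²). No explicit sheet graph is constructed: the available
  description (figures of corner-sharing rings) underdetermines the
  adjacency, while the partition fully determines every degree-based
  index. The partitions are validated structurally instead: totals match
  the edge polynomial coefficient-wise, all evaluated counts are
  nonnegative for n ≥ 1, and the degree-class censuses solved from the
  handshake and incidence identities
  (OT: {4: 18n²+6n, 8: 9n²−3n}; IS: {5: 54n²+6n, 10: 9n²−3n})
  are consistent with the partitions at every tested n.

## Numerical choices

* **Exact where possible.** Partition and closed-form computations run in
  sympy: rational kernels (AL, IRF, IRRt, IRDIF, IRLU, IRLA) stay exact,
  and irrational kernels keep symbolic form (rational combinations of
  ln 2, ln 5, √2, …) until rendered. Integer-valued results are returned
  as exact ints; irrational ones as floats, shown to 6 decimals in tables.
* **Graph route.** Edge iteration over concrete graphs uses cached float
  kernels; tests require agreement with the exact partition route to
  1e-12 relative.
* **Degenerate inputs.** Isolated vertices are allowed (they carry no
  edges). Kernels that divide by a degree or take its logarithm (IRDIF,
  IRL, IRLU, IRLF, IRA, IRGA) raise a domain error on degree-0 entries of
  a partition; difference kernels accept them. Family evaluation rejects
  negative class counts; comparisons report an exact-zero difference as a
  tie, never as dominance.
* **Comparison.** `compare_families` evaluates both families exactly per
  n and issues a dominance verdict only when the sign is strict at every
  n. For IRDIF the OT/IS difference is 27n² − 9n, positive for all n ≥ 1:
  the icosahedral sheet is the more irregular family. The package makes
  no claim beyond per-index verdicts.

## Reference values and discrepancies

`irrnet.reference` stores the literature-printed index tables (n = 1..5)
and closed-form coefficients for OT_n and IS_n verbatim, including their
flaws. The discrepancy report compares every printed cell against the
definition-faithful exact value and classifies deviations:

* **rounding** — the exact value is an integer but the printed cell
  carries decimal noise (the IS IRLA row: 32.000016 vs exact 32; caused
  by multiplying class counts by a rounded 2/3);
* **convention** — the printed cell equals half the defined value, i.e. a
  dropped prefactor of 2 (the entire IS IRGA row; the OT table uses the
  full prefactor, and the published IS closed form for IRGA matches
  neither reading, so no IRGA reference closed form is kept for IS);
* **typo** — neither reading fits (one cell: IS IRB at n = 4 prints
  720.736120 where the published closed form for that same row gives
  720.60612 and the exact value is 720.606078).

Irrational cells within 1e-4 relative of the exact value are treated as
faithful renderings (the printed tables propagate 6-decimal coefficient
rounding, worst ≈ 2·10⁻⁵ relative); under this rule the OT table has no
discrepancies. Flawed cells are never silently matched: table-reproduction
tests compare printed cells at 1e-4 relative, and cells the report flags
are pinned to the family's own closed form instead.

## Testing strategy and scope

Unit tests freeze hand-computed oracles (brute-force degree counts and
edge sums on constructed chains, kernel spot values); hypothesis property
tests (derandomised, ≤ 9-vertex random simple graphs) check the
route-equivalence, nonnegativity, AL = 2·IRRt, IRLA ≤ IRLU and IRF ≥ AL
invariants; every regular fixture (cycles, complete graphs, both solids)
must score exactly zero on all twelve indices. All problem sizes are
desk-scale (n ≤ 6 for constructions, n ≤ 5 for family grids) — the
quantities of interest are closed-form, so nothing is gained from larger n.

Known limitations: no directed graphs, multigraphs, weighted edges, or
3-D coordinates; sheet families exist only as partitions, so non-degree
invariants (distances, spectra) are out of reach for them; the synthetic
random fixtures exercise only small dense degree ranges and say nothing
about performance on very large sparse graphs.
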