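# Methods

## Data model

A `KPartiteGraph` stores string vertex labels (external), dense 0-based
integer indices (internal), a 1-based part index per vertex, and a
symmetric, irreflexive adjacency over indices.  Parts must be nonempty;
edges inside a part are rejected at construction (empty parts are a hard
error by design — the definition of a k-partite graph requires nonempty
partite sets, and silently accepting degenerate partitions would change
what "covers the partition" means).  Graphs are immutable after
construction; adding the intrapartite edges (`complete_intrapartite`)
returns a copy flagged `completed`, adding exactly Σ_i C(|V_i|, 2) edges.
Enumeration engines convert adjacency to integer bitmasks, so set
intersection, difference and popcount are single big-int operations.

## Enumeration (`mmce`)

Maximal k-partite cliques of G are the maximal cliques of the completed
graph G′ that cover the partition.  `mmce` is the pivoted Bron–Kerbosch
recursion on G′:

* state (R, P, X): R the current clique, P the candidates adjacent to all
  of R, X the already-handled vertices adjacent to all of R; a maximal
  clique is reached exactly when P = X = ∅;
* pivot u ∈ P ∪ X maximizing |P ∩ N(u)|, recursing only on P \ N(u),
  which yields the O(3^(n/3)) bound;
* partition coverage is maintained incrementally (a membership array, a
  per-part counter vector C and a covered-part count t, updated in O(1)
  on each push/pop), so the emission check `t ≥ min_cover` is a single
  comparison and the coverage bookkeeping never affects the asymptotics;
* `min_cover = k` (default) is the strict problem; `min_cover < k` emits
  maximal subspace clusters of at least `min_cover` dimensions.  The
  coverage test is applied only at emission, never as mid-recursion
  pruning, keeping the recursion tree identical to plain Bron–Kerbosch.

Determinism: pivot ties break toward the smallest internal index and
candidates are branched in ascending index order, so emission order is a
pure function of the input.  Cliques are yielded as discovered
(reporting, not storing); `mode="count_only"` counts without
materializing clique objects.  Recursion depth is bounded by n, far below
interpreter limits for every size this package targets (n ≤ ~60).

`vertex_maximum` / `edge_maximum` scan the full enumeration — exact but
exponential, which is unavoidable: the decision problem is NP-complete
for k ≥ 3 (see Hardness).  Adding a vertex to a covering clique never
decreases either measure, so the optimum over *maximal* cliques is the
global optimum.  Ties prefer the lexicographically least canonical form.

## Extremal families (`constructions`)

* `construct_k3(p)`: balanced complete tripartite on n = 3p vertices
  minus p disjoint triangles {x_i, y_i, z_i}.  Maximal tricliques
  correspond bijectively to ordered tripartitions of {1..p} into three
  labeled nonempty blocks, so their number is exactly
  3^p − 3(2^p − 1) (`k3_count`; `k3_double_sum` evaluates the equivalent
  double sum Σ_a Σ_b C(p,a)·C(p−a,b) directly).
* `construct_cyclic(k, p)` (k ≥ 4): balanced complete k-partite on
  n = 3pk vertices minus kp disjoint triangles; each part is split into
  thirds and triangle family j takes positions i, i+p, i+2p in parts j,
  j+1, j+2 (cyclically).  The k = 4 and k = 5 cases use the same code
  path as k ≥ 6 because their explicit triangle lists follow the
  identical cyclic pattern; unit tests pin both lists against the
  spelled-out four- and five-family patterns to guard the index
  arithmetic.  The count of maximal k-partite cliques is bounded below by
  (3^p − 3(2^p − 1))^k (`general_lower_bound`), attained by cliques
  touching every third of every part; only the finite bound is asserted —
  no asymptotic (limit) statements are tested.
* `random_kpartite(k, sizes, density, seed)`: independent-edge model —
  every interpartite pair is an edge with the given probability under a
  dedicated `random.Random(seed)`.  This is purely a test fixture: real
  association networks have degree heterogeneity and transitivity this
  model lacks, so oracle-equivalence results on it certify algorithmic
  correctness, not performance or statistical behavior on real data.
  Test shapes keep n ≤ 12 so the 2^n subset oracle stays exact and fast;
  densities 0.3/0.6/0.9 cover sparse through near-complete regimes.

## Hardness gadget (`hardness`)

For a monotone one-in-three-SAT instance with m clauses (three distinct
variables per clause, clauses pairwise distinct as sets — repeated
variables inside a clause are rejected because the cross-clause
matching-literal rules are defined only between different clauses), the
reduction graph has nine vertices x_{i,1..3}, y_{i,1..3}, z_{i,1..3} and
12 fixed edges per clause, plus 6 edges per unordered matching literal
pair l_{i,s} = l_{j,t} (a two-variable overlap between two clauses counts
as two pairs, hence 12 edges).  The instance is satisfiable with exactly
one true literal per clause iff the gadget has an independent set of size
4m touching all three parts, iff the interpartite complement has a
covering clique of size 4m; adding k − 3 universal single-vertex parts
shifts the optimum by exactly k − 3.

`max_covering_independent_set` needs the largest independent set meeting
every part.  Any maximum covering independent set extends to a *maximal*
independent set that still covers (supersets cover at least as much and
cannot shrink), so searching the maximal independent sets is exact.
These are enumerated as the maximal cliques of the plain graph complement
via `networkx.find_cliques` — deliberately an implementation independent
of this package's own engine, so `reduction_holds` genuinely
cross-validates two code paths (networkx on the independent-set side,
`mmce` on the complement-clique side) against the exhaustive assignment
search.  Guard: n ≤ 45 (maximal independent sets, not 2^n subsets, are
enumerated, so sparse instances of a few clauses stay fast); the
assignment search is guarded at 20 variables.

## Set-intersection graphs (`set_intersection`)

`build_si_graph` materializes the k-partite graph of a `SetSystem`
(universe S; per part 2..k an ordered family of named nonempty subsets —
duplicates are distinct vertices and are never merged).  `compress` fuses
all subset vertices into one side of a bipartite graph whose edges are
the element-membership pairs; singleton neighborhoods are preserved, and
subset–subset edges are dropped (they are recoverable: two subsets
intersect iff they share a singleton neighbor).

`enumerate_maximal_bicliques` runs the package's Bron–Kerbosch engine on
the intrapartite-completed bipartite compression and keeps maximal
cliques covering both sides — the k = 2 instance of the completion
correspondence.  This honors the enumeration contract of the published
bipartite-specialized algorithms without re-implementing their search
tree; a specialized enumerator could be swapped in behind the same
interface.  `mmce_si` maps each biclique back to the original vertices
and reports it iff all k original parts are represented; its output set
provably equals direct `mmce` on the full graph, and the clique count is
bounded by the biclique count of the compression (both asserted in
tests).

`msigr` tries each part P in increasing index order and accepts the
first where every cross-part pair outside P is adjacent exactly when it
has a common neighbor in P.  One strengthening beyond the bare
characterization: every vertex outside P must have at least one neighbor
in P.  Subset vertices represent *nonempty* subsets, and admitting
empty-neighborhood vertices would make `recover_sets` emit empty subsets
on accepted inputs; a graph failing only this condition is reported
not-a-set-intersection-graph.  `recover_sets` assigns each outside
vertex its P-neighborhood as its subset; rebuilding the graph from the
recovered system reproduces the input up to renumbering P as part 1
(property-tested over random systems).

The text formats (.kpg for graphs, .sets for set systems, a
positive-literal DIMACS dialect for formulas) are line-oriented,
whitespace-separated, with `#` comments; canonical writers sort labels
so serialization is byte-stable.

## Problem sizes in the test suite

Chosen so every result is exact and the whole suite stays quick: subset
oracles at n ≤ 12 (4096 subsets; 450 random graphs across three shapes
and three densities); extremal counts through p = 6 (n = 18, 729 maximal
cliques); cyclic-family counts at (k,p) = (4,3) and (5,2) (n = 36 and 30;
531441 and 59049 maximal cliques of the completed graphs, counted without
listing); the full 175-instance reduction family (m ≤ 3 over 5
variables, gadgets up to 27 vertices, extensions to k = 4, 5); 50-seed
property suites for the set-intersection equivalences.

## Known limitations

* No degeneracy-ordering or P∪X-minimizing pivot variants; the single
  line-7 pivot rule only.  These are extension points, not claims.
* No polynomial-delay guarantee — only the global O(3^(n/3)) bound.
* General (unpartitioned) graph input is out of scope: deciding
  k-partiteness is itself NP-complete for k ≥ 3, so the partition is
  required input everywhere.
* No weighted edges, directed edges, or multigraphs.
* The optional coverage-based pruning idea (discarding branches where
  R ∪ P cannot reach `min_cover` parts) is not implemented; the
  enumeration stays faithful to the emission-time check.
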