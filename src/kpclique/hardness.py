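"""One-in-three-SAT hardness gadget for vertex-maximum k-partite clique.

Finding a vertex-maximum k-partite clique is NP-hard for every k >= 3.
The reduction goes through monotone one-in-three-SAT (no negated literals;
a satisfying assignment must make exactly one literal true per clause):

* Each clause C_i contributes nine vertices x_{i,1..3}, y_{i,1..3},
  z_{i,1..3} and 12 intra-gadget edges; each unordered cross-clause pair
  of matching literals l_{i,s} = l_{j,t} contributes 6 more edges.  The
  resulting graph is balanced 3-partite (parts = the x-, y- and
  z-vertices) with 9m vertices and 12m + 6d edges, d the number of
  matching literal pairs.
* The instance is one-in-three satisfiable iff the gadget graph has an
  independent set of size 4m touching all three parts, iff the
  interpartite complement has a 3-partite clique of size 4m.
* For k > 3, adding k - 3 universal vertices (each its own part) shifts
  the covering-clique optimum by exactly k - 3.

This module builds the gadget, the interpartite complement and the
k-extension, and provides exhaustive small-instance oracles so the
equivalence can be machine-checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, TextIO

import networkx as nx

from .core import KPartiteError, KPartiteGraph, ParseError, build_graph
from .enumeration import TooLargeError, mmce

__all__ = [
    "InvalidInstanceError",
    "OneInThreeInstance",
    "make_instance",
    "matching_literal_pairs",
    "build_gadget",
    "interpartite_complement",
    "extend_to_k",
    "one_in_three_sat_brute",
    "max_covering_independent_set",
    "reduction_holds",
    "read_cnf",
]


class InvalidInstanceError(KPartiteError):
    """Malformed monotone one-in-three instance."""


@dataclass(frozen=True)
class OneInThreeInstance:
    """m distinct monotone 3-literal clauses over positive variables.

    Each clause is a triple of three distinct variable labels; clauses
    must be pairwise distinct as sets.  (Repeated variables within a
    clause are disallowed: the cross-clause matching-literal machinery is
    defined only between different clauses.)
    """

    clauses: tuple[tuple[str, str, str], ...]

    @property
    def m(self) -> int:
        return len(self.clauses)

    @property
    def variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for clause in self.clauses:
            for v in clause:
                seen.setdefault(v)
        return tuple(sorted(seen))

    @property
    def d(self) -> int:
        """Number of unordered cross-clause matching-literal pairs; two
        clauses sharing two variables contribute 2."""
        return len(matching_literal_pairs(self))


def make_instance(clauses: Iterable[Iterable[str]]) -> OneInThreeInstance:
    """Validate and build a monotone one-in-three instance."""
    rows: list[tuple[str, str, str]] = []
    for clause in clauses:
        lits = tuple(clause)
        if len(lits) != 3:
            raise InvalidInstanceError(f"clause {lits!r} does not have 3 literals")
        if any(not isinstance(v, str) or not v for v in lits):
            raise InvalidInstanceError(f"bad variable label in clause {lits!r}")
        if any(v.startswith("-") for v in lits):
            raise InvalidInstanceError(
                f"negated literal in clause {lits!r}: only monotone instances allowed"
            )
        if len(set(lits)) != 3:
            raise InvalidInstanceError(f"repeated variable in clause {lits!r}")
        rows.append(lits)  # type: ignore[arg-type]
    sets = [frozenset(c) for c in rows]
    if len(set(sets)) != len(sets):
        raise InvalidInstanceError("duplicate clauses (equal as sets)")
    return OneInThreeInstance(clauses=tuple(rows))


def matching_literal_pairs(
    e: OneInThreeInstance,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All ((i, s), (j, t)) with i < j and l_{i,s} = l_{j,t}; clause
    indices 1-based, literal positions in 1..3."""
    pairs = []
    for i in range(1, e.m + 1):
        for j in range(i + 1, e.m + 1):
            for s in range(1, 4):
                for t in range(1, 4):
                    if e.clauses[i - 1][s - 1] == e.clauses[j - 1][t - 1]:
                        pairs.append(((i, s), (j, t)))
    return pairs


def _x(i: int, s: int) -> str:
    return f"x{i}_{s}"


def _y(i: int, s: int) -> str:
    return f"y{i}_{s}"


def _z(i: int, s: int) -> str:
    return f"z{i}_{s}"


def build_gadget(e: OneInThreeInstance) -> KPartiteGraph:
    """The 3-partite reduction graph: 9m vertices, 12m + 6d edges.

    Parts are the x-, y- and z-vertices.  Per clause i the 12 intra-gadget
    edges are (x_s, y_s) for each s, (x_s, z_h) for each s != h, and
    (y_s, z_s) for each s.  Per matching literal pair l_{i,s} = l_{j,t}
    the 6 cross edges are (x_{i,s}, z_{j,h}) for h != t, (x_{j,t},
    z_{i,h}) for h != s, (y_{i,s}, z_{j,t}) and (y_{j,t}, z_{i,s}).
    """
    if e.m < 1:
        raise InvalidInstanceError("need at least one clause")
    xs = [_x(i, s) for i in range(1, e.m + 1) for s in range(1, 4)]
    ys = [_y(i, s) for i in range(1, e.m + 1) for s in range(1, 4)]
    zs = [_z(i, s) for i in range(1, e.m + 1) for s in range(1, 4)]
    edges: list[tuple[str, str]] = []
    for i in range(1, e.m + 1):
        for s in range(1, 4):
            edges.append((_x(i, s), _y(i, s)))
            edges.append((_y(i, s), _z(i, s)))
            for h in range(1, 4):
                if h != s:
                    edges.append((_x(i, s), _z(i, h)))
    for (i, s), (j, t) in matching_literal_pairs(e):
        for h in range(1, 4):
            if h != t:
                edges.append((_x(i, s), _z(j, h)))
            if h != s:
                edges.append((_x(j, t), _z(i, h)))
        edges.append((_y(i, s), _z(j, t)))
        edges.append((_y(j, t), _z(i, s)))
    return build_graph([xs, ys, zs], edges)


def interpartite_complement(g: KPartiteGraph) -> KPartiteGraph:
    """Complement only the cross-part pairs; the partition is unchanged.

    An involution; a set covering all parts is independent in g iff it is
    a k-partite clique (cross-part pairs all adjacent) of the complement.
    """
    parts = [list(g.parts[p]) for p in range(1, g.k + 1)]
    edges = []
    for a in range(g.k):
        for b in range(a + 1, g.k):
            for u in parts[a]:
                for v in parts[b]:
                    if not g.has_edge(u, v):
                        edges.append((u, v))
    return build_graph(parts, edges)


def extend_to_k(g3: KPartiteGraph, k: int) -> KPartiteGraph:
    """Extend to k parts by adding k - 3 universal vertices, each its own
    part; covering-clique sizes shift by exactly k - 3.  Identity at
    k = 3.  The new labels are u4..uk (must not collide with existing
    labels)."""
    if k < 3:
        raise KPartiteError(f"k must be >= 3, got {k}")
    if g3.k != 3:
        raise KPartiteError(f"input must be 3-partite, got k = {g3.k}")
    if k == 3:
        return g3
    parts = [list(g3.parts[p]) for p in range(1, 4)]
    edges = list(g3.edges())
    old = [v for part in parts for v in part]
    new = [f"u{q}" for q in range(4, k + 1)]
    for i, u in enumerate(new):
        for v in old + new[:i]:
            edges.append((u, v))
        parts.append([u])
    return build_graph(parts, edges)


def one_in_three_sat_brute(e: OneInThreeInstance) -> dict[str, bool] | None:
    """Exhaustive search for an assignment with exactly one true literal
    per clause; None if unsatisfiable.  Guarded to <= 20 variables."""
    variables = e.variables
    if len(variables) > 20:
        raise TooLargeError(f"brute force limited to 20 variables, got {len(variables)}")
    for bits in product((False, True), repeat=len(variables)):
        assignment = dict(zip(variables, bits))
        if all(sum(assignment[v] for v in clause) == 1 for clause in e.clauses):
            return assignment
    return None


def max_covering_independent_set(g: KPartiteGraph) -> int:
    """Maximum size of an independent set containing at least one vertex
    of every part; 0 if none exists.  Guarded to n <= 45 (maximal
    independent sets are enumerated, not all 2^n subsets, so moderate n
    stays tractable on sparse inputs).

    Every maximum covering independent set extends to a maximal
    independent set that still covers (supersets cover at least as much),
    so the optimum is found among maximal independent sets.  Those are
    enumerated as the maximal cliques of the plain graph complement via
    networkx, which serves as an implementation independent of this
    package's own clique engine.
    """
    if g.n > 45:
        raise TooLargeError(f"independent-set search limited to n <= 45, got n = {g.n}")
    h = nx.Graph()
    h.add_nodes_from(g.vertices)
    h.add_edges_from(g.edges())
    comp = nx.complement(h)
    best = 0
    k = g.k
    for clique in nx.find_cliques(comp):
        if len(clique) > best and len({g.part_of_label(v) for v in clique}) == k:
            best = len(clique)
    return best


def reduction_holds(e: OneInThreeInstance) -> bool:
    """Machine-check the reduction on one instance.

    Verifies that one-in-three satisfiability (by exhaustive assignment
    search) coincides with the gadget graph having a covering independent
    set of size 4m, and cross-checks the independent-set optimum against
    the covering-clique optimum of the interpartite complement computed
    with this package's own enumerator.
    """
    sat = one_in_three_sat_brute(e) is not None
    g = build_gadget(e)
    mis = max_covering_independent_set(g)
    comp = interpartite_complement(g)
    best_clique = max((len(c) for c in mmce(comp, min_cover=3)), default=0)
    if best_clique != mis:
        return False
    return (mis == 4 * e.m) == sat


# ---------------------------------------------------------------------------
# DIMACS-style CNF input, restricted to three positive literals per clause
# ---------------------------------------------------------------------------


def read_cnf(stream: TextIO) -> OneInThreeInstance:
    """Parse a DIMACS CNF dialect: 'c' comments, a 'p cnf V C' header, then
    clause lines of three positive literals terminated by 0.  Any negative
    literal is rejected (the reduction handles only monotone instances)."""
    n_vars: int | None = None
    clauses: list[tuple[str, str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("c"):
            continue
        if line.startswith("p"):
            tokens = line.split()
            if len(tokens) != 4 or tokens[1] != "cnf":
                raise ParseError(f"bad problem line {line!r}", lineno)
            n_vars = int(tokens[2])
            continue
        if n_vars is None:
            raise ParseError("clause before 'p cnf' header", lineno)
        tokens = line.split()
        if tokens[-1] != "0":
            raise ParseError("clause line must end with 0", lineno)
        lits = []
        for tok in tokens[:-1]:
            try:
                lit = int(tok)
            except ValueError:
                raise ParseError(f"bad literal {tok!r}", lineno) from None
            if lit < 0:
                raise InvalidInstanceError(
                    f"line {lineno}: negative literal {lit}; "
                    "only monotone (positive-literal) instances are supported"
                )
            if lit == 0 or lit > n_vars:
                raise ParseError(f"literal {lit} out of range 1..{n_vars}", lineno)
            lits.append(lit)
        if len(lits) != 3:
            raise InvalidInstanceError(
                f"line {lineno}: clause must have exactly 3 literals, got {len(lits)}"
            )
        clauses.append(tuple(str(v) for v in lits))  # type: ignore[arg-type]
    return make_instance(clauses)
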