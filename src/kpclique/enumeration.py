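"""Maximal k-partite clique enumeration (MMCE).

The enumerator is the classic Bron–Kerbosch recursion with pivoting, run
on the intrapartite-completed graph, with an O(1) partition-coverage check
applied at each emission: a maximal clique of the completed graph is
reported iff it covers at least ``min_cover`` parts.  With ``min_cover``
equal to k this enumerates exactly the maximal k-partite cliques; smaller
values give the subspace-cluster variant in which only some of the parts
need be represented.

The recursion state at every call consists of the current clique R, the
candidate set P (vertices adjacent to all of R that may still extend it)
and the excluded set X (vertices adjacent to all of R already handled on
another branch); a clique is maximal exactly when P and X are both empty.
The pivot u is chosen from P ∪ X to maximize |P ∩ N(u)|, which bounds the
whole search by O(3^(n/3)).  Vertex sets are integer bitmasks internally,
so each recursion step costs a handful of word operations per vertex.

Determinism: pivot ties are broken by smallest internal vertex index and
candidates are branched in ascending index order, so the emission order is
a pure function of the input graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

from .core import (
    Clique,
    KPartiteError,
    KPartiteGraph,
    complete_intrapartite,
)

__all__ = [
    "EmptyCandidatesError",
    "BadCoverBoundError",
    "TooLargeError",
    "NoCoveringCliqueError",
    "EnumerationState",
    "select_pivot",
    "mmce",
    "brute_force_enumerate",
    "clique_edge_count",
    "vertex_maximum",
    "edge_maximum",
]


class EmptyCandidatesError(KPartiteError):
    """Pivot selection requested with P and X both empty."""


class BadCoverBoundError(KPartiteError):
    """min_cover outside 1..k."""


class TooLargeError(KPartiteError):
    """Brute-force guard exceeded."""


class NoCoveringCliqueError(KPartiteError):
    """The graph has no clique covering all k parts."""


@dataclass
class EnumerationState:
    """A Bron–Kerbosch recursion frame, in label form (for inspection)."""

    R: frozenset[str]
    P: frozenset[str]
    X: frozenset[str]


def select_pivot(state: EnumerationState, g: KPartiteGraph) -> str:
    """The pivot rule: u in P ∪ X maximizing |P ∩ N(u)|.

    Ties are broken by smallest internal vertex index.  ``g`` should be the
    completed graph (the one the recursion walks).
    """
    gc = g if g.completed else complete_intrapartite(g)
    candidates = state.P | state.X
    if not candidates:
        raise EmptyCandidatesError("P and X are both empty")
    best_label: str | None = None
    best_score = -1
    best_index = -1
    for label in candidates:
        i = gc.index[label]
        score = len(state.P & gc.neighbors(label))
        if score > best_score or (score == best_score and i < best_index):
            best_label, best_score, best_index = label, score, i
    assert best_label is not None
    return best_label


def _enumerate_masks(
    masks: list[int],
    part_of: tuple[int, ...],
    k: int,
    min_cover: int,
    n: int,
) -> Iterator[tuple[int, ...]]:
    """Core pivoted Bron–Kerbosch over bitmask vertex sets.

    Yields index tuples of maximal cliques (of the graph described by
    ``masks``) covering >= ``min_cover`` parts.  Coverage is maintained
    incrementally with per-part counters so the emission check is a single
    comparison.
    """
    counts = [0] * (k + 1)
    covered = 0
    R: list[int] = []

    def rec(P: int, X: int) -> Iterator[tuple[int, ...]]:
        nonlocal covered
        if P == 0 and X == 0:
            if covered >= min_cover:
                yield tuple(R)
            return
        # pivot: maximize |P & N(u)| over u in P | X, smallest index wins ties
        both = P | X
        best_u = -1
        best_c = -1
        m = both
        while m:
            b = m & -m
            u = b.bit_length() - 1
            m ^= b
            c = (P & masks[u]).bit_count()
            if c > best_c:
                best_c, best_u = c, u
        cand = P & ~masks[best_u]
        while cand:
            b = cand & -cand
            v = b.bit_length() - 1
            cand ^= b
            R.append(v)
            p = part_of[v]
            counts[p] += 1
            if counts[p] == 1:
                covered += 1
            yield from rec(P & masks[v], X & masks[v])
            counts[p] -= 1
            if counts[p] == 0:
                covered -= 1
            R.pop()
            P &= ~b
            X |= b

    yield from rec((1 << n) - 1, 0)


def mmce(
    g: KPartiteGraph,
    min_cover: int | None = None,
    mode: str = "all",
):
    """Enumerate maximal cliques of the completed graph covering parts.

    Parameters
    ----------
    g : KPartiteGraph
        Input graph; completed internally if needed.
    min_cover : int, optional
        Minimum number of parts a reported clique must cover.  Defaults to
        k (the strict k-partite clique problem); values below k enumerate
        maximal subspace clusters of at least ``min_cover`` dimensions.
    mode : {"all", "count_only"}
        "all" returns a lazy iterator of :class:`Clique`; "count_only"
        returns the count without materializing cliques (reporting, not
        listing).

    Each qualifying clique is emitted exactly once; nothing is stored
    beyond the O(n)-per-level recursion state.
    """
    if min_cover is None:
        min_cover = g.k
    if not 1 <= min_cover <= g.k:
        raise BadCoverBoundError(f"min_cover must be in 1..{g.k}, got {min_cover}")
    if mode not in ("all", "count_only"):
        raise ValueError(f"mode must be 'all' or 'count_only', got {mode!r}")

    gc = g if g.completed else complete_intrapartite(g)
    masks = gc.adjacency_masks()
    stream = _enumerate_masks(masks, gc.part_of, gc.k, min_cover, gc.n)

    if mode == "count_only":
        return sum(1 for _ in stream)

    def cliques() -> Iterator[Clique]:
        for idxs in stream:
            yield Clique.from_members(gc, (gc.vertices[i] for i in idxs))

    return cliques()


def brute_force_enumerate(g: KPartiteGraph, min_cover: int | None = None) -> set[Clique]:
    """Testing oracle: examine all 2^n vertex subsets.

    Keeps every subset that is a maximal clique of the completed graph and
    covers >= ``min_cover`` parts.  Guarded to n <= 20.
    """
    if g.n > 20:
        raise TooLargeError(f"brute force limited to n <= 20, got n = {g.n}")
    if min_cover is None:
        min_cover = g.k
    if not 1 <= min_cover <= g.k:
        raise BadCoverBoundError(f"min_cover must be in 1..{g.k}, got {min_cover}")
    gc = g if g.completed else complete_intrapartite(g)
    masks = gc.adjacency_masks()
    n = gc.n
    out: set[Clique] = set()
    for subset in range(1, 1 << n):
        # clique check: each member adjacent to all the others
        is_clique = True
        m = subset
        while m:
            b = m & -m
            v = b.bit_length() - 1
            m ^= b
            if (subset & ~b) & ~masks[v]:
                is_clique = False
                break
        if not is_clique:
            continue
        # maximality: no outside vertex adjacent to the whole subset
        maximal = True
        for w in range(n):
            if subset >> w & 1:
                continue
            if subset & ~masks[w] == 0:
                maximal = False
                break
        if not maximal:
            continue
        parts = {gc.part_of[v] for v in range(n) if subset >> v & 1}
        if len(parts) >= min_cover:
            out.add(
                Clique.from_members(gc, (gc.vertices[v] for v in range(n) if subset >> v & 1))
            )
    return out


def clique_edge_count(c: Clique) -> int:
    """Induced interpartite edge count: sum over part pairs of the product
    of part sizes (the sum-of-products size measure for edge-maximum)."""
    sizes = [len(v) for v in c.by_part.values()]
    return sum(a * b for a, b in combinations(sizes, 2))


def _best_clique(g: KPartiteGraph, key) -> Clique:
    best: Clique | None = None
    best_key = None
    for c in mmce(g, min_cover=g.k):
        k_val = key(c)
        # maximize the measure; break ties toward the lexicographically
        # least canonical form
        cand = (-k_val, c.canonical())
        if best is None or cand < best_key:
            best, best_key = c, cand
    if best is None:
        raise NoCoveringCliqueError("no clique covers all parts")
    return best


def vertex_maximum(g: KPartiteGraph) -> Clique:
    """A covering maximal clique with the most vertices.

    NP-hard for k >= 3, so this is exhaustive over the maximal cliques.
    """
    return _best_clique(g, len)


def edge_maximum(g: KPartiteGraph) -> Clique:
    """A covering maximal clique maximizing the sum-of-products edge count."""
    return _best_clique(g, clique_edge_count)
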