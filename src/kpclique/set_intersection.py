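"""k-partite set-intersection graphs: construction, bipartite compression,
clique enumeration via maximal bicliques, recognition, and set recovery.

A k-partite set-intersection graph has one part of "singleton" vertices,
one per element of a finite universe S, and k-1 parts of "subset" vertices
representing (not necessarily distinct) nonempty subsets of S; cross-part
vertices are adjacent iff the sets they represent intersect.  Such graphs
model, e.g., multiple ontologies annotated to a common gene set, each
ontology a part of terms (subsets of the gene universe).

Because two subset vertices intersect exactly when they share a singleton
neighbor, all subset vertices can be fused into a single side of a
bipartite graph without losing information: maximal k-partite cliques of
the original graph are precisely the maximal bicliques of the compression
whose pre-images cover all k parts.  Enumerating maximal bicliques costs
O(2^(n/2)) rather than O(3^(n/3)), so this route is asymptotically faster
than general-purpose enumeration.

Recognition: a k-partite graph is a set-intersection graph iff it has a
part P such that every cross-part pair outside P is adjacent exactly when
it has a common neighbor in P (and, so that subset vertices are nonempty,
every vertex outside P has at least one neighbor in P).  The O(k n^3)
scan over candidate parts is implemented by ``msigr``; ``recover_sets``
reads a witness set system back off an accepted part.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from .core import (
    Clique,
    KPartiteError,
    KPartiteGraph,
    ParseError,
    build_graph,
)
from .enumeration import mmce

__all__ = [
    "EmptySubsetError",
    "NotSIInputError",
    "NotRecognizedError",
    "SetSystem",
    "make_set_system",
    "BipartiteCompression",
    "build_si_graph",
    "compress",
    "enumerate_maximal_bicliques",
    "mmce_si",
    "msigr",
    "recover_sets",
    "random_set_system",
    "read_sets",
    "write_sets",
]


class EmptySubsetError(KPartiteError):
    """A subset vertex must represent a nonempty subset of the universe."""


class NotSIInputError(KPartiteError):
    """Compression requested on a graph that is not a set-intersection graph."""


class NotRecognizedError(KPartiteError):
    """The chosen part fails the set-intersection characterization."""


@dataclass(frozen=True)
class SetSystem:
    """A universe S plus, for each part 2..k, an ordered family of named
    nonempty subsets of S.  ``families[i]`` holds part i+2's subsets as
    (name, members) pairs; duplicate subsets are distinct vertices."""

    universe: tuple[str, ...]
    families: tuple[tuple[tuple[str, frozenset[str]], ...], ...]

    @property
    def k(self) -> int:
        return len(self.families) + 1

    def family(self, part: int) -> tuple[tuple[str, frozenset[str]], ...]:
        """The (name, members) list of part ``part`` (2..k)."""
        return self.families[part - 2]


def make_set_system(
    universe: Sequence[str],
    parts: Sequence[Sequence],
) -> SetSystem:
    """Validate and build a :class:`SetSystem`.

    ``parts`` lists, for each part 2..k in order, its subsets.  A subset is
    either an iterable of element labels or an explicit ``(name, members)``
    2-tuple (any 2-tuple whose first item is a string is read as the named
    form, so give unnamed subsets as lists, sets, or strings of element
    characters); unnamed subsets are labeled ``{e1,e2,...}`` with elements sorted,
    and repeated unnamed subsets get ``#2``, ``#3``... suffixes so vertex
    labels stay unique.
    """
    universe = tuple(universe)
    if len(set(universe)) != len(universe):
        raise KPartiteError("duplicate universe elements")
    if not universe:
        raise KPartiteError("universe must be nonempty")
    uset = set(universe)
    seen_names: dict[str, int] = {}
    families = []
    for fam in parts:
        rows = []
        for entry in fam:
            if (
                isinstance(entry, tuple)
                and len(entry) == 2
                and isinstance(entry[0], str)
                and isinstance(entry[1], (list, tuple, set, frozenset, str))
            ):
                name, members = entry[0], frozenset(entry[1])
            else:
                members = frozenset(entry)
                name = "{" + ",".join(sorted(members)) + "}"
            if not members:
                raise EmptySubsetError("empty subset vertex")
            if not members <= uset:
                raise KPartiteError(
                    f"subset {sorted(members)} not contained in the universe"
                )
            count = seen_names.get(name, 0)
            seen_names[name] = count + 1
            if count:
                name = f"{name}#{count + 1}"
            rows.append((name, members))
        families.append(tuple(rows))
    if not families:
        raise KPartiteError("need at least one subset part (k >= 2)")
    return SetSystem(universe=universe, families=tuple(families))


@dataclass(frozen=True)
class BipartiteCompression:
    """The bipartite form of a set-intersection graph.

    ``graph`` has part 1 = singleton vertices and part 2 = all subset
    vertices fused together; its edges are the singleton-subset membership
    pairs, so every singleton's neighborhood is identical to the original
    graph's (subset-subset edges are dropped).  ``original_part_of`` maps
    each vertex label back to its part in the k-partite graph.
    """

    graph: KPartiteGraph
    original_part_of: Mapping[str, int]
    system: SetSystem


def build_si_graph(sys: SetSystem) -> KPartiteGraph:
    """Materialize the k-partite set-intersection graph of a set system.

    Part 1 holds one singleton vertex per universe element; parts 2..k hold
    the subset vertices; cross-part vertices are adjacent iff their sets
    intersect.
    """
    part_lists: list[list[str]] = [list(sys.universe)]
    rep: dict[str, frozenset[str]] = {e: frozenset((e,)) for e in sys.universe}
    for part in range(2, sys.k + 1):
        labels = []
        for name, members in sys.family(part):
            labels.append(name)
            rep[name] = members
        part_lists.append(labels)

    edges = []
    for a in range(len(part_lists)):
        for b in range(a + 1, len(part_lists)):
            for u in part_lists[a]:
                for v in part_lists[b]:
                    if rep[u] & rep[v]:
                        edges.append((u, v))
    return build_graph(part_lists, edges)


def compress(source: SetSystem | KPartiteGraph) -> BipartiteCompression:
    """Fuse all subset vertices into one side of a bipartite graph.

    Accepts a :class:`SetSystem` directly, or a k-partite graph, which is
    first recognized (``msigr``) and converted back to a set system; a
    graph failing recognition raises :class:`NotSIInputError`.
    """
    if isinstance(source, KPartiteGraph):
        part = msigr(source)
        if part is None:
            raise NotSIInputError("graph is not a k-partite set-intersection graph")
        sys = recover_sets(source, part)
    else:
        sys = source

    singleton_side = list(sys.universe)
    subset_side: list[str] = []
    original_part_of: dict[str, int] = {e: 1 for e in sys.universe}
    edges = []
    for part in range(2, sys.k + 1):
        for name, members in sys.family(part):
            subset_side.append(name)
            original_part_of[name] = part
            for e in members:
                edges.append((e, name))
    graph = build_graph([singleton_side, subset_side], edges)
    return BipartiteCompression(graph=graph, original_part_of=original_part_of, system=sys)


def enumerate_maximal_bicliques(b: BipartiteCompression) -> Iterator[frozenset[str]]:
    """All maximal bicliques of the compression with both sides nonempty.

    Implemented by running the pivoted Bron–Kerbosch engine on the
    intrapartite-completed bipartite graph and keeping the maximal cliques
    that cover both sides (the k = 2 instance of the completion
    correspondence); one-sided maximal cliques are suppressed, as they can
    never cover the original partition.
    """
    for clique in mmce(b.graph, min_cover=2):
        yield clique.members


def mmce_si(sys: SetSystem) -> Iterator[Clique]:
    """Enumerate maximal k-partite cliques of the set-intersection graph
    via its bipartite compression.

    Each maximal biclique is mapped back to the original vertices and
    reported iff every original part 1..k is represented; the output set
    equals ``mmce(build_si_graph(sys))``.
    """
    b = compress(sys)
    k = sys.k
    part_of = b.original_part_of
    for members in enumerate_maximal_bicliques(b):
        by_part: dict[int, set[str]] = {}
        for v in members:
            by_part.setdefault(part_of[v], set()).add(v)
        if len(by_part) == k:
            yield Clique(by_part, k)


def _part_accepts(g: KPartiteGraph, P: int, masks: list[int], pmask: int) -> bool:
    """The characterization test for candidate singleton part P."""
    n = g.n
    outside = [v for v in range(n) if g.part_of[v] != P]
    # nonempty-subset condition: every outside vertex has a neighbor in P
    for v in outside:
        if masks[v] & pmask == 0:
            return False
    for ai in range(len(outside)):
        u = outside[ai]
        for bi in range(ai + 1, len(outside)):
            v = outside[bi]
            if g.part_of[u] == g.part_of[v]:
                continue
            adjacent = masks[u] >> v & 1
            common = masks[u] & masks[v] & pmask
            if adjacent and not common:
                return False
            if not adjacent and common:
                return False
    return True


def msigr(g: KPartiteGraph) -> int | None:
    """Multipartite set-intersection graph recognition.

    Returns the smallest part index P such that every cross-part vertex
    pair outside P is adjacent exactly when it has a common neighbor in P,
    and every vertex outside P has a nonempty P-neighborhood; ``None`` if
    no part qualifies.  O(k n^3) via bitmask intersection tests.
    """
    masks = g.adjacency_masks()
    for P in range(1, g.k + 1):
        if _part_accepts(g, P, masks, g.part_mask(P)):
            return P
    return None


def recover_sets(g: KPartiteGraph, P: int) -> SetSystem:
    """Read a witness set system off an accepted singleton part.

    The universe is P's labels; each vertex outside P becomes a subset
    vertex (named by its own label) whose members are its P-neighbors.
    Parts other than P keep their relative order as parts 2..k.
    ``build_si_graph`` of the result reproduces g up to relabeling P as
    part 1.
    """
    masks = g.adjacency_masks()
    if not 1 <= P <= g.k:
        raise NotRecognizedError(f"part {P} out of range 1..{g.k}")
    if not _part_accepts(g, P, masks, g.part_mask(P)):
        raise NotRecognizedError(f"part {P} fails the set-intersection test")
    universe = list(g.parts[P])
    parts = []
    for q in range(1, g.k + 1):
        if q == P:
            continue
        fam = []
        for label in g.parts[q]:
            members = frozenset(v for v in g.neighbors(label) if g.part_of_label(v) == P)
            fam.append((label, members))
        parts.append(fam)
    return make_set_system(universe, parts)


def random_set_system(
    seed: int,
    k: int = 3,
    n_elements: int = 6,
    max_subsets_per_part: int = 4,
) -> SetSystem:
    """Seeded random set system (test fixture generator): k-1 subset parts
    with 1..max_subsets_per_part random nonempty subsets each."""
    rng = random.Random(seed)
    universe = [f"e{i}" for i in range(1, n_elements + 1)]
    parts = []
    for part in range(2, k + 1):
        fam = []
        for idx in range(1, rng.randint(1, max_subsets_per_part) + 1):
            size = rng.randint(1, n_elements)
            members = rng.sample(universe, size)
            fam.append((f"s{part}_{idx}", members))
        parts.append(fam)
    return make_set_system(universe, parts)


# ---------------------------------------------------------------------------
# .sets file format
#
#   sets 1
#   universe <label> <label> ...
#   part <i> <name>=<e1>,<e2>,... <name>=<...> ...      (for i = 2..k)
#
# '#' starts a comment; element labels may not contain ',' or whitespace.
# ---------------------------------------------------------------------------


def read_sets(stream: TextIO) -> SetSystem:
    """Parse a .sets stream."""
    lines = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            lines.append((lineno, line.split()))
    if not lines:
        raise ParseError("empty file, expected 'sets 1' header", 1)
    lineno, tokens = lines[0]
    if tokens != ["sets", "1"]:
        raise ParseError(f"expected 'sets 1' header, got {' '.join(tokens)!r}", lineno)
    if len(lines) < 2 or lines[1][1][0] != "universe":
        raise ParseError("expected 'universe <labels...>' line", lines[0][0] + 1)
    lineno, tokens = lines[1]
    universe = tokens[1:]
    if not universe:
        raise ParseError("universe must be nonempty", lineno)

    parts: list[list[tuple[str, list[str]]]] = []
    for lineno, tokens in lines[2:]:
        if tokens[0] != "part" or len(tokens) < 3:
            raise ParseError(
                f"expected 'part <i> <name>=<elems> ...', got {' '.join(tokens)!r}",
                lineno,
            )
        try:
            idx = int(tokens[1])
        except ValueError:
            raise ParseError(f"part index not an integer: {tokens[1]!r}", lineno) from None
        if idx != len(parts) + 2:
            raise ParseError(f"expected part {len(parts) + 2}, got part {idx}", lineno)
        fam = []
        for spec in tokens[2:]:
            if "=" not in spec:
                raise ParseError(f"expected <name>=<e1>,<e2>,..., got {spec!r}", lineno)
            name, elems = spec.split("=", 1)
            members = [e for e in elems.split(",") if e]
            if not members:
                raise EmptySubsetError(f"line {lineno}: subset {name!r} is empty")
            fam.append((name, members))
        parts.append(fam)
    return make_set_system(universe, parts)


def write_sets(sys: SetSystem, stream: TextIO) -> None:
    """Write a set system canonically (universe order kept, subset members
    sorted)."""
    stream.write("sets 1\n")
    stream.write("universe " + " ".join(sys.universe) + "\n")
    for part in range(2, sys.k + 1):
        specs = [
            f"{name}={','.join(sorted(members))}" for name, members in sys.family(part)
        ]
        stream.write(f"part {part} " + " ".join(specs) + "\n")
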