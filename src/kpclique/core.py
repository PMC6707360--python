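"""Core data model for k-partite graphs.

A k-partite graph is a simple undirected graph whose vertex set is split
into k >= 2 nonempty partite sets V_1..V_k with every edge running between
two different parts ("interpartite").  A k-partite clique is a vertex set
inducing a complete k-partite subgraph: every cross-part pair adjacent and
every part represented.  Enumeration works on the "completed" form of the
graph, in which all intrapartite edges have been added, because a maximal
k-partite clique of G is exactly a maximal clique of the completed graph
that covers the partition.

Vertices carry string labels externally and dense 0-based integer indices
internally; part indices are 1-based.  Graphs are treated as immutable
after construction; completion returns a copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "KPartiteError",
    "EmptyPartError",
    "DuplicateLabelError",
    "UnknownEndpointError",
    "IntrapartiteEdgeError",
    "AlreadyCompletedError",
    "UnknownVertexError",
    "NegativeCounterError",
    "ParseError",
    "KPartiteGraph",
    "Clique",
    "CoverageTracker",
    "build_graph",
    "complete_intrapartite",
    "is_maximal_kpartite_clique",
    "coverage_update",
    "read_kpg",
    "write_kpg",
]


class KPartiteError(Exception):
    """Base class for all errors raised by this package."""


class EmptyPartError(KPartiteError):
    """A partite set is empty (all parts must be nonempty)."""


class DuplicateLabelError(KPartiteError):
    """The same vertex label occurs more than once."""


class UnknownEndpointError(KPartiteError):
    """An edge references a label that is not a declared vertex."""


class IntrapartiteEdgeError(KPartiteError):
    """An input edge joins two vertices of the same part."""


class AlreadyCompletedError(KPartiteError):
    """Intrapartite completion requested on an already-completed graph."""


class UnknownVertexError(KPartiteError):
    """A vertex set references a label not present in the graph."""


class NegativeCounterError(KPartiteError):
    """A coverage counter would be decremented below zero."""


class ParseError(KPartiteError):
    """Malformed .kpg / .sets / .cnf input.

    Attributes
    ----------
    line : int
        1-based line number at which the problem was detected.
    """

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True, eq=False)
class KPartiteGraph:
    """An immutable k-partite graph.

    Parameters
    ----------
    k : int
        Number of partite sets (>= 2).
    vertices : tuple of str
        Vertex labels, in internal index order (index 0..n-1).
    part_of : tuple of int
        ``part_of[i]`` is the 1-based part index of vertex ``i``.
    adj : tuple of frozenset of int
        ``adj[i]`` is the set of internal indices adjacent to vertex ``i``.
    completed : bool
        True once all intrapartite edges have been added.
    """

    k: int
    vertices: tuple[str, ...]
    part_of: tuple[int, ...]
    adj: tuple[frozenset[int], ...]
    completed: bool = False

    # -- derived views ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.vertices)

    @cached_property
    def index(self) -> Mapping[str, int]:
        """Label -> internal index."""
        return {label: i for i, label in enumerate(self.vertices)}

    @cached_property
    def parts(self) -> Mapping[int, tuple[str, ...]]:
        """Part index -> labels of its vertices (internal order)."""
        out: dict[int, list[str]] = {i: [] for i in range(1, self.k + 1)}
        for label, p in zip(self.vertices, self.part_of):
            out[p].append(label)
        return {i: tuple(v) for i, v in out.items()}

    def part_of_label(self, label: str) -> int:
        try:
            return self.part_of[self.index[label]]
        except KeyError:
            raise UnknownVertexError(label) from None

    def neighbors(self, label: str) -> frozenset[str]:
        try:
            i = self.index[label]
        except KeyError:
            raise UnknownVertexError(label) from None
        return frozenset(self.vertices[j] for j in self.adj[i])

    def has_edge(self, a: str, b: str) -> bool:
        return self.index[b] in self.adj[self.index[a]]

    def edges(self) -> Iterator[tuple[str, str]]:
        """Each edge once, as a label pair sorted within the pair."""
        for i, nbrs in enumerate(self.adj):
            for j in nbrs:
                if i < j:
                    a, b = self.vertices[i], self.vertices[j]
                    yield (a, b) if a <= b else (b, a)

    def edge_count(self) -> int:
        return sum(len(s) for s in self.adj) // 2

    # -- bitset helpers for the enumeration engines -----------------------

    def adjacency_masks(self) -> list[int]:
        """Adjacency as integer bitmasks over internal indices."""
        masks = []
        for nbrs in self.adj:
            m = 0
            for j in nbrs:
                m |= 1 << j
            masks.append(m)
        return masks

    def part_mask(self, p: int) -> int:
        m = 0
        for i, pi in enumerate(self.part_of):
            if pi == p:
                m |= 1 << i
        return m

    # -- equality: semantic, independent of vertex storage order ----------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KPartiteGraph):
            return NotImplemented
        if self.k != other.k or self.completed != other.completed:
            return False
        if any(
            frozenset(self.parts[i]) != frozenset(other.parts[i])
            for i in range(1, self.k + 1)
        ):
            return False
        return frozenset(self.edges()) == frozenset(other.edges())

    __hash__ = None  # type: ignore[assignment]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        sizes = ",".join(str(len(self.parts[i])) for i in range(1, self.k + 1))
        return (
            f"KPartiteGraph(k={self.k}, sizes=({sizes}), "
            f"m={self.edge_count()}, completed={self.completed})"
        )


class Clique:
    """A reported maximal k-partite clique, grouped by part.

    Attributes
    ----------
    members : frozenset of str
        All member labels.
    by_part : dict int -> frozenset of str
        Nonempty parts only.
    covered : int
        Number of parts with at least one member.
    k : int
        Number of parts of the originating graph (for canonical printing).
    """

    __slots__ = ("members", "by_part", "covered", "k")

    def __init__(self, by_part: Mapping[int, Iterable[str]], k: int):
        grouped = {
            p: frozenset(v) for p, v in by_part.items() if len(frozenset(v)) > 0
        }
        self.by_part: dict[int, frozenset[str]] = grouped
        self.members: frozenset[str] = frozenset().union(*grouped.values()) if grouped else frozenset()
        self.covered: int = len(grouped)
        self.k = k

    @classmethod
    def from_members(cls, g: KPartiteGraph, labels: Iterable[str]) -> "Clique":
        by_part: dict[int, set[str]] = {}
        for label in labels:
            by_part.setdefault(g.part_of_label(label), set()).add(label)
        return cls(by_part, g.k)

    def canonical(self) -> str:
        """Parts in index order separated by ' | ', labels sorted."""
        return " | ".join(
            " ".join(sorted(self.by_part.get(p, ()))) for p in range(1, self.k + 1)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Clique):
            return NotImplemented
        return self.members == other.members

    def __hash__(self) -> int:
        return hash(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Clique({self.canonical()!r})"


class CoverageTracker:
    """O(1) partition-coverage bookkeeping for the current clique R.

    Keeps the part membership map ``M``, per-part counters ``C`` and the
    number ``t`` of currently covered parts.  A single comparison of ``t``
    against ``k`` decides whether R covers the partition.
    """

    __slots__ = ("M", "C", "t", "k")

    def __init__(self, g: KPartiteGraph):
        self.M: dict[str, int] = dict(zip(g.vertices, g.part_of))
        self.C: list[int] = [0] * (g.k + 1)
        self.t: int = 0
        self.k: int = g.k


def coverage_update(tr: CoverageTracker, v: str, direction: str) -> CoverageTracker:
    """Push or pop vertex ``v`` on the tracker; returns the tracker.

    ``t`` changes exactly when a per-part counter crosses 0 <-> 1.
    """
    p = tr.M[v]
    if direction == "push":
        tr.C[p] += 1
        if tr.C[p] == 1:
            tr.t += 1
    elif direction == "pop":
        if tr.C[p] <= 0:
            raise NegativeCounterError(f"part {p} counter already zero")
        tr.C[p] -= 1
        if tr.C[p] == 0:
            tr.t -= 1
    else:
        raise ValueError(f"direction must be 'push' or 'pop', got {direction!r}")
    return tr


def build_graph(
    part_lists: Sequence[Sequence[str]],
    edges: Iterable[tuple[str, str]],
) -> KPartiteGraph:
    """Validate and build a (non-completed) k-partite graph.

    ``part_lists`` gives the labels of parts 1..k in order; ``edges`` are
    interpartite label pairs.  Duplicate edges are merged silently.
    """
    k = len(part_lists)
    if k < 2:
        raise EmptyPartError(f"need at least 2 parts, got {k}")
    vertices: list[str] = []
    part_of: list[int] = []
    for p, labels in enumerate(part_lists, start=1):
        labels = list(labels)
        if not labels:
            raise EmptyPartError(f"part {p} is empty")
        for label in labels:
            vertices.append(label)
            part_of.append(p)
    index: dict[str, int] = {}
    for i, label in enumerate(vertices):
        if label in index:
            raise DuplicateLabelError(label)
        index[label] = i

    adj: list[set[int]] = [set() for _ in vertices]
    for a, b in edges:
        if a not in index:
            raise UnknownEndpointError(a)
        if b not in index:
            raise UnknownEndpointError(b)
        i, j = index[a], index[b]
        if i == j:
            raise IntrapartiteEdgeError(f"self-loop on {a!r}")
        if part_of[i] == part_of[j]:
            raise IntrapartiteEdgeError(
                f"edge ({a!r}, {b!r}) joins two vertices of part {part_of[i]}"
            )
        adj[i].add(j)
        adj[j].add(i)

    return KPartiteGraph(
        k=k,
        vertices=tuple(vertices),
        part_of=tuple(part_of),
        adj=tuple(frozenset(s) for s in adj),
        completed=False,
    )


def complete_intrapartite(g: KPartiteGraph) -> KPartiteGraph:
    """Return a copy of ``g`` with all intrapartite edges added.

    Adds exactly sum_i C(|V_i|, 2) edges; interpartite adjacency is
    unchanged.  Enumeration runs on this form (a maximal k-partite clique
    of g is a maximal clique of the completed graph covering all parts).
    """
    if g.completed:
        raise AlreadyCompletedError("graph is already intrapartite-completed")
    adj = [set(s) for s in g.adj]
    by_part: dict[int, list[int]] = {}
    for i, p in enumerate(g.part_of):
        by_part.setdefault(p, []).append(i)
    for members in by_part.values():
        for i, j in combinations(members, 2):
            adj[i].add(j)
            adj[j].add(i)
    return KPartiteGraph(
        k=g.k,
        vertices=g.vertices,
        part_of=g.part_of,
        adj=tuple(frozenset(s) for s in adj),
        completed=True,
    )


def is_maximal_kpartite_clique(g: KPartiteGraph, u: Iterable[str]) -> bool:
    """True iff ``u`` is a maximal k-partite clique of ``g``.

    Equivalently: ``u`` is a maximal clique of the intrapartite-completed
    graph that covers every part.
    """
    labels = set(u)
    try:
        idxs = {g.index[label] for label in labels}
    except KeyError as exc:
        raise UnknownVertexError(str(exc.args[0])) from None
    if not idxs:
        return False
    gc = g if g.completed else complete_intrapartite(g)
    # coverage
    if len({gc.part_of[i] for i in idxs}) != gc.k:
        return False
    # clique in the completed graph
    for i, j in combinations(idxs, 2):
        if j not in gc.adj[i]:
            return False
    # inextensibility
    for w in range(gc.n):
        if w in idxs:
            continue
        if idxs <= gc.adj[w]:
            return False
    return True


# ---------------------------------------------------------------------------
# .kpg file format
#
#   kpg 1
#   k <K>
#   part <i> <label> <label> ...     (for i = 1..K, in order)
#   edge <label> <label>             (zero or more)
#
# '#' starts a comment running to end of line; tokens are whitespace-split.
# ---------------------------------------------------------------------------


def _tokenized_lines(stream: TextIO) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        yield lineno, line.split()


def read_kpg(stream: TextIO) -> KPartiteGraph:
    """Parse a .kpg stream into a validated k-partite graph."""
    lines = _tokenized_lines(stream)

    try:
        lineno, tokens = next(lines)
    except StopIteration:
        raise ParseError("empty file, expected 'kpg 1' header", 1) from None
    if tokens != ["kpg", "1"]:
        raise ParseError(f"expected 'kpg 1' header, got {' '.join(tokens)!r}", lineno)

    try:
        lineno, tokens = next(lines)
    except StopIteration:
        raise ParseError("missing 'k <K>' line", lineno) from None
    if len(tokens) != 2 or tokens[0] != "k":
        raise ParseError(f"expected 'k <K>', got {' '.join(tokens)!r}", lineno)
    try:
        k = int(tokens[1])
    except ValueError:
        raise ParseError(f"k is not an integer: {tokens[1]!r}", lineno) from None
    if k < 2:
        raise ParseError(f"k must be >= 2, got {k}", lineno)

    part_lists: list[list[str]] = []
    label_part: dict[str, int] = {}
    for expect in range(1, k + 1):
        try:
            lineno, tokens = next(lines)
        except StopIteration:
            raise ParseError(f"missing 'part {expect}' line", lineno) from None
        if len(tokens) < 2 or tokens[0] != "part":
            raise ParseError(
                f"expected 'part {expect} <labels...>', got {' '.join(tokens)!r}",
                lineno,
            )
        try:
            idx = int(tokens[1])
        except ValueError:
            raise ParseError(f"part index not an integer: {tokens[1]!r}", lineno) from None
        if idx != expect:
            raise ParseError(f"expected part {expect}, got part {idx}", lineno)
        labels = tokens[2:]
        if not labels:
            raise EmptyPartError(f"line {lineno}: part {idx} has no vertices")
        for label in labels:
            if label in label_part:
                raise DuplicateLabelError(f"line {lineno}: {label!r}")
            label_part[label] = idx
        part_lists.append(labels)

    edges: set[tuple[str, str]] = set()
    for lineno, tokens in lines:
        if tokens[0] != "edge" or len(tokens) != 3:
            raise ParseError(f"expected 'edge <u> <v>', got {' '.join(tokens)!r}", lineno)
        a, b = tokens[1], tokens[2]
        for end in (a, b):
            if end not in label_part:
                raise UnknownEndpointError(f"line {lineno}: {end!r}")
        if a == b or label_part[a] == label_part[b]:
            raise IntrapartiteEdgeError(
                f"line {lineno}: edge ({a!r}, {b!r}) lies inside part {label_part[a]}"
            )
        key = (a, b) if a <= b else (b, a)
        if key in edges:
            logger.warning("duplicate edge %s %s merged", key[0], key[1])
            continue
        edges.add(key)

    return build_graph(part_lists, sorted(edges))


def write_kpg(g: KPartiteGraph, stream: TextIO) -> None:
    """Write ``g`` canonically: parts in index order with sorted labels,
    then interpartite edges sorted lexicographically.

    Only interpartite edges are written; the completed form is derived,
    never serialized.
    """
    stream.write("kpg 1\n")
    stream.write(f"k {g.k}\n")
    for p in range(1, g.k + 1):
        labels = " ".join(sorted(g.parts[p]))
        stream.write(f"part {p} {labels}\n")
    inter = (
        e for e in g.edges()
        if g.part_of_label(e[0]) != g.part_of_label(e[1])
    )
    for a, b in sorted(inter):
        stream.write(f"edge {a} {b}\n")
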