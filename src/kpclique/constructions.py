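"""Extremal and synthetic k-partite graph families.

The triangle-deleted families here certify that a k-partite graph can have
~3^(n/3) maximal k-partite cliques, matching the enumeration engine's
upper bound:

* ``construct_k3(p)`` — remove p disjoint triangles from the balanced
  complete tripartite graph on n = 3p vertices.  Maximal tricliques
  correspond bijectively to ordered tripartitions of {1..p} into three
  nonempty blocks, so their number is exactly 3^p - 3(2^p - 1).
* ``construct_cyclic(k, p)`` — for k >= 4, remove kp disjoint triangles
  laid out cyclically across consecutive part triples from the balanced
  complete k-partite graph on n = 3pk vertices.  The count is bounded
  below by (3^p - 3(2^p - 1))^k.

Also provided: complete multipartite (Turán when balanced) graphs, a
seeded random k-partite generator for test fixtures, and the counting
formulas used as oracles.
"""

from __future__ import annotations

import random
from math import comb
from typing import Sequence

from .core import KPartiteError, KPartiteGraph, build_graph

__all__ = [
    "BadKError",
    "BadDensityError",
    "complete_multipartite",
    "construct_k3",
    "cyclic_triangles",
    "construct_cyclic",
    "k3_count",
    "k3_double_sum",
    "general_lower_bound",
    "random_kpartite",
]


class BadKError(KPartiteError):
    """k out of range for the requested construction."""


class BadDensityError(KPartiteError):
    """Edge density outside [0, 1]."""


def complete_multipartite(sizes: Sequence[int]) -> KPartiteGraph:
    """K_{x1,...,xk}: all interpartite edges present.

    Balanced sizes give the Turán graph.  Vertex labels are ``v<part>_<i>``.
    """
    parts = [[f"v{p}_{i}" for i in range(1, s + 1)] for p, s in enumerate(sizes, 1)]
    edges = []
    for a in range(len(parts)):
        for b in range(a + 1, len(parts)):
            for u in parts[a]:
                for v in parts[b]:
                    edges.append((u, v))
    return build_graph(parts, edges)


def construct_k3(p: int) -> KPartiteGraph:
    """Balanced complete tripartite graph on 3p vertices minus p disjoint
    triangles {x_i, y_i, z_i}.

    Edges are exactly the index-disagreeing interpartite pairs
    (x_i, y_j), (x_i, z_j), (y_i, z_j) with i != j: 3p(p-1) in total.
    The maximal tricliques are {x_i | i in I} ∪ {y_j | j in J} ∪
    {z_l | l in K} for each ordered tripartition {I, J, K} of {1..p}
    into nonempty blocks, hence exactly ``k3_count(p)`` of them.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    xs = [f"x{i}" for i in range(1, p + 1)]
    ys = [f"y{i}" for i in range(1, p + 1)]
    zs = [f"z{i}" for i in range(1, p + 1)]
    edges = []
    for i in range(p):
        for j in range(p):
            if i != j:
                edges.append((xs[i], ys[j]))
                edges.append((xs[i], zs[j]))
                edges.append((ys[i], zs[j]))
    return build_graph([xs, ys, zs], edges)


def cyclic_triangles(k: int, p: int) -> list[tuple[str, str, str]]:
    """The kp deleted triangles of the cyclic family, as label triples.

    Triangle family j (one per part, 1-based) contributes, for each
    1 <= i <= p, the triple {s_{j,i}, s_{j+1,i+p}, s_{j+2,i+2p}} with part
    indices taken cyclically in 1..k.  Within each part of size 3p the
    first, middle and last thirds are hit by different families, so the
    triangles are pairwise vertex-disjoint.
    """
    if k < 4:
        raise BadKError(f"cyclic construction needs k >= 4, got {k} (k=3 uses construct_k3)")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    triangles = []
    for j in range(1, k + 1):
        j2 = j % k + 1
        j3 = (j + 1) % k + 1
        for i in range(1, p + 1):
            triangles.append((f"s{j}_{i}", f"s{j2}_{i + p}", f"s{j3}_{i + 2 * p}"))
    return triangles


def construct_cyclic(k: int, p: int) -> KPartiteGraph:
    """Balanced complete k-partite graph on n = 3pk vertices minus the kp
    disjoint cyclic triangles (k >= 4).

    Exactly 3kp interpartite edges are removed.  The number of maximal
    k-partite cliques is at least ``general_lower_bound(k, p)``.
    """
    removed = set()
    for a, b, c in cyclic_triangles(k, p):
        for e in ((a, b), (a, c), (b, c)):
            removed.add(frozenset(e))
    parts = [[f"s{j}_{i}" for i in range(1, 3 * p + 1)] for j in range(1, k + 1)]
    edges = []
    for a in range(k):
        for b in range(a + 1, k):
            for u in parts[a]:
                for v in parts[b]:
                    if frozenset((u, v)) not in removed:
                        edges.append((u, v))
    return build_graph(parts, edges)


def k3_count(p: int) -> int:
    """Exact number of maximal tricliques of ``construct_k3(p)``:
    3^p - 3(2^p - 1), the number of ordered tripartitions of a p-set into
    three labeled nonempty blocks (inclusion-exclusion over surjections
    onto 3 labels)."""
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    return 3**p - 3 * (2**p - 1)


def k3_double_sum(p: int) -> int:
    """The tripartition count as the direct double sum
    sum_{a=1}^{p-2} sum_{b=1}^{p-a-1} C(p,a) C(p-a,b); equals
    ``k3_count(p)`` for p >= 3."""
    return sum(
        comb(p, a) * comb(p - a, b)
        for a in range(1, p - 1)
        for b in range(1, p - a)
    )


def general_lower_bound(k: int, p: int) -> int:
    """(3^p - 3(2^p - 1))^k: a lower bound on the number of maximal
    k-partite cliques of ``construct_cyclic(k, p)``, counting only the
    cliques that touch every third of every part."""
    if k < 4:
        raise BadKError(f"lower bound defined for k >= 4, got {k}")
    return k3_count(p) ** k


def random_kpartite(
    k: int,
    sizes: Sequence[int],
    density: float,
    seed: int,
) -> KPartiteGraph:
    """Independent-edge random k-partite graph (test fixture generator).

    Each interpartite pair becomes an edge with probability ``density``
    under a :class:`random.Random` seeded with ``seed``; the same seed
    always yields the identical graph.
    """
    if k != len(sizes):
        raise ValueError(f"k = {k} but {len(sizes)} sizes given")
    if not 0.0 <= density <= 1.0:
        raise BadDensityError(f"density must be in [0, 1], got {density}")
    rng = random.Random(seed)
    parts = [[f"v{p}_{i}" for i in range(1, s + 1)] for p, s in enumerate(sizes, 1)]
    edges = []
    for a in range(k):
        for b in range(a + 1, k):
            for u in parts[a]:
                for v in parts[b]:
                    if rng.random() < density:
                        edges.append((u, v))
    return build_graph(parts, edges)
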