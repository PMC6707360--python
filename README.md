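# kpclique

Enumeration and analysis of **maximal k-partite cliques** in k-partite
graphs, with the companion machinery that makes the problem tractable or
provably hard: extremal graph families, a fast path for set-intersection
graphs, and the one-in-three-SAT reduction gadget.

## The problem

A graph is *k-partite* when its vertices split into k nonempty parts
V_1..V_k with every edge running between two different parts.  A
*k-partite clique* is a vertex set inducing a complete k-partite subgraph:
every cross-part pair adjacent and **every part represented**; it is
*maximal* when no vertex can be added.  Multipartite cliques are the gold
standard for multidimensional density-based clustering — for example,
linking terms from several biomedical ontologies (each ontology a part)
through the genes they annotate (another part), or finding coherent
modules across heterogeneous similarity networks.

The key observation is that C is a maximal k-partite clique of G exactly
when C is a maximal clique of the graph G′ obtained by adding all
intrapartite edges, provided C covers the partition.  The enumerator
(`mmce`) is therefore the pivoted Bron–Kerbosch recursion on G′ with an
O(1) coverage check at each emission, running in O(3^(n/3)) time — and
that bound is unimprovable: the triangle-deleted families in
`constructions` have 3^(n/3) − 3(2^(n/3) − 1) maximal tripartite cliques
(and k-partite analogues), asymptotically 3^(n/3).

Two complexity boundaries are machine-checked rather than taken on faith:

* **Hardness** (`hardness`): finding a vertex-maximum k-partite clique is
  NP-hard for k ≥ 3, via a reduction from monotone one-in-three-SAT.  The
  reduction graph (9m vertices, 12m + 6d edges for m clauses and d
  matching literal pairs) is built explicitly, and exhaustive oracles
  confirm on every small instance that satisfiability coincides with a
  covering independent set of size 4m, i.e. a covering clique of size 4m
  in the interpartite complement.
* **The easy subclass** (`set_intersection`): in a *k-partite
  set-intersection graph* one part holds singleton vertices for the
  elements of a universe S and the other parts hold nonempty subsets of
  S, with edges marking nonempty intersection.  Fusing all subset
  vertices into one side of a bipartite graph preserves singleton
  neighborhoods, so maximal k-partite cliques correspond to maximal
  bicliques whose pre-image covers all parts — an O(n²·2^(n/2)) route
  (`mmce_si`) instead of O(3^(n/3)).  `msigr` recognizes the class in
  O(k·n³) without being told S, and `recover_sets` reads a witness set
  system back off the accepted part.

## Worked example

Generate the p = 3 triangle-deleted tripartite graph (n = 9, parts X, Y,
Z; the edge (x_i, y_j) exists iff i ≠ j, likewise X–Z and Y–Z) and
enumerate its maximal tricliques:

```console
$ kpclique generate --family k3 --p 3 -o g.kpg
$ kpclique enumerate --graph g.kpg --sorted
x1 | y2 | z3
x1 | y3 | z2
x2 | y1 | z3
x2 | y3 | z1
x3 | y1 | z2
x3 | y2 | z1
$ kpclique enumerate --graph g.kpg --count-only
6
```

Six cliques — exactly 3³ − 3(2³ − 1), the number of ways to tripartition
{1,2,3} into three labeled nonempty blocks.  Each output line is one
clique, parts separated by `|`.

The set-intersection fast path, on a universe {a..e} with two subset
parts (an ontology-annotation shaped instance):

```console
$ cat s.sets
sets 1
universe a b c d e
part 2 s1=a,b,d s2=a,d,e s3=c,d
part 3 s4=b,e s5=b,c
$ kpclique enumerate-si --sets s.sets --sorted
b | s1 | s4 s5
c | s3 | s5
e | s2 | s4
```

Three maximal 3-partite cliques; e.g. the first says gene b together with
the annotation sets s1 = {a,b,d}, s4 = {b,e} and s5 = {b,c} forms an
inextensible fully-linked module.  (The maximal *biclique* {b, c, s5}
exists in the compressed graph but leaves part 2 unrepresented, so it is
correctly not reported.)

And the hardness gadget on the monotone formula (v1 ∨ v2 ∨ v3) ∧ (v3 ∨ v4
∨ v5):

```console
$ kpclique verify-reduction --cnf f.cnf
SAT
covering-clique size 8 (target 4m = 8)
equivalence holds
```

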