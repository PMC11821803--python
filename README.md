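# lcadag

Least-common-ancestor structure and simplification of rooted DAGs and
phylogenetic networks.

## The problem

Rooted phylogenetic networks — and, more generally, directed acyclic graphs
on a taxon set *X* — are inferred from genomic data, but the inferred graphs
are often tangled and contain vertices with no direct support from the data.
A vertex *v* carries its *hardwired cluster* `C(v)`: the set of leaves
(taxa) reachable from it.  A vertex is *witnessed* by the data when it is a
**least common ancestor (LCA)** of some leaf set *A ⊆ X*, i.e. a
⪯-minimal common ancestor of *A*; in a DAG `LCA(A)` may be empty or contain
several incomparable vertices, and `lca(A)` is *well-defined* only when it
is a singleton.  A DAG is **LCA-relevant** (**lca-relevant**) when every
vertex is an LCA (the unique LCA) of some leaf set.

`lcadag` answers the questions a practitioner asks about such graphs:

* compute `LCA(A)` in `O((|V|+|E|)·|A|)` time by a topological sweep;
* decide whether a vertex is a *k*-LCA / *k*-lca vertex — for *some* k
  (polynomial), or for a *given* k (NP-complete in general; a guarded
  subset search with a polynomial fast path for **N3O** DAGs, those without
  three pairwise overlapping clusters — a class covering trees and galled
  trees);
* recognize the structural classes involved: **PCC** (path–cluster
  comparability), **CL** / **strong-CL** (`lca(C(v))` well-defined /
  equal to *v* for all *v*), **regular** (isomorphic to the Hasse diagram
  of its own cluster system), LCA-/lca-relevance, and 𝓘-relevance for
  restricted query sizes;
* simplify any DAG into an LCA-relevant or lca-relevant one with the
  vertex-suppression operator `G ⊖ v` (delete *v*, join each parent to each
  child) while provably preserving the leaf set, the ancestor order, the
  clusters, and all LCA answers (guarantees S0–S5);
* build Hasse diagrams of cluster systems, the transformations
  `φ_LCA(G) = (G ⊖ W(G))⁻` and `φ_lca` (suppress all non-LCA / non-lca
  vertices, then delete shortcut edges), and the cluster-restriction
  `G ≀ Y`; `φ_LCA` satisfies the simplification axioms — fixpoints are left
  unchanged, and the map commutes with leaf relabelling and with
  restriction;
* generate test instances: named worked examples, seeded random DAGs and
  galled trees, and vertex-cover gadgets whose root is a *k*-LCA vertex
  exactly when the underlying graph has a vertex cover of size *k*.

## Worked example

A galled tree whose root duplicates its child's cluster (root `rho` over
`u1`, `u2` with an extra edge `u1 → u2`; leaves `x1, x2, x3`):

```python
>>> import lcadag as L
>>> G = L.fixture("galled_cor710")
>>> sorted(G.edges)
[('rho', 'u1'), ('rho', 'u2'), ('u1', 'u2'), ('u1', 'x1'), ('u2', 'x2'), ('u2', 'x3')]
>>> L.unique_lca(G, {"x2", "x3"})
'u2'
>>> sorted(L.lca_set(G, {"x1", "x2", "x3"}).members)
['u1']
```

The root is *not* an LCA of any leaf set (`u1` carries the same cluster),
so simplification suppresses exactly it:

```python
>>> rep = L.make_lca_relevant(G)
>>> rep.removed
('rho',)
>>> sorted(rep.output.edges)
[('u1', 'u2'), ('u1', 'x1'), ('u2', 'x2'), ('u2', 'x3')]
>>> rep.s_flags
{'S1': True, 'S2': True, 'S3': True, 'S0': True, 'S4': True, 'S5': True}
```

The report records that no clusters or LCA answers changed (S0, S4, S5),
the leaf set is intact (S1), no vertices were invented (S2), and the
ancestor order among the surviving vertices is exactly the original one
(S3).  The output is lca-relevant: every remaining vertex is the unique LCA
of some taxa.

The same operations are available from the shell:

```bash
lcadag generate fixture galled_cor710 --output g.json
lcadag simplify g.json --mode lca --report report.json
lcadag check g.json --property lca-rel      # exit code 1, prints a witness
lcadag lca g.json --set x2,x3 --unique      # prints: u2
```

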