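# Methods

This note records the model, the algorithmic choices, and the design
decisions behind `lcadag`, in the order the package builds on them.

## The data model

A DAG is a finite set of string-labelled vertices with a set of directed
edges, no self-loops, and no directed cycles.  Vertex identity is the label:
two DAGs are equal exactly when their vertex and edge sets coincide, and
isomorphism (always up to inner labels but fixing the leaf labels, since the
leaves are the observed taxa) is a separate utility used in tests and
post-condition checks.  Leaves are the out-degree-0 vertices, roots the
in-degree-0 vertices; multiple roots and disconnected graphs are first-class
— no implicit super-root is ever added, because several of the structural
phenomena of interest (empty LCA sets, incomparable maximal vertices with
nested clusters) only occur in multi-rooted DAGs.

DAGs are immutable values.  Construction validates acyclicity with Kahn's
algorithm using a lexicographic min-heap, which fixes a canonical
topological order (ancestors first, ties broken by label).  Every
order-dependent computation — in particular the processing order of the
stepwise simplification — derives from this order, so all results are
deterministic.  Reachability sets and clusters are computed once per DAG in
reverse topological order and cached; structural edits (suppression,
shortcut removal, relabelling) return new DAGs, so caches are never
invalidated in place.

A cluster system is a ground set plus a family of nonempty subsets.  It is
*grounded* when all singletons are present, a *clustering system* when it is
grounded and contains the ground set, a *hierarchy* when additionally no two
clusters overlap, and *N3O* when no three clusters pairwise overlap.  The
N3O check is a cubic scan over cluster triples; at the instance sizes this
package targets (tens of clusters) that is never a bottleneck, and the
verdict is cached per DAG.

## LCA computation

`lca_set` processes the vertices in reverse topological order and maintains
the residue `A \ C(v)` per vertex: a leaf's residue is `A \ {v}`, an inner
vertex's is the intersection of its children's residues (the cluster of an
inner vertex is the union of its children's clusters).  A vertex belongs to
`LCA(A)` exactly when its residue is empty and every child's residue is
nonempty.  Residues are Python frozensets rather than the sorted arrays a
linear-time-in-the-word-RAM implementation would use; the asymptotic
contract `O((|V|+|E|)·|A|)` is unchanged and the constant is irrelevant at
desk scale.  An independent oracle, `lca_bruteforce`, implements the
definition literally (intersect the leaf's ancestor sets, keep the
⪯-minimal elements) and is used only in tests.

An undefined `lca` is a typed falsy sentinel (`UNDEFINED`), never an
exception: an empty or multi-member LCA set is a legitimate answer in a DAG.

## Explicit-k queries and the work bound

Whether a vertex is a k-LCA (k-lca) vertex for *some* k reduces to a single
query on its own cluster.  For a *given* k the problem is NP-complete, so
the general path enumerates the size-k subsets of `C(v)`; the number of
candidate subsets is capped by a work bound (default 10⁶, configurable) and
exceeding it raises a typed error rather than silently approximating.  The
admissible k always form an interval ending at `|C(v)|`, which
`some_k_interval` exploits by an ascending guarded search.

For N3O DAGs the interval is the full `2..|C(v)|` as soon as the vertex is
admissible at all, so explicit-k queries collapse to a constant number of
cluster comparisons.  Automatic dispatch tests N3O once per DAG (cached);
both code paths stay callable explicitly so that tests can compare them.

## Recognizers

Every recognizer returns a verdict plus a machine-checkable witness on
failure (a vertex, pair, edge, or cluster triple); tests re-validate
witnesses rather than trusting verdicts.  PCC and lca-relevance are
all-pairs checks over cached clusters and reachability; LCA-relevance is the
adjacent-equal-cluster edge test; CL uses the local characterization (each
vertex either is the unique LCA of its cluster or has a child with the same
cluster), which avoids one LCA query per vertex on the common path.
Regularity has two routes — the characterization (no out-degree-1 vertex,
shortcut-free, PCC) as the default, and the definition (the cluster map is
an isomorphism onto the Hasse diagram) as a cross-check — and the test suite
asserts they agree on the whole corpus.

`is_I_relevant` treats an index set without 1 as an immediate, documented
`False` (leaves are only 1-LCA vertices), delegates the full index set to
the plain recognizers, uses the N3O shortcut when available, and otherwise
falls back to guarded per-vertex searches.

## Suppression and the simplification algorithms

`G ⊖ v` deletes v and joins each parent to each child; it commutes with
itself, so suppressing a set is order-independent.  Suppressing inner
vertices preserves the leaf set, the ancestor order among survivors, and all
surviving clusters (S0–S3); suppressing only non-LCA (non-lca) vertices
additionally preserves all LCA answers (S5, resp. S4).  The
`SimplificationReport` re-verifies these flags on the concrete output:
S3 by comparing reachability on the surviving vertices, S4/S5 by comparing
LCA answers over all leaf subsets of size ≤ 3 (or a deterministic sample of
400 subsets once the exhaustive pool would exceed that — large leaf sets
only occur in generated stress instances).

`make_LCA_relevant` evaluates its removal condition `v ∉ LCA(C(v))`
entirely on the input DAG; this is sound because LCA answers are invariant
throughout the removal, and it makes the algorithm one pass.  Its removal
set is the unique minimum one subject to (S0)–(S5), which the tests confirm
exhaustively on instances with at most 10 vertices.

`make_lca_relevant` must re-evaluate `v ≠ lca(C(v))` on the *updated* DAG —
removing one vertex can turn another into a unique LCA — and its outcome
genuinely depends on the processing order.  The package fixes the order to
the canonical topological order (ancestors first).  Rationale: the choice is
deterministic, and processing superfluous extra roots before their
descendants preserves the largest cluster set on the double-rooted chain
family, where the opposite order destroys all non-trivial clusters.  Leaves
are structurally excluded from removal in both algorithms (a leaf is always
the unique LCA of itself).

## Hasse diagrams, transformations, restriction

The Hasse diagram of a set system has the clusters as vertices and the cover
pairs of strict inclusion as edges; cover detection is the direct
cubic-in-`|C|` scan.  Cluster vertices get canonical labels
(`{a,b,c}` with sorted elements) and relabelling — only defined for grounded
systems — renames each singleton `{x}` to `x` so that the diagram's own
cluster system reproduces the input.

`φ_LCA` composes the one-pass simplification with shortcut removal (an edge
is a shortcut when a longer directed path joins its endpoints; removing all
of them is order-independent and preserves reachability and clusters).  Its
image is the class of shortcut-free LCA-relevant DAGs, on which it is the
identity; it is idempotent.  `φ_lca` suppresses all non-lca vertices of the
*input* in one pass.  On inputs with CL (or PCC, which implies CL) the two
maps coincide and land on the Hasse diagram of the input's clusters; without
CL, `φ_lca` proceeds with a logged warning instead of refusing — applied to
e.g. the double-rooted chain diagram it collapses everything to an edgeless
DAG, which is exactly the documented counterexample to the restriction
axiom.

The cluster-restriction `G ≀ Y` is the relabelled Hasse diagram of the
nonempty traces `C ∩ Y`; the trace system is grounded on Y, so the result is
always regular.  Because restriction outputs carry canonical labels, the
axiom checks (`φ(G ≀ Y) ≅ φ(G) ≀ Y`, equivariance under leaf permutation)
reduce to label-wise equality in most tests, with the generic
leaf-label-respecting VF2 isomorphism as the fallback.

## Generators and gadgets

`random_dag(n_inner, n_leaves, density, seed)` places the inner vertices on
a fixed topological spine and samples forward edges independently at the
given density, forcing at least one child per inner vertex so the leaf set
is exactly the requested one.  Default study conditions in the tests are
small instances — 3–6 leaves, up to ~12 vertices — chosen because every
brute-force oracle (subset enumeration, all deletion orders, exhaustive
minimality) must stay exact alongside them; all sampling is reproducible
from explicit seeds with one private PRNG stream per call.

`random_galled_tree` grows a random binary tree and converts the two child
edges of up to `n_leaves − 1` distinct tree vertices into galls (two
internally disjoint directed paths), reattaching the displaced subtrees
inside the gall.  Using each tree vertex at most once guarantees the
biconnected components never merge, so the output is a genuine galled tree;
N3O is asserted at generation time.

The vertex-cover gadgets build, for an undirected graph H (at least 4
vertices, 2 edges, not a star), the relabelled Hasse diagram of the
singletons plus the edge complements `V(H) \ e` (plus `V(H)` itself for the
LCA variant).  The root of the LCA gadget is a k-LCA vertex iff H has a
vertex cover of size k; the lca variant instead hangs two private leaves
under each complement vertex and adds a separate root r* over the original
leaves, making r* a k-lca vertex iff a size-k cover exists.  Gadget vertex
names are deterministic (`r_<sorted endpoints>`, `x1_<tag>`/`x2_<tag>`,
`rho`, `rstar`).  The test corpus enumerates every connected non-star graph
on 4–6 vertices (one per isomorphism class, via the networkx graph atlas)
rather than sampling.

## What the synthetic data does and does not show

The generators exercise the combinatorial structure the algorithms act on —
multiple roots, shortcuts, redundant vertices, galls, overlapping clusters,
adversarial cluster systems — but they are not calibrated simulations of
reticulate evolution: edge densities, gall counts and leaf numbers are
chosen for coverage of structural cases, not biological realism.  Passing
tests therefore certify the graph-theoretic guarantees (exact LCA sets,
preservation properties S0–S5, minimality and uniqueness of removal sets,
axiom compliance) on any input DAG; they say nothing about whether a given
inference method produces DAGs whose non-LCA vertices *should* be removed.

## Numerical and degenerate-input choices

There is no floating-point numerics in the core; all computation is exact
set manipulation.  Degenerate inputs are defined rather than rejected
wherever the theory defines them: single-vertex DAGs (leaf = root),
disconnected DAGs, empty LCA sets, `W = ∅` in suppression.  Hard errors are
reserved for genuine contract violations: cycles, self-loops, unknown
vertices, empty queries, non-leaf query elements, suppressing the only
vertex, relabelling a non-grounded Hasse diagram, and exceeding the
explicit-k work bound.

## Known limitations

* Explicit-k queries on non-N3O DAGs are exponential in `min(k, |C(v)|-k)`;
  the work bound makes the failure mode explicit but does not remove it
  (the problem is NP-complete).
* The package exposes only the deterministic removal sets with the S-
  guarantees; finding a globally minimum set that merely achieves
  lca-relevance (without S4), or one maximizing the preserved clusters, is
  left open.
* Isomorphism checking is a small-instance utility (canonical cluster
  labelling when clusters are pairwise distinct, VF2 otherwise), not a
  scalable canonical form.
* Extended-Newick / GML import and any visualization are out of scope; the
  JSON/TSV formats are the interchange surface.
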