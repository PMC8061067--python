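# Methods

## Problem

Given a collection of undirected, vertex-labelled target graphs
G^t = {G_1, ..., G_n} and a query graph G^q, one-to-many subgraph search
asks for every *subgraph monomorphism* of G^q into every G_i: an injective
mapping of query vertices to target vertices that preserves vertex labels
and maps every query edge onto a target edge (extra edges between images
are allowed — matching is non-induced). Exact matching is NP-complete, so
practical systems are *filter-and-verify*: a precomputed index discards
targets and target vertices that provably cannot participate in a match,
and an exhaustive matcher verifies only what remains. The filter must be
sound — it may keep non-matching graphs (false positives cost time) but
must never drop a matching one (false negatives cost correctness).

## Index features: labelled paths

The indexing feature is the labelled path: the sequence of vertex labels
(σ₁, ..., σ_l) along a *simple* path (distinct vertices) of l ≤ l_p
vertices. For every start vertex the index stores, per distinct label
sequence, the number of distinct vertex sequences realising it. Paths of
every length 1..l_p are stored, so the length-1 path is exactly the
vertex's own label. Whether bounded walks (vertex repeats allowed) or
simple paths are the right enumeration is genuinely open; this package
fixes simple paths, which keep counts finite, bounded and monotone under
edge addition. The default l_p = 4 balances filtering power against index
size; it is configurable everywhere.

Counting soundness rests on a composition property: if φ is a monomorphism
of the query into a target, φ maps every simple query path starting at v_q
to a distinct simple target path with the same label sequence starting at
φ(v_q). Hence, for every query path p:

* graph-level test — occurrences of p in the target ≥ occurrences in the
  query, otherwise the whole graph is discarded;
* vertex-level test — every path starting at v_q must also start at any
  candidate image v (nonzero count), otherwise v is removed from v_q's
  candidate set.

An optional stricter per-vertex count-dominance test (count at v ≥ count
at v_q, also implied by the composition property) is available behind a
flag and off by default, matching the plain start-vertex formulation of
the two conditions above.

## The decision-diagram index

The per-vertex count table is a function

    f(v, σ₁, ..., σ_lp) → count

over l_p + 1 finite variables: v ranges over the *global* vertex
enumeration of the whole collection (graph i's vertex u has global id
offset_i + u, offsets being prefix sums of graph sizes) and each label
variable ranges over the label codes {1..|Σ|} plus the reserved padding
value 0. Paths shorter than l_p are right-padded with 0s, so padding zeros
always form a suffix of the label variables.

This function is stored in a multi-terminal multi-way decision diagram
(MTMDD): a rooted, ordered DAG with one node level per variable and
integer-labelled terminals. The engine implements the *quasi-reduced*
normal form — duplicate nodes are merged through a hash-consing unique
table, redundant nodes are kept, and every root-to-terminal path visits
every level exactly once. Quasi-reduction plus hash-consing make the form
canonical (equal functions are the identical node), keep the binary
`apply` recursion level-synchronised, and give an O(1) emptiness test (a
subfunction is identically zero iff it *is* the canonical zero chain of
its level). Binary operators (pointwise addition and multiplication) use
recursive descent memoised in a computed table; correctness never depends
on cache retention, so the cache may be dropped at any time.

Construction is incremental: one graph at a time, vertices grouped by
label, each group's paths enumerated by depth-limited search and counted
in a temporary trie, the trie converted to a diagram with `create_edge`
and merged into the accumulator with `apply(plus)`, the temporaries then
discarded. Canonicity guarantees the result is independent of graph and
group order. A whole-collection trie (`TrieIndex`) with the same count
interface is retained as the reference backend: the prefix-compressed trie
is the classic container for this index, and comparing the two backends'
node counts and serialised sizes measures the sharing the DAG adds —
beyond prefixes, the diagram also shares suffixes and whole subfunctions
across start vertices and graphs.

The node-sharing argument is made precise by the decision-tree bound: the
quasi-reduced diagram of a function never has more non-terminal nodes than
the decision tree (the unshared unfolding over the same variable order) of
that function. The engine computes the unfolding size by dynamic
programming, and the bound is asserted for every index the tests build.
Note the bound is stated against the full decision tree, not against the
support-pruned trie: on near-empty functions the quasi-reduced form's
zero-padding chains can exceed a pruned trie, while on real indexes the
diagram is far smaller — the reported trie/diagram ratios quantify this.

## Filtering

Query paths are enumerated exactly as target paths are. The query's own
vertices are *not* represented in its diagram: the query diagram has a
fully redundant vertex level (all branches share one child) and value 1 on
every (any vertex id, padded query path) assignment. Multiplying it
pointwise into the index zeroes every index entry whose path the query
does not contain, while the 0/1 terminals preserve the index counts on the
surviving entries — which is why the query diagram carries 1s rather than
query counts. Candidate start vertices are then read off the vertex level
of the pruned diagram; the two filter conditions run on the counts; and
the maximally connected components of the subgraph induced by the union of
candidate vertices are computed, dropping components with fewer vertices
than the query (a connected query's image is connected and lies inside one
component, so the cut is sound). A query using a label absent from the
collection's alphabet short-circuits to an empty report — it trivially
matches nothing — rather than raising.

## Verification

Match enumeration is a VF2-style depth-first state extension restricted to
the filtered candidate domains per component. Feasibility rules: mapped
query neighbours must map to target neighbours of the tried vertex (only
query edges are required — non-induced semantics), and a look-ahead
requires the tried vertex to have at least as many unused target
neighbours as the query vertex has unmapped neighbours. The exploration
order is greatest-constrained-first: most already-mapped neighbours, then
smallest candidate domain, then lowest index; with the order fixed the
mapping sequence is deterministic. Because filtering is sound and
components are vertex-disjoint, per-component counts add up to exactly the
unfiltered match count — the filter changes speed, never results, and the
tests assert this equality instance by instance. A deliberately naive
brute-force matcher (injective label-preserving assignment with
edge-by-edge checks) ships in the same module as the oracle for the search
code; disconnected queries are rejected by collection-level verification,
whose component restriction assumes connectivity.

## Synthetic data

The generators produce the kind of inputs the method targets — scale-free
biological-network-like topologies with controlled label diversity:

* **Degree-power attachment** (`barabasi`): m₀ seed vertices in a path;
  each new vertex attaches to min(m₀, current size) distinct existing
  vertices drawn with probability ∝ degree^α. α = 1 is classic
  preferential attachment; α > 1 sharpens hubs, α < 1 flattens them.
  Edges-per-step equals m₀, so the mean degree is ≈ 2·m₀. Defaults:
  m₀ = 2, α = 1.
* **Forest fire** (`forestfire`): each new vertex links to a uniform
  ambassador and burns forward through the neighbourhood; every visited
  vertex burns x unvisited neighbours, x geometric on {0, 1, 2, ...} with
  mean p/(1−p) (success probability 1−p), and every burned vertex gets an
  edge to the newcomer. Burning is supercritical for p > 0.5 — the mean
  branching factor p/(1−p) exceeds 1 and each fire reaches most of the
  graph, which drives the density towards a clique. Mid-size experiments
  therefore use subcritical p (default 0.3); exhaustive path enumeration
  on strongly supercritical graphs is combinatorially out of reach for
  any implementation of this index.
* **Labelling**: each vertex draws uniformly from an alphabet of
  max(1, round(label_pct · n)) labels; label_pct is the single strongest
  lever on index size and filtering power (fewer labels → more shared
  paths → larger counts and weaker filters).
* **Query extraction**: randomised connected expansion from a uniform
  start vertex up to a vertex or induced-edge budget, then the induced
  subgraph. Every extracted query is an induced subgraph of its origin, so
  at least one (identity) match is guaranteed — the planted-match property
  used as the end-to-end check.

All generators are deterministic functions of their seed; identical
configurations reproduce byte-identical `.gfu` files.

What the generators do not emulate: real molecular graphs' degree caps
(valence), label distributions that are highly non-uniform (atom types),
or correlated motif structure. Passing the synthetic suite demonstrates
algorithmic correctness and the compression mechanism, not performance on
any particular biochemical corpus.

## Numerical and design choices

* Terminals are exact nonnegative integers — counts never touch floating
  point.
* Label codes start at 1; 0 is reserved for the padding symbol. Vertex ids
  and file formats are 0-based.
* Trie children and diagram serialisation follow ascending label/branch
  order; diagram node numbering is depth-first discovery order, so equal
  functions serialise byte-identically.
* Self-loops and parallel edges are rejected at parse time; graphs are
  undirected throughout.
* The index file is the diagram text followed by a `### META` block
  (l_p, label strings by code, per-graph name and size); loading
  cross-validates the metadata against the diagram's domain.
* Exhaustive oracle comparisons in the tests run on domains up to 10⁵
  assignments and collections up to ~60 vertices per graph; the index
  equivalence check compares the diagram's nonzero support against the
  brute-force table (canonicity makes "equal support" equivalent to "equal
  everywhere").

## Known limitations

* Path enumeration is exponential in l_p on dense graphs; the package is
  intended for sparse, bounded-degree targets (see the forest-fire note
  above).
* No incremental index maintenance: adding or removing a graph rebuilds
  the index (the addition-merge makes appending collections cheap in
  principle, but the global vertex enumeration shifts).
* Single-threaded; no variable-reordering heuristics — the fixed order is
  vertex id first, then path positions.
* Matching is monomorphism only; induced (isomorphism-style) matching is
  not implemented.
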