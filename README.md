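# pathmdd

Filter-and-verify subgraph search over collections of vertex-labelled
undirected graphs, with the labelled-path index stored in a
multi-terminal multi-way decision diagram (MTMDD).

## Who this is for

Searching a small query graph inside a collection of larger targets —
molecules, protein structures, protein–protein interaction networks — is
a recurring primitive in systems biology and cheminformatics. Exact
matching (subgraph monomorphism: an injective, label-preserving mapping
sending every query edge onto a target edge) is NP-complete, so
one-to-many search engines precompute an index of cheap features and use
it to discard, before any matching, the targets and target vertices that
cannot possibly participate in a match.

`pathmdd` indexes *labelled paths*: for every vertex `v` and every label
sequence (σ₁, ..., σ_l) of a simple path of at most `l_p` vertices
starting at `v`, it stores the number of occurrences. The key design
point is the container: the whole table

    f(v, σ₁, ..., σ_lp) → count

is a single decision diagram over the collection-wide vertex enumeration
and `l_p` label variables (short paths padded with a reserved 0 symbol).
The quasi-reduced, hash-consed diagram shares not only common prefixes
(as the classic trie container does) but suffixes and whole subfunctions
across start vertices and graphs — and query filtering becomes one
pointwise multiplication between the index and a 0/1 diagram of the
query's paths. Surviving candidates are checked by two sound count
conditions (per-graph count dominance and per-vertex path containment),
grouped into connected components, and handed to a VF2-style enumerator
that reports every match. Filtering never changes results — only how fast
they are found — and the test suite asserts exactly that.

A prefix-trie backend with the same interface ships alongside the diagram
as the reference baseline; comparing the two measures the compression the
diagram adds.

## Worked example

Generate two synthetic targets (a forest-fire graph and a scale-free
graph, 10% distinct labels), extract a 5-vertex query from the first, and
search:

```
$ pathmdd generate --model forestfire -n 120 --p 0.3 --labels 0.1 --seed 11 -o t0.gfu
$ pathmdd generate --model barabasi  -n 100 --m0 2 --alpha 1.0 --labels 0.1 --seed 12 -o t1.gfu
$ cat t0.gfu t1.gfu > targets.gfu
$ pathmdd extract-query -i targets.gfu --graph 0 --vertices 5 --seed 3 -o query.gfu
$ pathmdd build -i targets.gfu -l 4 -o targets.index
index written to targets.index (1787 nodes, 104610 bytes)
$ pathmdd stats --index targets.index --compare targets.gfu
graphs	2
lp	4
dd_nodes	1787
dd_edges	41298
dd_terminals	14
serialized_bytes	104610
trie_nodes	7418
trie_links	7418
trie_payload_entries	12976
trie_to_dd_node_ratio	11.412
$ pathmdd query --index targets.index -q query.gfu --collection targets.gfu
ff_n120_p0.3_s11	candidates=6	components=1
ff_n120_p0.3_s11	0	97
ff_n120_p0.3_s11	1	36
...
ff_n120_p0.3_s11	matches=2
total matches: 2
```

Reading the output: the two 220-vertex targets produce an index function
with 12,976 nonzero (vertex, path) entries; the trie stores it in 7,418
label nodes plus 12,976 payload entries, the diagram in 1,787 nodes — a
node ratio of 11.4. Filtering the 5-vertex query keeps only the
forest-fire graph (the scale-free target lacks some query path), with 6
candidate vertices in one connected component; lines like `0 97` say
target vertex 97 is a possible image of query vertex 0. Verification then
finds exactly 2 monomorphisms. `--backend trie-oracle` reruns any query
on the trie baseline and must print identical results; `filter` (or
`query --filter-only`) stops before verification.

The same pipeline is available as a library:

```python
from pathmdd import (read_collection, build_index, run_filter,
                     verify_collection)

coll = read_collection("targets.gfu")
index = build_index(coll, l_p=4)
query = read_collection("query.gfu")[0]
features, report = run_filter(index, query, collection=coll)
print(verify_collection(query, report, coll).total)   # -> 2
```

## File formats

Graphs use a line-based text dialect (`.gfu`), one record per graph:
`#name`, vertex count, one label string per vertex, edge count, one
`u v` pair per undirected edge (0-based, listed once). Indexes are stored
as the diagram's deterministic text serialisation followed by a `### META`
block (l_p, label codes, graph names and sizes).

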