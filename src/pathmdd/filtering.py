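"""The filtering phase: query features, diagram multiplication, candidates.

Filtering never decides matches; it only discards what provably cannot
match, so it must have zero false dismissals.  Two conditions are applied:

1. graph level — every labelled path of the query must occur in the target
   graph at least as many times as in the query;
2. vertex level — a target vertex is a candidate image of a query vertex
   only if every path starting at the query vertex also starts at it
   (which subsumes the label-equality requirement, since the length-1 path
   is the vertex's own label).

With the diagram backend, condition checks read the *pruned* diagram: the
pointwise product of the index and a 0/1 query diagram whose vertex variable
is redundant, which zeroes every index entry whose path does not occur in
the query while preserving the index counts on the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .graphs import LabelAlphabet, LabelledGraph
from .indexing import GraphIndex, TrieIndex, encode_assignment
from .paths import enumerate_paths

__all__ = [
    "QueryFeatures",
    "CandidateReport",
    "extract_query_features",
    "build_query_mdd",
    "prune",
    "candidate_vertices",
    "filter_graphs",
    "run_filter",
]

Path = tuple[int, ...]


@dataclass
class QueryFeatures:
    """Labelled-path features of a query graph, coded in the index alphabet.

    ``unmatchable`` is set when the query uses a label absent from the index
    alphabet: no target can contain it, so filtering short-circuits to an
    empty report instead of raising.
    """

    total: dict[Path, int] = field(default_factory=dict)
    per_vertex: dict[int, dict[Path, int]] = field(default_factory=dict)
    n_query_vertices: int = 0
    unmatchable: bool = False

    @property
    def paths(self) -> list[Path]:
        return list(self.total)

    def vertex_label(self, qv: int) -> int:
        """Label code of a query vertex = its unique length-1 path."""
        for path in self.per_vertex[qv]:
            return path[0]
        raise KeyError(qv)


@dataclass
class CandidateReport:
    """Output of the filtering phase.

    ``candidates[i][qv]`` is the set of local vertices of graph *i* that may
    be images of query vertex *qv*; ``components[i]`` lists the maximally
    connected components (vertex sets) of the subgraph induced by the union
    of candidate vertices, after dropping components smaller than the query.
    """

    surviving: list[int] = field(default_factory=list)
    candidates: dict[int, dict[int, set[int]]] = field(default_factory=dict)
    components: dict[int, list[set[int]]] = field(default_factory=dict)

    @property
    def n_surviving(self) -> int:
        return len(self.surviving)


def extract_query_features(
    query: LabelledGraph, alphabet: LabelAlphabet, l_p: int
) -> QueryFeatures:
    """Enumerate the query's labelled paths, recoded into *alphabet*.

    Uses the same simple-path depth-limited enumeration as target indexing.
    """
    recode: dict[int, int] = {}
    for own_code in set(query.labels):
        target_code = alphabet.code(query.alphabet.string(own_code))
        if target_code is None:
            return QueryFeatures(
                n_query_vertices=query.n_vertices, unmatchable=True
            )
        recode[own_code] = target_code
    features = QueryFeatures(n_query_vertices=query.n_vertices)
    for qv in range(query.n_vertices):
        per_vertex: dict[Path, int] = {}
        for own_path, _end in enumerate_paths(query, qv, l_p):
            path = tuple(recode[c] for c in own_path)
            per_vertex[path] = per_vertex.get(path, 0) + 1
            features.total[path] = features.total.get(path, 0) + 1
        features.per_vertex[qv] = per_vertex
    return features


def build_query_mdd(features: QueryFeatures, index: GraphIndex) -> int:
    """0/1 diagram over the index domain marking the query's paths.

    The vertex variable is fully redundant (all branches share one child),
    since the query's own vertices are not represented; the value is 1 on
    every (any gid, padded query path) assignment and 0 elsewhere.  Terminal
    1 — rather than the query count — keeps the subsequent multiplication
    count-preserving on the surviving index entries.
    """
    if not features.total:
        raise ValueError("query features are empty")
    forest = index.forest
    l_p = index.l_p
    padded = [
        tuple(path) + (0,) * (l_p - len(path)) for path in features.total
    ]
    items = [((0,) + suffix, 1) for suffix in sorted(padded)]
    # build the label-level subfunction, then a redundant vertex-level root
    label_sub = forest._build_rows(l_p, items, 1)
    return forest.node(forest.K, (label_sub,) * forest.size(forest.K))


def prune(index: GraphIndex, query_dd: int) -> int:
    """Pointwise product of index and query diagrams.

    Retains exactly the index entries whose path occurs in the query, with
    the index's occurrence counts.
    """
    return index.forest.apply("times", index.root, query_dd)


def candidate_vertices(pruned: int, index: GraphIndex) -> dict[int, set[int]]:
    """Per-graph sets of vertices at which some query path starts.

    Reads the vertex level of the pruned diagram: global id *gid* qualifies
    iff its branch is not the identically-zero subfunction.
    """
    forest = index.forest
    out: dict[int, set[int]] = {i: set() for i in range(index.n_graphs)}
    children = forest.children_of(pruned)
    zero_sub = forest.zero(forest.K - 1)
    for gid, child in enumerate(children):
        if child != zero_sub:
            i, v = index.graph_of_gid(gid)
            out[i].add(v)
    return out


def _connected_components(
    graph: LabelledGraph, vertices: set[int]
) -> list[set[int]]:
    """Maximally connected components of the induced subgraph on *vertices*."""
    remaining = set(vertices)
    components: list[set[int]] = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        stack = [seed]
        remaining.discard(seed)
        while stack:
            v = stack.pop()
            for w in graph.neighbours(v):
                if w in remaining:
                    remaining.discard(w)
                    comp.add(w)
                    stack.append(w)
        components.append(comp)
    return components


def filter_graphs(
    candidates: Mapping[int, set[int]],
    index: GraphIndex | TrieIndex,
    features: QueryFeatures,
    collection=None,
    per_vertex_counts: bool = False,
) -> CandidateReport:
    """Apply both filter conditions and assemble the candidate report.

    *candidates* holds, per graph, the vertices at which some query path
    starts (the pruned-diagram support).  *collection* supplies target
    adjacency for the component computation; when omitted, components are
    skipped (``components`` stays empty and no size cut is applied).

    ``per_vertex_counts`` additionally requires the count at the target
    vertex to dominate the count at the query vertex (a stricter, still
    sound, vertex test; off by default).
    """
    report = CandidateReport()
    if features.unmatchable or not features.total:
        return report
    query_paths = list(features.total.items())
    n_query = features.n_query_vertices
    for i in range(index.n_graphs):
        # condition (2), graph level: target counts dominate query counts
        if any(
            index.per_graph_path_count(i, path) < q_count
            for path, q_count in query_paths
        ):
            continue
        starts = candidates.get(i, set())
        offset = index.vertex_offsets[i]
        per_qv: dict[int, set[int]] = {}
        for qv, qv_paths in features.per_vertex.items():
            images: set[int] = set()
            for v in starts:
                gid = offset + v
                ok = True
                for path, q_count in qv_paths.items():
                    c = index.vertex_path_count(gid, path)
                    if c == 0 or (per_vertex_counts and c < q_count):
                        ok = False
                        break
                if ok:
                    images.add(v)
            per_qv[qv] = images
        if any(not images for images in per_qv.values()):
            continue
        if collection is not None:
            union = set().union(*per_qv.values())
            comps = [
                c
                for c in _connected_components(collection[i], union)
                if len(c) >= n_query
            ]
            if not comps:
                continue
            kept = set().union(*comps)
            per_qv = {qv: images & kept for qv, images in per_qv.items()}
            if any(not images for images in per_qv.values()):
                continue
            report.components[i] = comps
        report.surviving.append(i)
        report.candidates[i] = per_qv
    return report


def _trie_candidate_starts(
    index: TrieIndex, features: QueryFeatures
) -> dict[int, set[int]]:
    """Oracle-backend equivalent of the pruned-diagram support scan."""
    out: dict[int, set[int]] = {i: set() for i in range(index.n_graphs)}
    query_paths = set(features.total)
    for gid, path, _count in index.iter_entries():
        if path in query_paths:
            i, v = index.graph_of_gid(gid)
            out[i].add(v)
    return out


def run_filter(
    index: GraphIndex | TrieIndex,
    query: LabelledGraph,
    collection=None,
    per_vertex_counts: bool = False,
) -> tuple[QueryFeatures, CandidateReport]:
    """Full filtering pipeline for either backend.

    Diagram backend: query diagram, multiplication, support scan.  Trie
    backend: direct table scan.  Both feed the same condition checks, so the
    reports are identical by construction up to backend bugs — which is what
    the backend-equivalence tests pin down.
    """
    features = extract_query_features(query, index.alphabet, index.l_p)
    if features.unmatchable:
        return features, CandidateReport()
    if isinstance(index, TrieIndex):
        starts = _trie_candidate_starts(index, features)
    else:
        query_dd = build_query_mdd(features, index)
        pruned = prune(index, query_dd)
        starts = candidate_vertices(pruned, index)
    report = filter_graphs(
        starts, index, features, collection=collection,
        per_vertex_counts=per_vertex_counts,
    )
    return features, report
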