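"""Independent reference implementations used as test oracles.

Deliberately written in the most naive style possible — plain recursion and
dictionaries, no shared code with the package internals — so that agreement
with the package is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import itertools


def oracle_simple_paths(graph, start, l_p):
    """All simple paths of 1..l_p vertices from *start*, as label tuples.

    One entry per distinct vertex sequence (multiplicities preserved).
    """
    results = []

    def recurse(vertex_seq):
        results.append(tuple(graph.labels[v] for v in vertex_seq))
        if len(vertex_seq) == l_p:
            return
        for w in graph.neighbours(vertex_seq[-1]):
            if w not in vertex_seq:
                recurse(vertex_seq + [w])

    recurse([start])
    return results


def oracle_collection_counts(collection, l_p):
    """Brute-force (global id, label path) -> count table for a collection."""
    counts = {}
    for i, g in enumerate(collection):
        offset = collection.vertex_offsets[i]
        for v in range(g.n_vertices):
            for labels in oracle_simple_paths(g, v, l_p):
                key = (offset + v, labels)
                counts[key] = counts.get(key, 0) + 1
    return counts


def oracle_graph_path_counts(graph, l_p):
    """Whole-graph label-path occurrence counts."""
    counts = {}
    for v in range(graph.n_vertices):
        for labels in oracle_simple_paths(graph, v, l_p):
            counts[labels] = counts.get(labels, 0) + 1
    return counts


def oracle_monomorphisms(query, target):
    """Every injective label-preserving mapping with all query edges present,
    found by filtering the raw cartesian product of label classes."""
    classes = []
    for qv in range(query.n_vertices):
        wanted = query.label_string(qv)
        classes.append(
            [tv for tv in range(target.n_vertices) if target.label_string(tv) == wanted]
        )
    matches = []
    for images in itertools.product(*classes):
        if len(set(images)) != len(images):
            continue
        if all(target.has_edge(images[u], images[w]) for u, w in query.edges):
            matches.append(dict(enumerate(images)))
    return matches


def random_function_rows(rng, domain, n_rows, max_value=20):
    """Distinct random (assignment, value>=0) rows over *domain* (root-first)."""
    seen = set()
    rows = []
    for _ in range(n_rows):
        assignment = tuple(int(rng.integers(n)) for n in domain)
        if assignment in seen:
            continue
        seen.add(assignment)
        rows.append((assignment, int(rng.integers(max_value + 1))))
    return rows


def all_assignments(domain):
    return itertools.product(*(range(n) for n in domain))


def lookup_table(rows):
    """Plain-dictionary semantics of an explicit row list (default 0)."""
    table = {tuple(a): v for a, v in rows}
    return lambda assignment: table.get(tuple(assignment), 0)
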