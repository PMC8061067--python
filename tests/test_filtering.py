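"""Query features, diagram multiplication and the two filter conditions."""

import numpy as np
import pytest

from pathmdd import (
    build_collection,
    build_index,
    build_query_mdd,
    build_trie_index,
    candidate_vertices,
    encode_assignment,
    extract_query,
    extract_query_features,
    filter_graphs,
    generate_collection,
    prune,
    run_filter,
)

from _oracles import oracle_monomorphisms


def _graph(labels, edges, name="q"):
    return build_collection([(name, labels, edges)])[0]


def test_single_edge_features(tiny_collection):
    q = _graph(["A", "B"], [(0, 1)])
    feats = extract_query_features(q, tiny_collection.alphabet, 2)
    a, b = tiny_collection.alphabet.code("A"), tiny_collection.alphabet.code("B")
    assert feats.total == {(a,): 1, (b,): 1, (a, b): 1, (b, a): 1}
    assert not feats.unmatchable


def test_triangle_whole_query_count(tiny_collection):
    q = _graph(["A", "B", "B"], [(0, 1), (0, 2), (1, 2)])
    feats = extract_query_features(q, tiny_collection.alphabet, 3)
    a, b = tiny_collection.alphabet.code("A"), tiny_collection.alphabet.code("B")
    assert feats.total[(a, b)] == 2


def test_alien_label_is_unmatchable(tiny_collection):
    q = _graph(["Z"], [])
    feats = extract_query_features(q, tiny_collection.alphabet, 2)
    assert feats.unmatchable
    index = build_index(tiny_collection, 2)
    _, report = run_filter(index, q, collection=tiny_collection)
    assert report.surviving == []


class TestQueryDiagram:
    def test_vertex_level_redundant(self, tiny_collection):
        index = build_index(tiny_collection, 2)
        q = _graph(["A", "B"], [(0, 1)])
        feats = extract_query_features(q, tiny_collection.alphabet, 2)
        qdd = build_query_mdd(feats, index)
        children = index.forest.children_of(qdd)
        assert len(set(children)) == 1  # invariant under the vertex value
        # value 1 exactly on (any gid, padded query path)
        n_support = sum(1 for _ in index.forest.iter_support(qdd))
        assert n_support == index.domain.total_vertices * len(feats.total)
        for path in feats.total:
            a = encode_assignment(0, path, index.l_p)
            assert index.forest.evaluate(qdd, a) == 1

    def test_prune_pointwise(self, tiny_collection):
        """pruned(a) = index(a) if a encodes a query path, else 0."""
        index = build_index(tiny_collection, 3)
        q = _graph(["A", "B", "B"], [(0, 1), (1, 2)])
        feats = extract_query_features(q, tiny_collection.alphabet, 3)
        pruned = prune(index, build_query_mdd(feats, index))
        pruned_support = dict(index.forest.iter_support(pruned))
        for assignment, value in index.forest.iter_support(index.root):
            gid = assignment[0]
            path = tuple(c for c in assignment[1:] if c != 0)
            if path in feats.total:
                assert pruned_support.pop(assignment) == value
        assert not pruned_support  # support subset of the index support

    def test_disjoint_query_annihilates(self, tiny_collection):
        from pathmdd import QueryFeatures

        index = build_index(tiny_collection, 2)
        # the C-C path never occurs in the tiny collection, so a feature set
        # sharing nothing with the index multiplies to the zero diagram
        c = tiny_collection.alphabet.code("C")
        feats = QueryFeatures(total={(c, c): 1}, n_query_vertices=2)
        pruned = prune(index, build_query_mdd(feats, index))
        assert pruned == index.forest.zero()
        assert all(
            not s for s in candidate_vertices(pruned, index).values()
        )

    def test_full_path_set_query_keeps_index(self, tiny_collection):
        """A query containing every index path prunes nothing."""
        index = build_index(tiny_collection, 2)
        feats = extract_query_features(
            tiny_collection[2], tiny_collection.alphabet, 2
        )
        # enrich with all other paths by unioning the three graphs' features
        for g in tiny_collection:
            f = extract_query_features(g, tiny_collection.alphabet, 2)
            for p, c in f.total.items():
                feats.total.setdefault(p, c)
        pruned = prune(index, build_query_mdd(feats, index))
        assert pruned == index.root


def test_exact_copy_survives(tiny_collection):
    index = build_index(tiny_collection, 3)
    target = tiny_collection[1]
    q = _graph(target.label_strings(), sorted(target.edges))
    _, report = run_filter(index, q, collection=tiny_collection)
    assert 1 in report.surviving
    for qv, images in report.candidates[1].items():
        # the identity self-match guarantees the vertex's own image survives
        assert qv in images


def test_missing_path_removes_graph(tiny_collection):
    index = build_index(tiny_collection, 3)
    # star query A(B,B,C) fits the star graph only
    q = _graph(["A", "B", "B", "C"], [(0, 1), (0, 2), (0, 3)])
    _, report = run_filter(index, q, collection=tiny_collection)
    assert report.surviving == [1]


@pytest.mark.parametrize("backend", ["mtmdd", "trie"])
@pytest.mark.parametrize("seed", [3, 14, 159])
def test_filter_soundness_no_false_dismissals(seed, backend):
    """Every graph with a monomorphism survives; every matched image of a
    query vertex lies in that vertex's candidate set."""
    rng = np.random.default_rng(seed)
    coll = generate_collection(
        4, seed=seed, n_range=(12, 30), label_pct=0.15
    )
    origin = int(rng.integers(len(coll)))
    q = extract_query(coll[origin], 4, mode="vertices", seed=seed)
    index = (
        build_trie_index(coll, 3) if backend == "trie" else build_index(coll, 3)
    )
    _, report = run_filter(index, q, collection=coll)
    for i, g in enumerate(coll):
        matches = oracle_monomorphisms(q, g)
        if matches:
            assert i in report.surviving
            for m in matches:
                for qv, tv in m.items():
                    assert tv in report.candidates[i][qv]


def test_backend_equivalence(seeded_collection):
    index = build_index(seeded_collection, 3)
    trie_index = build_trie_index(seeded_collection, 3)
    for seed in range(5):
        q = extract_query(seeded_collection[seed % 4], 4, seed=seed)
        _, a = run_filter(index, q, collection=seeded_collection)
        _, b = run_filter(trie_index, q, collection=seeded_collection)
        assert a.surviving == b.surviving
        assert a.candidates == b.candidates
        assert {i: sorted(map(sorted, c)) for i, c in a.components.items()} == {
            i: sorted(map(sorted, c)) for i, c in b.components.items()
        }


def test_monotonicity_adding_target_edges():
    """Adding edges to a surviving target never removes it."""
    coll = generate_collection(1, seed=4, n_range=(15, 15), label_pct=0.2)
    g = coll[0]
    q = extract_query(g, 4, seed=2)
    rng = np.random.default_rng(0)
    extra = set(g.edges)
    non_edges = [
        (u, v)
        for u in range(g.n_vertices)
        for v in range(u + 1, g.n_vertices)
        if (u, v) not in extra
    ]
    rng.shuffle(non_edges)
    extra.update(non_edges[:10])
    denser = build_collection([(g.name, g.label_strings(), sorted(extra))])
    for target in (coll, denser):
        index = build_index(target, 3)
        _, report = run_filter(index, q, collection=target)
        assert 0 in report.surviving


def test_small_components_are_dropped():
    # two disjoint A-B dumbbells in one graph; query is a 4-vertex chain,
    # so 2-vertex components cannot host it
    coll = build_collection(
        [
            (
                "two_pairs",
                ["A", "B", "A", "B", "C"],
                [(0, 1), (2, 3), (0, 4), (2, 4)],
            )
        ]
    )
    q = _graph(["A", "B"], [(0, 1)])
    index = build_index(coll, 2)
    _, report = run_filter(index, q, collection=coll)
    assert 0 in report.surviving
    for comp in report.components[0]:
        assert len(comp) >= 2
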