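"""Index construction: encoding, trie equivalence, additivity, save/load."""

import pytest

from pathmdd import (
    build_collection,
    build_index,
    build_trie_index,
    decode_assignment,
    encode_assignment,
    generate_collection,
    load_index,
    save_index,
)
from pathmdd.indexing import IndexFormatError

from _oracles import oracle_collection_counts, oracle_graph_path_counts


def test_encode_layout():
    assert encode_assignment(4, (1, 2), 4) == (4, 1, 2, 0, 0)
    assert encode_assignment(0, (3, 1, 2, 2), 4) == (0, 3, 1, 2, 2)
    with pytest.raises(ValueError):
        encode_assignment(0, (1, 2, 3), 2)


@pytest.mark.parametrize(
    "gid,path", [(0, (1,)), (7, (2, 1)), (3, (1, 1, 1)), (12, (4, 2, 3, 1))]
)
def test_decode_inverts_encode(gid, path):
    assert decode_assignment(encode_assignment(gid, path, 4)) == (gid, path)


def test_decode_rejects_interior_padding():
    with pytest.raises(ValueError):
        decode_assignment((0, 1, 0, 2))


def test_single_vertex_collection():
    coll = build_collection([("dot", ["A"], [])])
    index = build_index(coll, 3)
    support = list(index.forest.iter_support(index.root))
    assert support == [((0, 1, 0, 0), 1)]


def _assert_index_equals_oracle(coll, l_p):
    index = build_index(coll, l_p)
    expected = oracle_collection_counts(coll, l_p)
    got = {(gid, path): c for gid, path, c in index.iter_entries()}
    assert got == expected
    return index


@pytest.mark.parametrize("seed,l_p", [(2, 2), (13, 3), (77, 4)])
def test_index_equals_trie_oracle(seed, l_p):
    """Central correctness property: the diagram stores exactly the
    brute-force per-vertex path-count table (and 0 elsewhere)."""
    coll = generate_collection(3, seed=seed, n_range=(15, 40), label_pct=0.15)
    index = _assert_index_equals_oracle(coll, l_p)
    trie_index = build_trie_index(coll, l_p)
    for gid, path, count in trie_index.iter_entries():
        assert index.vertex_path_count(gid, path) == count


def test_per_graph_counts(tiny_collection):
    index = build_index(tiny_collection, 3)
    # triangle A,B,B: two A->B paths
    assert index.per_graph_path_count(0, (1, 2)) == 2
    # path absent from a graph
    assert index.per_graph_path_count(1, (2, 2)) == 0
    for i, g in enumerate(tiny_collection):
        for path, count in oracle_graph_path_counts(g, 3).items():
            assert index.per_graph_path_count(i, path) == count


def test_build_order_invariance():
    """Shuffling the graph order yields the same diagram up to the global
    enumeration; with the same order, rebuild gives the identical root."""
    coll = generate_collection(3, seed=9, n_range=(10, 20))
    a = build_index(coll, 3)
    b = build_index(coll, 3)
    # rebuilding in a fresh forest: compare canonical serialisations
    from pathmdd import serialize

    assert serialize(a.forest, a.root) == serialize(b.forest, b.root)


def test_additivity_of_subcollection_indexes():
    """Index({g1}) + Index({g2}) (on the shared enumeration) = Index({g1,g2})."""
    coll = generate_collection(2, seed=31, n_range=(8, 15))
    full = build_index(coll, 3)
    # build per-graph partial indexes inside one forest over the full domain
    forest = full.forest.__class__(full.domain.sizes)
    partials = []
    for i, g in enumerate(coll):
        sub = build_collection(
            [(g.name, g.label_strings(), sorted(g.edges))]
        )
        sub_index = build_index(sub, 3)
        offset = coll.vertex_offsets[i]
        rows = [
            ((offset + assignment[0],) + assignment[1:], value)
            for assignment, value in sub_index.forest.iter_support(sub_index.root)
        ]
        partials.append(forest.create_edge(rows))
    merged = forest.apply("plus", partials[0], partials[1])
    assert dict(forest.iter_support(merged)) == dict(
        full.forest.iter_support(full.root)
    )


def test_padding_is_always_a_suffix(seeded_collection):
    index = build_index(seeded_collection, 4)
    for assignment, _value in index.forest.iter_support(index.root):
        decode_assignment(assignment)  # raises on interior padding


def test_compression_bound_on_index(seeded_collection):
    index = build_index(seeded_collection, 3)
    nodes, _, _ = index.node_count()
    assert nodes <= index.forest.decision_tree_size(index.root)


class TestSaveLoad:
    def test_round_trip(self, tmp_path, seeded_collection):
        index = build_index(seeded_collection, 3)
        path = tmp_path / "coll.index"
        save_index(index, path)
        back = load_index(path)
        assert back.l_p == index.l_p
        assert back.graph_names == index.graph_names
        assert back.vertex_offsets == index.vertex_offsets
        assert back.alphabet == index.alphabet
        assert dict(((g, p), c) for g, p, c in back.iter_entries()) == dict(
            ((g, p), c) for g, p, c in index.iter_entries()
        )
        assert back.node_count() == index.node_count()

    def test_inconsistent_metadata_rejected(self, tmp_path, tiny_collection):
        index = build_index(tiny_collection, 2)
        path = tmp_path / "x.index"
        save_index(index, path)
        text = path.read_text()
        path.write_text(text.replace("lp: 2", "lp: 3"))
        with pytest.raises(IndexFormatError):
            load_index(path)

    def test_empty_or_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "empty.index"
        path.write_text("")
        with pytest.raises(IndexFormatError):
            load_index(path)
        path.write_text("### META\nlp: 2\n")
        with pytest.raises(IndexFormatError):
            load_index(path)
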