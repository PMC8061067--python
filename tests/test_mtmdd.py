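"""Decision-diagram engine: semantics, canonicity, operators, serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathmdd import MddForest, MddFormatError, deserialize, serialize

from _oracles import all_assignments, lookup_table, random_function_rows


def test_zero_diagram_defaults():
    f = MddForest([2, 3, 4])
    zero = f.create_edge([])
    assert zero == f.zero()
    for a in all_assignments(f.domain):
        assert f.evaluate(zero, a) == 0
    # quasi-reduction: one redundant node per level
    nodes, edges, terminals = f.node_count(zero)
    assert (nodes, terminals) == (3, 1)
    assert edges == 2 + 3 + 4


def test_multiset_membership_example():
    """A single tuple with three occurrences: nonzero only at that tuple."""
    # domain root-first: x4 in {0..3}, x3 in {0..3}, x2 in {0..2}, x1 in {0,1}
    f = MddForest([4, 4, 3, 2])
    d = f.create_edge([((2, 3, 0, 1), 3)])
    assert f.evaluate(d, (2, 3, 0, 1)) == 3
    assert sum(1 for _ in f.iter_support(d)) == 1


def test_forced_two_variable_function():
    f = MddForest([2, 2])
    d = f.create_edge([((0, 0), 7)])
    assert f.evaluate(d, (0, 0)) == 7
    assert f.evaluate(d, (0, 1)) == 0
    assert f.evaluate(d, (1, 0)) == 0


def test_create_edge_rejects_bad_rows():
    f = MddForest([2, 2])
    with pytest.raises(ValueError):
        f.create_edge([((0, 5), 1)])           # out-of-range component
    with pytest.raises(ValueError):
        f.create_edge([((0, 0), -1)])          # negative value
    with pytest.raises(ValueError):
        f.create_edge([((0, 0), 1), ((0, 0), 2)])  # duplicate assignment


@pytest.mark.parametrize("seed", range(6))
def test_exhaustive_lookup_semantics(seed):
    """create_edge / evaluate / plus / times agree with plain tables."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 5))
    domain = [int(rng.integers(2, 7)) for _ in range(k)]
    rows1 = random_function_rows(rng, domain, int(rng.integers(1, 40)))
    rows2 = random_function_rows(rng, domain, int(rng.integers(1, 40)))
    f = MddForest(domain)
    d1, d2 = f.create_edge(rows1), f.create_edge(rows2)
    t1, t2 = lookup_table(rows1), lookup_table(rows2)
    d_plus = f.apply("plus", d1, d2)
    d_times = f.apply("times", d1, d2)
    for a in all_assignments(domain):
        assert f.evaluate(d1, a) == t1(a)
        assert f.evaluate(d2, a) == t2(a)
        assert f.evaluate(d_plus, a) == t1(a) + t2(a)
        assert f.evaluate(d_times, a) == t1(a) * t2(a)


def test_operator_identities(rng):
    f = MddForest([3, 3, 3])
    d = f.create_edge(random_function_rows(rng, f.domain, 10))
    zero = f.zero()
    assert f.apply("times", d, zero) == zero
    assert f.apply("plus", d, zero) == d


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10_000), st.permutations(range(8)))
def test_canonicity_under_row_shuffles(seed, order):
    """Any construction order of the same function gives the identical root."""
    rng = np.random.default_rng(seed)
    domain = [3, 4, 2]
    rows = random_function_rows(rng, domain, 8)
    f = MddForest(domain)
    reference = f.create_edge(rows)
    shuffled = [rows[i] for i in order if i < len(rows)]
    shuffled += [r for r in rows if r not in shuffled]
    assert f.create_edge(shuffled) == reference
    assert f.node_count(f.create_edge(shuffled)) == f.node_count(reference)


def test_unique_table_has_no_duplicates(rng):
    f = MddForest([4, 4, 4])
    for _ in range(10):
        d1 = f.create_edge(random_function_rows(rng, f.domain, 15))
        d2 = f.create_edge(random_function_rows(rng, f.domain, 15))
        f.apply("plus", d1, d2)
        f.apply("times", d1, d2)
    assert f.scan_unique_table() == len(f)


def test_correctness_does_not_depend_on_cache(rng):
    f = MddForest([3, 3])
    d1 = f.create_edge(random_function_rows(rng, f.domain, 5))
    d2 = f.create_edge(random_function_rows(rng, f.domain, 5))
    first = f.apply("plus", d1, d2)
    f.clear_cache()
    assert f.apply("plus", d1, d2) == first


def test_compression_bound_against_decision_tree(rng):
    """Sharing can only shrink: DAG nodes <= unfolded decision-tree nodes."""
    for _ in range(20):
        k = int(rng.integers(2, 5))
        domain = [int(rng.integers(2, 6)) for _ in range(k)]
        f = MddForest(domain)
        d = f.create_edge(random_function_rows(rng, domain, int(rng.integers(0, 60))))
        nodes, _, _ = f.node_count(d)
        assert nodes <= f.decision_tree_size(d)


def test_iter_support_matches_rows(rng):
    domain = [4, 3, 5]
    rows = random_function_rows(rng, domain, 25)
    f = MddForest(domain)
    d = f.create_edge(rows)
    support = dict(f.iter_support(d))
    assert support == {a: v for a, v in rows if v != 0}


class TestSerialization:
    def test_round_trip_zero(self):
        f = MddForest([2, 3])
        text = serialize(f, f.zero())
        g, root = deserialize(text)
        assert g.domain == f.domain
        assert root == g.zero()
        assert g.node_count(root) == f.node_count(f.zero())

    @pytest.mark.parametrize("seed", [0, 17])
    def test_round_trip_random(self, seed):
        rng = np.random.default_rng(seed)
        domain = [3, 4, 3, 2]
        rows = random_function_rows(rng, domain, 30)
        f = MddForest(domain)
        d = f.create_edge(rows)
        g, back = deserialize(serialize(f, d))
        for a in all_assignments(domain):
            assert g.evaluate(back, a) == f.evaluate(d, a)
        assert g.node_count(back) == f.node_count(d)
        # deterministic numbering: same function serialises byte-identically
        assert serialize(g, back) == serialize(f, d)

    def test_round_trip_into_same_forest_is_identity(self, rng):
        f = MddForest([3, 3])
        d = f.create_edge(random_function_rows(rng, f.domain, 6))
        _, back = deserialize(serialize(f, d), forest=f)
        assert back == d

    def test_truncated_file_rejected(self):
        f = MddForest([2, 2])
        text = serialize(f, f.zero())
        lines = text.strip().splitlines()
        with pytest.raises(MddFormatError):
            deserialize("\n".join(lines[:-1]) + "\n")  # missing root trailer
        with pytest.raises(MddFormatError):
            deserialize("levels 2\n")

    def test_domain_mismatch_on_load(self):
        f = MddForest([2, 2])
        text = serialize(f, f.zero())
        other = MddForest([3, 2])
        with pytest.raises(MddFormatError):
            deserialize(text, forest=other)
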