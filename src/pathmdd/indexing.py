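"""Building the labelled-path index as a decision diagram.

The index encodes the function

    (start vertex global id, sigma_1, ..., sigma_lp)  ->  occurrence count

over ``l_p + 1`` variables: the root-level variable ranges over the global
vertex enumeration of the whole collection, the ``l_p`` label variables range
over the label codes plus the reserved padding value 0.  A path shorter than
``l_p`` is right-padded with 0s, so padding zeros always form a suffix.

Construction is incremental, one graph at a time: vertices are grouped by
label, each group's paths are counted in a temporary trie, converted into a
diagram with ``create_edge`` and merged into the accumulator with the
pointwise addition operator; the temporaries are then discarded.  A
whole-collection trie backend (:class:`TrieIndex`) is retained as the
reference baseline and oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graphs import GraphCollection, LabelAlphabet, LabelledGraph
from .mtmdd import MddForest, MddFormatError, deserialize, serialize
from .paths import PathTable, Trie, build_collection_table, build_path_table

__all__ = [
    "IndexDomain",
    "GraphIndex",
    "TrieIndex",
    "encode_assignment",
    "decode_assignment",
    "build_index",
    "build_trie_index",
    "save_index",
    "load_index",
    "IndexFormatError",
]

PADDING = 0

Path = tuple[int, ...]


class IndexFormatError(ValueError):
    """Malformed or inconsistent index file."""


@dataclass(frozen=True)
class IndexDomain:
    """Variable layout of the index diagram.

    Root-first order: one vertex variable with range ``total_vertices``, then
    ``l_p`` label variables each with range ``n_labels + 1`` (value 0 is the
    padding symbol for paths shorter than ``l_p``).
    """

    l_p: int
    total_vertices: int
    n_labels: int

    def __post_init__(self) -> None:
        if self.l_p < 1:
            raise ValueError("l_p must be >= 1")
        if self.total_vertices < 1:
            raise ValueError("the collection must contain at least one vertex")
        if self.n_labels < 1:
            raise ValueError("the alphabet must contain at least one label")

    @property
    def sizes(self) -> tuple[int, ...]:
        return (self.total_vertices,) + (self.n_labels + 1,) * self.l_p


def encode_assignment(gid: int, path: Path, l_p: int) -> tuple[int, ...]:
    """(gid, sigma_1..sigma_l, 0, ..., 0) with l_p - l trailing padding zeros."""
    if len(path) > l_p:
        raise ValueError(f"path of length {len(path)} exceeds l_p={l_p}")
    if not path:
        raise ValueError("paths are nonempty")
    return (gid,) + tuple(path) + (PADDING,) * (l_p - len(path))


def decode_assignment(assignment: tuple[int, ...]) -> tuple[int, Path]:
    """Inverse of :func:`encode_assignment`; validates padding discipline."""
    gid, labels = assignment[0], assignment[1:]
    path: list[int] = []
    in_padding = False
    for code in labels:
        if code == PADDING:
            in_padding = True
        else:
            if in_padding:
                raise ValueError(
                    f"assignment {assignment} has a label after a padding zero"
                )
            path.append(code)
    if not path:
        raise ValueError(f"assignment {assignment} encodes an empty path")
    return gid, tuple(path)


class GraphIndex:
    """The decision-diagram index of a graph collection.

    Evaluating the diagram at ``encode_assignment(gid, path, l_p)`` gives the
    number of occurrences of the labelled *path* starting at the global
    vertex *gid*; unrecorded assignments evaluate to 0.
    """

    def __init__(
        self,
        forest: MddForest,
        root: int,
        domain: IndexDomain,
        alphabet: LabelAlphabet,
        vertex_offsets: tuple[int, ...],
        graph_names: tuple[str, ...],
        graph_sizes: tuple[int, ...],
    ) -> None:
        self.forest = forest
        self.root = root
        self.domain = domain
        self.alphabet = alphabet
        self.vertex_offsets = vertex_offsets
        self.graph_names = graph_names
        self.graph_sizes = graph_sizes
        self.l_p = domain.l_p

    @property
    def n_graphs(self) -> int:
        return len(self.graph_names)

    def vertex_path_count(self, gid: int, path: Path) -> int:
        """Occurrences of *path* starting at global vertex *gid*."""
        return self.forest.evaluate(
            self.root, encode_assignment(gid, path, self.l_p)
        )

    def per_graph_path_count(self, graph_index: int, path: Path) -> int:
        """Whole-graph occurrence count: sum over the graph's vertices."""
        offset = self.vertex_offsets[graph_index]
        size = self.graph_sizes[graph_index]
        forest, root, l_p = self.forest, self.root, self.l_p
        return sum(
            forest.evaluate(root, encode_assignment(offset + v, path, l_p))
            for v in range(size)
        )

    def graph_of_gid(self, gid: int) -> tuple[int, int]:
        """Global id -> (graph index, local vertex index)."""
        offsets = self.vertex_offsets
        lo, hi = 0, len(offsets) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if offsets[mid] <= gid:
                lo = mid
            else:
                hi = mid - 1
        return lo, gid - offsets[lo]

    def node_count(self) -> tuple[int, int, int]:
        return self.forest.node_count(self.root)

    def iter_entries(self):
        """Yield (gid, path, count) over the nonzero support."""
        for assignment, value in self.forest.iter_support(self.root):
            gid, path = decode_assignment(assignment)
            yield gid, path, value


class TrieIndex:
    """Whole-collection trie/path-table baseline with the same count API.

    Functionally equivalent to :class:`GraphIndex`; used as the reference
    backend and as the comparator for compression measurements.
    """

    def __init__(
        self,
        table: PathTable,
        trie: Trie,
        alphabet: LabelAlphabet,
        vertex_offsets: tuple[int, ...],
        graph_names: tuple[str, ...],
        graph_sizes: tuple[int, ...],
        l_p: int,
    ) -> None:
        self.table = table
        self.trie = trie
        self.alphabet = alphabet
        self.vertex_offsets = vertex_offsets
        self.graph_names = graph_names
        self.graph_sizes = graph_sizes
        self.l_p = l_p
        self._per_graph: dict[tuple[int, Path], int] = {}
        for gid, path, count in table.items():
            i = self._graph_of(gid)
            key = (i, path)
            self._per_graph[key] = self._per_graph.get(key, 0) + count

    def _graph_of(self, gid: int) -> int:
        offsets = self.vertex_offsets
        lo, hi = 0, len(offsets) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if offsets[mid] <= gid:
                lo = mid
            else:
                hi = mid - 1
        return lo

    @property
    def n_graphs(self) -> int:
        return len(self.graph_names)

    def graph_of_gid(self, gid: int) -> tuple[int, int]:
        i = self._graph_of(gid)
        return i, gid - self.vertex_offsets[i]

    def vertex_path_count(self, gid: int, path: Path) -> int:
        return self.table.get(gid, path)

    def per_graph_path_count(self, graph_index: int, path: Path) -> int:
        return self._per_graph.get((graph_index, path), 0)

    def iter_entries(self):
        yield from self.table.items()


def build_index(collection: GraphCollection, l_p: int) -> GraphIndex:
    """Build the index diagram for *collection* with maximum path length *l_p*.

    One graph at a time: vertices grouped by label; per group a path table is
    filled by depth-limited search, poured into a temporary trie, converted
    to a diagram and merged into the accumulator by pointwise addition.
    """
    if len(collection) == 0:
        raise ValueError("cannot index an empty collection")
    if l_p < 1:
        raise ValueError("l_p must be >= 1")
    domain = IndexDomain(
        l_p=l_p,
        total_vertices=collection.total_vertices,
        n_labels=len(collection.alphabet),
    )
    forest = MddForest(domain.sizes)
    accumulator = forest.zero()
    for i, graph in enumerate(collection):
        offset = collection.vertex_offsets[i]
        groups: dict[int, list[int]] = {}
        for v in range(graph.n_vertices):
            groups.setdefault(graph.labels[v], []).append(v)
        for label in sorted(groups):
            table = build_path_table(graph, groups[label], l_p, offset)
            trie = Trie.from_table(table)
            rows = [
                (encode_assignment(gid, path, l_p), count)
                for path, gid, count in trie.items()
            ]
            partial = forest.create_edge(rows)
            accumulator = forest.apply("plus", accumulator, partial)
            del table, trie, rows, partial
    return GraphIndex(
        forest=forest,
        root=accumulator,
        domain=domain,
        alphabet=collection.alphabet,
        vertex_offsets=collection.vertex_offsets,
        graph_names=tuple(g.name for g in collection),
        graph_sizes=tuple(g.n_vertices for g in collection),
    )


def build_trie_index(collection: GraphCollection, l_p: int) -> TrieIndex:
    """Build the whole-collection trie baseline over the same features."""
    if len(collection) == 0:
        raise ValueError("cannot index an empty collection")
    table = build_collection_table(collection, l_p)
    trie = Trie.from_table(table)
    return TrieIndex(
        table=table,
        trie=trie,
        alphabet=collection.alphabet,
        vertex_offsets=collection.vertex_offsets,
        graph_names=tuple(g.name for g in collection),
        graph_sizes=tuple(g.n_vertices for g in collection),
        l_p=l_p,
    )


META_SEPARATOR = "### META"


def save_index(index: GraphIndex, path) -> None:
    """Store the index: diagram text, then a metadata block.

    Metadata lines are ``key: value``; label and graph lines put the
    free-form string last so it may contain spaces.
    """
    dd_text = serialize(index.forest, index.root)
    meta: list[str] = [META_SEPARATOR, f"lp: {index.l_p}"]
    for label, code in sorted(index.alphabet.items(), key=lambda kv: kv[1]):
        meta.append(f"label: {code} {label}")
    for name, size in zip(index.graph_names, index.graph_sizes):
        meta.append(f"graph: {size} {name}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dd_text)
        fh.write("\n".join(meta) + "\n")


def load_index(path) -> GraphIndex:
    """Load an index written by :func:`save_index`; validates consistency."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if META_SEPARATOR not in text:
        raise IndexFormatError("missing metadata block")
    dd_text, meta_text = text.split(META_SEPARATOR, 1)
    if not dd_text.strip():
        raise IndexFormatError("empty diagram section")
    l_p: int | None = None
    labels: dict[int, str] = {}
    graph_names: list[str] = []
    graph_sizes: list[int] = []
    for line in meta_text.splitlines():
        line = line.strip()
        if not line:
            continue
        key, _, rest = line.partition(":")
        rest = rest.strip()
        if key == "lp":
            try:
                l_p = int(rest)
            except ValueError:
                raise IndexFormatError(f"malformed lp line {line!r}") from None
        elif key == "label":
            code_str, _, label = rest.partition(" ")
            try:
                code = int(code_str)
            except ValueError:
                raise IndexFormatError(f"malformed label line {line!r}") from None
            labels[code] = label
        elif key == "graph":
            size_str, _, name = rest.partition(" ")
            try:
                graph_sizes.append(int(size_str))
            except ValueError:
                raise IndexFormatError(f"malformed graph line {line!r}") from None
            graph_names.append(name)
        else:
            raise IndexFormatError(f"unknown metadata key {key!r}")
    if l_p is None:
        raise IndexFormatError("metadata missing lp")
    if not labels:
        raise IndexFormatError("metadata lists no labels")
    if not graph_names:
        raise IndexFormatError("metadata lists no graphs")
    if sorted(labels) != list(range(1, len(labels) + 1)):
        raise IndexFormatError("label codes must be contiguous from 1")
    alphabet = LabelAlphabet()
    for code in range(1, len(labels) + 1):
        if alphabet.intern(labels[code]) != code:
            raise IndexFormatError(f"duplicate label string {labels[code]!r}")
    try:
        forest, root = deserialize(dd_text)
    except MddFormatError as exc:
        raise IndexFormatError(f"bad diagram section: {exc}") from exc
    total = sum(graph_sizes)
    domain = IndexDomain(l_p=l_p, total_vertices=total, n_labels=len(labels))
    if forest.domain != domain.sizes:
        raise IndexFormatError(
            f"diagram domain {forest.domain} inconsistent with metadata"
            f" (expected {domain.sizes})"
        )
    offsets = []
    acc = 0
    for size in graph_sizes:
        offsets.append(acc)
        acc += size
    return GraphIndex(
        forest=forest,
        root=root,
        domain=domain,
        alphabet=alphabet,
        vertex_offsets=tuple(offsets),
        graph_names=tuple(graph_names),
        graph_sizes=tuple(graph_sizes),
    )
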