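"""Labelled-path features: depth-limited enumeration, count tables and tries.

The indexing feature is the *labelled path*: the sequence of vertex labels
along a simple path (no repeated vertex) of at most ``l_p`` vertices.  For
each start vertex the index records, per distinct label sequence, the number
of distinct vertex sequences realising it — the occurrence count.  Paths of
every length 1..l_p are recorded, so short paths are first-class features,
not only prefixes of longer ones.

Counts are first accumulated in a :class:`PathTable`; a prefix-compressed
:class:`Trie` stores the same information and doubles as the reference
baseline that the decision-diagram index is checked against.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

from .graphs import GraphCollection, LabelledGraph

__all__ = [
    "enumerate_paths",
    "PathTable",
    "build_path_table",
    "build_collection_table",
    "Trie",
    "trie_insert",
    "trie_stats",
]

DEFAULT_LP = 4

Path = tuple[int, ...]


def enumerate_paths(
    graph: LabelledGraph, start: int, l_p: int
) -> Iterator[tuple[Path, int]]:
    """Yield every simple path of 1..l_p vertices beginning at *start*.

    Each yield is ``(label sequence, terminal vertex)``; one yield per
    distinct *vertex* sequence, so a label sequence repeats as many times as
    it has realisations — that multiplicity is the occurrence count.
    Neighbours are explored in ascending index order, so the yield order is
    deterministic.
    """
    if not 0 <= start < graph.n_vertices:
        raise IndexError(f"start vertex {start} out of range")
    if l_p < 1:
        raise ValueError("l_p must be >= 1")
    labels = graph.labels
    # iterative DFS over simple paths; stack holds (vertex, depth)
    path_vertices = [start]
    path_labels = [labels[start]]
    on_path = [False] * graph.n_vertices
    on_path[start] = True
    yield (labels[start],), start

    def _extend() -> Iterator[tuple[Path, int]]:
        v = path_vertices[-1]
        for w in graph.neighbours(v):
            if on_path[w]:
                continue
            path_vertices.append(w)
            path_labels.append(labels[w])
            on_path[w] = True
            yield tuple(path_labels), w
            if len(path_vertices) < l_p:
                yield from _extend()
            on_path[w] = False
            path_vertices.pop()
            path_labels.pop()

    if l_p > 1:
        yield from _extend()


class PathTable:
    """Mapping (start vertex global id, label sequence) -> occurrence count."""

    __slots__ = ("counts",)

    def __init__(self) -> None:
        self.counts: dict[tuple[int, Path], int] = {}

    def add(self, gid: int, path: Path, count: int = 1) -> None:
        if count < 1:
            raise ValueError("counts must be positive")
        key = (gid, path)
        self.counts[key] = self.counts.get(key, 0) + count

    def get(self, gid: int, path: Path) -> int:
        return self.counts.get((gid, path), 0)

    def items(self) -> Iterator[tuple[int, Path, int]]:
        for (gid, path), count in self.counts.items():
            yield gid, path, count

    def __len__(self) -> int:
        return len(self.counts)

    def merge(self, other: "PathTable") -> None:
        for gid, path, count in other.items():
            self.add(gid, path, count)

    def total_occurrences(self, length: int | None = None) -> int:
        """Total path occurrences, optionally restricted to one length."""
        return sum(
            c
            for (gid, p), c in self.counts.items()
            if length is None or len(p) == length
        )


def build_path_table(
    graph: LabelledGraph,
    vertices: Iterable[int],
    l_p: int,
    offset: int = 0,
) -> PathTable:
    """Aggregate path occurrence counts for a same-label vertex group.

    *offset* is the graph's base in the global vertex enumeration, so table
    keys are global ids.  The group must be label-homogeneous — grouping by
    label is how the index is built incrementally.
    """
    vertices = list(vertices)
    if vertices:
        group_labels = {graph.labels[v] for v in vertices}
        if len(group_labels) != 1:
            raise ValueError(f"vertex group mixes labels {sorted(group_labels)}")
    table = PathTable()
    for v in vertices:
        gid = offset + v
        for path, _end in enumerate_paths(graph, v, l_p):
            table.add(gid, path)
    return table


def build_collection_table(collection: GraphCollection, l_p: int) -> PathTable:
    """Whole-collection path table over the global vertex enumeration."""
    table = PathTable()
    for i, g in enumerate(collection):
        offset = collection.vertex_offsets[i]
        for v in range(g.n_vertices):
            gid = offset + v
            for path, _end in enumerate_paths(g, v, l_p):
                table.add(gid, path)
    return table


class _TrieNode:
    __slots__ = ("children", "payload")

    def __init__(self) -> None:
        self.children: dict[int, "_TrieNode"] = {}
        self.payload: dict[int, int] = {}


class Trie:
    """Prefix-compressed store of labelled paths with per-start-vertex counts.

    Each edge carries one label code; a node's payload maps start global id
    to the aggregated count of the path spelled by the root-to-node labels.
    Children are iterated in ascending label code so stats and serialisation
    are deterministic.
    """

    def __init__(self) -> None:
        self.root = _TrieNode()

    def insert(self, path: Path, start: int, count: int = 1) -> None:
        trie_insert(self, path, start, count)

    def lookup(self, path: Path) -> dict[int, int] | None:
        """Payload at *path* (start gid -> count), or None if absent/empty."""
        node = self.root
        for code in path:
            node = node.children.get(code)
            if node is None:
                return None
        return dict(node.payload) if node.payload else None

    def items(self) -> Iterator[tuple[Path, int, int]]:
        """Yield (path, start gid, count), paths in lexicographic order."""
        stack: list[int] = []

        def walk(node: _TrieNode) -> Iterator[tuple[Path, int, int]]:
            if node.payload:
                path = tuple(stack)
                for gid in sorted(node.payload):
                    yield path, gid, node.payload[gid]
            for code in sorted(node.children):
                stack.append(code)
                yield from walk(node.children[code])
                stack.pop()

        yield from walk(self.root)

    def stats(self) -> tuple[int, int, int]:
        return trie_stats(self)

    def to_text(self) -> str:
        """Dump as indented text (one node per line) for debugging/storage."""
        out: list[str] = ["trie"]

        def walk(node: _TrieNode, depth: int) -> None:
            for code in sorted(node.children):
                child = node.children[code]
                payload = " ".join(
                    f"{gid}:{child.payload[gid]}" for gid in sorted(child.payload)
                )
                suffix = f" [{payload}]" if payload else ""
                out.append(f"{'  ' * depth}{code}{suffix}")
                walk(child, depth + 1)

        walk(self.root, 1)
        return "\n".join(out) + "\n"

    @classmethod
    def from_table(cls, table: PathTable) -> "Trie":
        trie = cls()
        for gid, path, count in table.items():
            trie.insert(path, gid, count)
        return trie


def trie_insert(trie: Trie, path: Path, start: int, count: int = 1) -> None:
    """Walk/create the label chain of *path* and add *count* for *start*."""
    if count < 1:
        raise ValueError("counts must be positive")
    if not path:
        raise ValueError("paths are nonempty")
    node = trie.root
    for code in path:
        nxt = node.children.get(code)
        if nxt is None:
            nxt = _TrieNode()
            node.children[code] = nxt
        node = nxt
    node.payload[start] = node.payload.get(start, 0) + count


def trie_stats(trie: Trie) -> tuple[int, int, int]:
    """(node count excluding root, link count, payload entry count)."""
    nodes = 0
    links = 0
    payload_entries = 0
    stack = [trie.root]
    while stack:
        node = stack.pop()
        links += len(node.children)
        payload_entries += len(node.payload)
        for child in node.children.values():
            nodes += 1
            stack.append(child)
    return nodes, links, payload_entries
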