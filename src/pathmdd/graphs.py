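"""Vertex-labelled undirected graphs, label alphabets and the .gfu text format.

A graph collection is an ordered sequence of vertex-labelled graphs sharing a
single label alphabet.  Vertices of every graph are additionally enumerated
globally: vertex ``v`` of graph ``i`` has global id ``vertex_offsets[i] + v``,
so the global ids of a collection with graph sizes 6, 5, 4 are 0..14 with
offsets (0, 6, 11).  The global enumeration is what the decision-diagram index
stores on its vertex level.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

__all__ = [
    "GfuParseError",
    "LabelAlphabet",
    "LabelledGraph",
    "GraphCollection",
    "build_collection",
    "read_collection",
    "parse_collection",
    "write_collection",
    "format_collection",
    "global_to_local",
]

#: code reserved for the "unlabelled" padding symbol of the path index.
PADDING_CODE = 0


class GfuParseError(ValueError):
    """Raised on a malformed .gfu file; carries the offending 1-based line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LabelAlphabet:
    """Bijection between raw label strings and integer codes >= 1.

    Codes are assigned in order of first appearance; code 0 is reserved for
    the padding symbol and is never assigned to a real label.
    """

    def __init__(self) -> None:
        self._to_code: dict[str, int] = {}
        self._to_str: dict[int, str] = {}

    def intern(self, label: str) -> int:
        """Return the code of *label*, assigning the next free code if new."""
        code = self._to_code.get(label)
        if code is None:
            code = len(self._to_code) + 1
            self._to_code[label] = code
            self._to_str[code] = label
        return code

    def code(self, label: str) -> int | None:
        """Code of *label*, or ``None`` if the label is unknown."""
        return self._to_code.get(label)

    def string(self, code: int) -> str:
        try:
            return self._to_str[code]
        except KeyError:
            raise KeyError(f"label code {code} not in alphabet") from None

    def __len__(self) -> int:
        return len(self._to_code)

    def __contains__(self, label: str) -> bool:
        return label in self._to_code

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self._to_code.items())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelAlphabet) and self._to_code == other._to_code


class LabelledGraph:
    """An undirected graph whose vertices carry exactly one label each.

    Labels are stored as integer codes relative to ``alphabet``.  Vertex
    indices are 0-based and contiguous; self-loops and parallel edges are
    rejected at construction.
    """

    __slots__ = ("name", "labels", "edges", "alphabet", "_adjacency")

    def __init__(
        self,
        name: str,
        labels: Sequence[int],
        edges: Iterable[tuple[int, int]],
        alphabet: LabelAlphabet,
    ) -> None:
        self.name = name
        self.labels: tuple[int, ...] = tuple(labels)
        n = len(self.labels)
        canon: set[tuple[int, int]] = set()
        for u, v in edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"graph {name!r}: edge ({u},{v}) out of range for {n} vertices")
            if u == v:
                raise ValueError(f"graph {name!r}: self-loop at vertex {u}")
            e = (u, v) if u < v else (v, u)
            if e in canon:
                raise ValueError(f"graph {name!r}: duplicate edge ({u},{v})")
            canon.add(e)
        self.edges: frozenset[tuple[int, int]] = frozenset(canon)
        self.alphabet = alphabet
        for code in self.labels:
            if code < 1:
                raise ValueError(f"graph {name!r}: invalid label code {code}")
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in canon:
            adj[u].append(v)
            adj[v].append(u)
        self._adjacency: tuple[tuple[int, ...], ...] = tuple(
            tuple(sorted(ns)) for ns in adj
        )

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbours(self, v: int) -> tuple[int, ...]:
        return self._adjacency[v]

    def degree(self, v: int) -> int:
        return len(self._adjacency[v])

    def has_edge(self, u: int, v: int) -> bool:
        return ((u, v) if u < v else (v, u)) in self.edges

    def label_string(self, v: int) -> str:
        return self.alphabet.string(self.labels[v])

    def label_strings(self) -> list[str]:
        return [self.alphabet.string(c) for c in self.labels]

    def is_connected(self) -> bool:
        if self.n_vertices == 0:
            return True
        seen = {0}
        stack = [0]
        while stack:
            for w in self._adjacency[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_vertices

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"LabelledGraph({self.name!r}, n={self.n_vertices}, m={self.n_edges})"
        )


class GraphCollection:
    """Ordered sequence of labelled graphs sharing one alphabet.

    Maintains the global vertex enumeration: ``vertex_offsets`` are the prefix
    sums of the graph sizes, and (graph, local vertex) <-> global id is a
    bijection onto 0..total_vertices-1.
    """

    def __init__(self, graphs: Sequence[LabelledGraph], alphabet: LabelAlphabet):
        self.graphs: list[LabelledGraph] = list(graphs)
        self.alphabet = alphabet
        offsets = [0]
        for g in self.graphs:
            offsets.append(offsets[-1] + g.n_vertices)
        self.vertex_offsets: tuple[int, ...] = tuple(offsets[:-1])
        self.total_vertices: int = offsets[-1]

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[LabelledGraph]:
        return iter(self.graphs)

    def __getitem__(self, i: int) -> LabelledGraph:
        return self.graphs[i]

    def global_id(self, graph_index: int, v: int) -> int:
        return self.vertex_offsets[graph_index] + v

    def global_to_local(self, gid: int) -> tuple[int, int]:
        return global_to_local(self, gid)

    def graph_of_gid(self, gid: int) -> int:
        return self.global_to_local(gid)[0]


def global_to_local(collection: GraphCollection, gid: int) -> tuple[int, int]:
    """Invert the global enumeration: global id -> (graph index, local vertex)."""
    if not 0 <= gid < collection.total_vertices:
        raise IndexError(
            f"global vertex id {gid} out of range [0, {collection.total_vertices})"
        )
    # binary search over the prefix sums
    offsets = collection.vertex_offsets
    lo, hi = 0, len(offsets) - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if offsets[mid] <= gid:
            lo = mid
        else:
            hi = mid - 1
    return lo, gid - offsets[lo]


def build_collection(
    records: Iterable[tuple[str, Sequence[str], Iterable[tuple[int, int]]]],
) -> GraphCollection:
    """Assemble a collection from (name, label strings, edge list) records.

    Labels are interned into a fresh shared alphabet in order of first
    appearance across the records.
    """
    alphabet = LabelAlphabet()
    graphs = []
    for name, labels, edges in records:
        codes = [alphabet.intern(s) for s in labels]
        graphs.append(LabelledGraph(name, codes, edges, alphabet))
    return GraphCollection(graphs, alphabet)


# ---------------------------------------------------------------------------
# .gfu dialect
#
# One record per graph, records concatenated:
#   #<name>
#   <n_vertices>
#   <label of vertex 0> ... one line per vertex
#   <n_edges>
#   <u> <v>            one line per undirected edge, 0-based, listed once
# ---------------------------------------------------------------------------


def parse_collection(text: str) -> GraphCollection:
    """Parse the .gfu dialect from a string. See :func:`read_collection`."""
    lines = text.splitlines()
    pos = 0
    n_lines = len(lines)

    def current() -> str:
        return lines[pos]

    records: list[tuple[str, list[str], list[tuple[int, int]]]] = []
    while pos < n_lines and not lines[pos].strip():
        pos += 1
    if pos >= n_lines:
        raise GfuParseError("empty file: no graph records")
    while pos < n_lines:
        if not lines[pos].strip():
            pos += 1
            continue
        header = current().strip()
        if not header.startswith("#"):
            raise GfuParseError(f"expected '#<name>' header, got {header!r}", pos + 1)
        name = header[1:]
        pos += 1
        if pos >= n_lines:
            raise GfuParseError("missing vertex count after header", pos)
        try:
            n_vertices = int(current().strip())
        except ValueError:
            raise GfuParseError(f"malformed vertex count {current()!r}", pos + 1) from None
        if n_vertices < 0:
            raise GfuParseError(f"negative vertex count {n_vertices}", pos + 1)
        pos += 1
        labels: list[str] = []
        for _ in range(n_vertices):
            if pos >= n_lines:
                raise GfuParseError(
                    f"record {name!r}: expected {n_vertices} label lines, file ended", pos
                )
            label = current().strip()
            if not label:
                raise GfuParseError("empty label line", pos + 1)
            labels.append(label)
            pos += 1
        if pos >= n_lines:
            raise GfuParseError(f"record {name!r}: missing edge count", pos)
        try:
            n_edges = int(current().strip())
        except ValueError:
            raise GfuParseError(f"malformed edge count {current()!r}", pos + 1) from None
        pos += 1
        edges: list[tuple[int, int]] = []
        for _ in range(n_edges):
            if pos >= n_lines:
                raise GfuParseError(
                    f"record {name!r}: expected {n_edges} edge lines, file ended", pos
                )
            parts = current().split()
            if len(parts) != 2:
                raise GfuParseError(f"malformed edge line {current()!r}", pos + 1)
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise GfuParseError(f"malformed edge line {current()!r}", pos + 1) from None
            if not (0 <= u < n_vertices and 0 <= v < n_vertices):
                raise GfuParseError(
                    f"edge ({u},{v}) out of range for {n_vertices} vertices", pos + 1
                )
            edges.append((u, v))
            pos += 1
        records.append((name, labels, edges))
    try:
        return build_collection(records)
    except ValueError as exc:
        raise GfuParseError(str(exc)) from exc


def read_collection(path) -> GraphCollection:
    """Read a graph collection from a .gfu-dialect text file.

    Every record becomes one :class:`LabelledGraph`, in file order; labels
    from all records are interned into a single shared alphabet.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    return parse_collection(text)


def format_collection(collection: GraphCollection) -> str:
    """Render a collection in the .gfu dialect (inverse of parsing)."""
    if len(collection) == 0:
        raise ValueError("refusing to write an empty collection")
    out: list[str] = []
    for g in collection:
        out.append(f"#{g.name}")
        out.append(str(g.n_vertices))
        out.extend(g.label_strings())
        edges = sorted(g.edges)
        out.append(str(len(edges)))
        out.extend(f"{u} {v}" for u, v in edges)
    return "\n".join(out) + "\n"


def write_collection(collection: GraphCollection, path) -> None:
    """Write a collection to *path*; round-trips exactly through reading."""
    text = format_collection(collection)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def collections_equal(a: GraphCollection, b: GraphCollection) -> bool:
    """Field-by-field equality: names, label strings, edge sets, order."""
    if len(a) != len(b):
        return False
    for ga, gb in zip(a, b):
        if ga.name != gb.name:
            return False
        if ga.label_strings() != gb.label_strings():
            return False
        if ga.edges != gb.edges:
            return False
    return True
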