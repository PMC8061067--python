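"""A self-contained multi-terminal multi-way decision diagram (MTMDD) engine.

An MTMDD is a rooted ordered DAG encoding a function from finite-domain
variables to nonnegative integers.  This engine implements the
*quasi-reduced* normal form: every root-to-terminal path visits exactly one
node per variable level (redundant nodes are kept, duplicate nodes are merged
through a unique table), which makes equal functions share the identical node
and keeps the binary `apply` recursion level-synchronised.

Conventions
-----------
* A forest is created over a fixed variable order; ``domain`` lists the
  range sizes root-first.  With ``K`` variables, the root level is ``K`` and
  terminals live at level 0.
* Assignments are tuples in root-first variable order.
* Terminal values are exact nonnegative integers (occurrence counts).
* Node handles are plain integers, only meaningful within their forest;
  because of hash-consing, two handles are equal iff the functions they
  represent are pointwise equal.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Sequence

__all__ = [
    "MddForest",
    "MddFormatError",
    "serialize",
    "deserialize",
]


class MddFormatError(ValueError):
    """Malformed textual decision-diagram file."""


_OPS: dict[str, Callable[[int, int], int]] = {
    "plus": lambda a, b: a + b,
    "times": lambda a, b: a * b,
}


class MddForest:
    """A shared store of quasi-reduced MTMDD nodes over one variable order.

    All diagrams built in a forest live in a single multi-rooted DAG held in
    the unique table, so no two structurally identical nodes ever coexist;
    binary operators memoise their recursion in a computed table keyed by
    (operator, operand handles).
    """

    def __init__(self, domain: Sequence[int]):
        self.domain: tuple[int, ...] = tuple(int(n) for n in domain)
        if not self.domain:
            raise ValueError("domain must have at least one variable")
        if any(n < 1 for n in self.domain):
            raise ValueError("all variable range sizes must be >= 1")
        self.K = len(self.domain)
        # per-node storage; index = handle
        self._level: list[int] = []
        self._children: list[tuple[int, ...] | None] = []
        self._value: list[int | None] = []
        self._unique: dict[tuple, int] = {}
        self._cache: dict[tuple, int] = {}
        # canonical zero chain, zero[k] = the identically-zero function at level k
        self._zero: list[int] = [self.terminal(0)]
        for level in range(1, self.K + 1):
            self._zero.append(
                self._make_node(level, (self._zero[level - 1],) * self.size(level))
            )

    # -- structure ----------------------------------------------------------

    def size(self, level: int) -> int:
        """Range size of the variable at *level* (root level = K)."""
        if not 1 <= level <= self.K:
            raise ValueError(f"level {level} out of range 1..{self.K}")
        return self.domain[self.K - level]

    def terminal(self, value: int) -> int:
        """Hash-consed terminal node holding *value* (level 0)."""
        if value < 0:
            raise ValueError("terminal values must be nonnegative integers")
        key = ("t", value)
        handle = self._unique.get(key)
        if handle is None:
            handle = self._new(0, None, value)
            self._unique[key] = handle
        return handle

    def node(self, level: int, children: Sequence[int]) -> int:
        """Hash-consed non-terminal at *level* with the given children.

        Children must all live at ``level - 1`` (quasi-reduced discipline).
        Redundant nodes (all children equal) are kept, not skipped.
        """
        children = tuple(children)
        if len(children) != self.size(level):
            raise ValueError(
                f"level {level} expects {self.size(level)} children, got {len(children)}"
            )
        for c in children:
            if self._level[c] != level - 1:
                raise ValueError(
                    f"child at level {self._level[c]} under a level-{level} node"
                )
        return self._make_node(level, children)

    def _make_node(self, level: int, children: tuple[int, ...]) -> int:
        key = (level, children)
        handle = self._unique.get(key)
        if handle is None:
            handle = self._new(level, children, None)
            self._unique[key] = handle
        return handle

    def _new(self, level: int, children: tuple[int, ...] | None, value: int | None) -> int:
        handle = len(self._level)
        self._level.append(level)
        self._children.append(children)
        self._value.append(value)
        return handle

    def zero(self, level: int | None = None) -> int:
        """The identically-zero function (at the root level by default)."""
        return self._zero[self.K if level is None else level]

    def level_of(self, handle: int) -> int:
        return self._level[handle]

    def children_of(self, handle: int) -> tuple[int, ...]:
        children = self._children[handle]
        if children is None:
            raise ValueError("terminal nodes have no children")
        return children

    def value_of(self, handle: int) -> int:
        value = self._value[handle]
        if value is None:
            raise ValueError("non-terminal nodes carry no value")
        return value

    def __len__(self) -> int:
        return len(self._level)

    # -- construction and evaluation ----------------------------------------

    def _check_assignment(self, assignment: Sequence[int]) -> tuple[int, ...]:
        assignment = tuple(assignment)
        if len(assignment) != self.K:
            raise ValueError(
                f"assignment length {len(assignment)} != number of variables {self.K}"
            )
        for pos, (x, n) in enumerate(zip(assignment, self.domain)):
            if not 0 <= x < n:
                raise ValueError(
                    f"assignment component {x} at position {pos} outside range [0,{n})"
                )
        return assignment

    def create_edge(self, rows: Iterable[tuple[Sequence[int], int]]) -> int:
        """Build the diagram of the function stated explicitly by *rows*.

        Each row is (assignment, value); unspecified assignments evaluate to
        the default 0.  Duplicate assignments and negative values are
        rejected.  The result is quasi-reduced and hash-consed, hence
        canonical: any row order produces the identical handle.
        """
        seen: dict[tuple[int, ...], int] = {}
        for assignment, value in rows:
            assignment = self._check_assignment(assignment)
            if value < 0:
                raise ValueError(f"negative value {value} for assignment {assignment}")
            if assignment in seen:
                raise ValueError(f"duplicate assignment {assignment}")
            seen[assignment] = value
        items = [(a, v) for a, v in seen.items() if v != 0]
        return self._build_rows(self.K, items, 0)

    def _build_rows(
        self, level: int, items: list[tuple[tuple[int, ...], int]], pos: int
    ) -> int:
        """Recursive grouping builder used by create_edge (and friends).

        *items* hold full assignments; *pos* is the coordinate handled at
        *level*.  Empty groups collapse to the canonical zero chain.
        """
        if not items:
            return self._zero[level]
        if level == 0:
            # all assignments exhausted; duplicates were rejected upstream
            return self.terminal(items[0][1])
        buckets: dict[int, list[tuple[tuple[int, ...], int]]] = {}
        for item in items:
            buckets.setdefault(item[0][pos], []).append(item)
        zero_child = self._zero[level - 1]
        children = tuple(
            self._build_rows(level - 1, buckets[i], pos + 1)
            if i in buckets
            else zero_child
            for i in range(self.size(level))
        )
        return self._make_node(level, children)

    def evaluate(self, root: int, assignment: Sequence[int]) -> int:
        """Trace the root-to-terminal path selected by *assignment*."""
        assignment = self._check_assignment(assignment)
        if self._level[root] != self.K:
            raise ValueError("root must be at the top level")
        node = root
        for x in assignment:
            node = self._children[node][x]  # type: ignore[index]
        return self._value[node]  # type: ignore[return-value]

    # -- operators -----------------------------------------------------------

    def apply(self, op: str, d1: int, d2: int) -> int:
        """Pointwise binary operator: evaluate(result, a) = f1(a) <op> f2(a).

        *op* is ``"plus"`` or ``"times"``.  Both operands must be diagrams of
        this forest (same domain).  Recursive descent with computed-table
        memoisation; correctness does not depend on cache retention.
        """
        if op not in _OPS:
            raise ValueError(f"unknown operator {op!r}")
        if self._level[d1] != self._level[d2]:
            raise ValueError("operands must be at the same level")
        return self._apply(op, _OPS[op], d1, d2)

    def _apply(self, op: str, fn: Callable[[int, int], int], a: int, b: int) -> int:
        level = self._level[a]
        # algebraic shortcuts on the canonical zero
        zero = self._zero[level]
        if op == "times":
            if a == zero or b == zero:
                return zero
        elif op == "plus":
            if a == zero:
                return b
            if b == zero:
                return a
        if a > b:  # plus and times are commutative
            a, b = b, a
        if level == 0:
            return self.terminal(fn(self._value[a], self._value[b]))  # type: ignore[arg-type]
        key = (op, a, b)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        ca = self._children[a]
        cb = self._children[b]
        children = tuple(
            self._apply(op, fn, x, y) for x, y in zip(ca, cb)  # type: ignore[arg-type]
        )
        result = self._make_node(level, children)
        self._cache[key] = result
        return result

    def clear_cache(self) -> None:
        """Drop the computed table (memory bound); never changes semantics."""
        self._cache.clear()

    # -- inspection -----------------------------------------------------------

    def node_count(self, root: int) -> tuple[int, int, int]:
        """(non-terminal node count, edge count, distinct terminal count)
        over the DAG reachable from *root*."""
        seen: set[int] = set()
        stack = [root]
        nonterminals = 0
        edges = 0
        terminals: set[int] = set()
        while stack:
            handle = stack.pop()
            if handle in seen:
                continue
            seen.add(handle)
            if self._level[handle] == 0:
                terminals.add(handle)
                continue
            children = self._children[handle]
            nonterminals += 1
            edges += len(children)  # type: ignore[arg-type]
            stack.extend(children)  # type: ignore[arg-type]
        return nonterminals, edges, len(terminals)

    def decision_tree_size(self, root: int) -> int:
        """Non-terminal node count of the decision *tree* over the same
        variable order — the unshared unfolding of the diagram.  The
        quasi-reduced DAG can never exceed it; the gap is the compression
        bought by node sharing."""
        memo: dict[int, int] = {}

        def count(handle: int) -> int:
            if self._level[handle] == 0:
                return 0
            cached = memo.get(handle)
            if cached is None:
                cached = 1 + sum(count(c) for c in self._children[handle])  # type: ignore[union-attr]
                memo[handle] = cached
            return cached

        return count(root)

    def iter_support(self, root: int) -> Iterator[tuple[tuple[int, ...], int]]:
        """Yield (assignment, value) for every nonzero assignment.

        Canonicity makes the zero test O(1): a subfunction is identically
        zero iff it *is* the canonical zero node of its level.
        """
        if self._level[root] != self.K:
            raise ValueError("root must be at the top level")
        prefix: list[int] = []

        def walk(handle: int) -> Iterator[tuple[tuple[int, ...], int]]:
            level = self._level[handle]
            if level == 0:
                value = self._value[handle]
                if value:
                    yield tuple(prefix), value  # type: ignore[misc]
                return
            if handle == self._zero[level]:
                return
            for i, child in enumerate(self._children[handle]):  # type: ignore[arg-type]
                prefix.append(i)
                yield from walk(child)
                prefix.pop()

        yield from walk(root)

    def scan_unique_table(self) -> int:
        """Defensive audit: verify no two stored nodes share (level, children)
        or (level, value); returns the number of stored nodes."""
        seen: set[tuple] = set()
        for handle in range(len(self._level)):
            level = self._level[handle]
            key: tuple
            if level == 0:
                key = ("t", self._value[handle])
            else:
                key = (level, self._children[handle])
            if key in seen:
                raise AssertionError(f"duplicate node for key {key}")
            seen.add(key)
        return len(seen)


# ---------------------------------------------------------------------------
# textual serialisation
#
#   levels <K>
#   domain <N_K> ... <N_1>
#   <id> <level> <child_0> ... <child_{N-1}>     (non-terminals)
#   <id> 0 <value>                               (terminals)
#   root <id>
#
# Node ids follow depth-first discovery order from the root, children visited
# in ascending branch-value order, so equal functions serialise identically.
# ---------------------------------------------------------------------------


def serialize(forest: MddForest, root: int, path=None) -> str:
    """Render the diagram reachable from *root* in the textual dialect.

    Returns the text; additionally writes it to *path* when given.
    """
    ids: dict[int, int] = {}
    lines: list[str] = [
        f"levels {forest.K}",
        "domain " + " ".join(str(n) for n in forest.domain),
    ]

    def visit(handle: int) -> int:
        if handle in ids:
            return ids[handle]
        ids[handle] = file_id = len(ids)
        if forest.level_of(handle) == 0:
            lines.append(f"{file_id} 0 {forest.value_of(handle)}")
        else:
            # reserve the line slot before recursing so ids follow discovery order
            slot = len(lines)
            lines.append("")
            child_ids = [visit(c) for c in forest.children_of(handle)]
            lines[slot] = (
                f"{file_id} {forest.level_of(handle)} "
                + " ".join(str(c) for c in child_ids)
            )
        return file_id

    root_id = visit(root)
    lines.append(f"root {root_id}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def deserialize(source, forest: MddForest | None = None) -> tuple[MddForest, int]:
    """Load a diagram from *source* (path or text); returns (forest, root).

    When *forest* is given, the diagram is rebuilt inside it (the domains
    must match exactly); otherwise a fresh forest is created.
    """
    if isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise MddFormatError("truncated diagram file")
    if not lines[0].startswith("levels "):
        raise MddFormatError(f"expected 'levels <K>', got {lines[0]!r}")
    try:
        k = int(lines[0].split()[1])
    except (IndexError, ValueError):
        raise MddFormatError(f"malformed levels line {lines[0]!r}") from None
    parts = lines[1].split()
    if parts[0] != "domain":
        raise MddFormatError(f"expected 'domain ...', got {lines[1]!r}")
    try:
        domain = tuple(int(x) for x in parts[1:])
    except ValueError:
        raise MddFormatError(f"malformed domain line {lines[1]!r}") from None
    if len(domain) != k:
        raise MddFormatError(f"domain lists {len(domain)} sizes for {k} levels")
    if forest is None:
        forest = MddForest(domain)
    elif forest.domain != domain:
        raise MddFormatError(
            f"domain mismatch: file {domain}, forest {forest.domain}"
        )
    if not lines[-1].startswith("root "):
        raise MddFormatError("missing 'root <id>' trailer")
    try:
        root_id = int(lines[-1].split()[1])
    except (IndexError, ValueError):
        raise MddFormatError(f"malformed root line {lines[-1]!r}") from None

    records: dict[int, tuple[int, tuple[int, ...]]] = {}
    for line in lines[2:-1]:
        parts = line.split()
        try:
            nums = [int(x) for x in parts]
        except ValueError:
            raise MddFormatError(f"malformed node line {line!r}") from None
        if len(nums) < 3:
            raise MddFormatError(f"malformed node line {line!r}")
        file_id, level, payload = nums[0], nums[1], tuple(nums[2:])
        if file_id in records:
            raise MddFormatError(f"duplicate node id {file_id}")
        records[file_id] = (level, payload)

    built: dict[int, int] = {}

    def build(file_id: int) -> int:
        if file_id in built:
            return built[file_id]
        if file_id not in records:
            raise MddFormatError(f"reference to undefined node id {file_id}")
        level, payload = records[file_id]
        if level == 0:
            if len(payload) != 1:
                raise MddFormatError(f"terminal {file_id} must carry exactly one value")
            handle = forest.terminal(payload[0])
        else:
            if len(payload) != forest.size(level):
                raise MddFormatError(
                    f"node {file_id} at level {level} has {len(payload)} children,"
                    f" expected {forest.size(level)}"
                )
            try:
                handle = forest.node(level, tuple(build(c) for c in payload))
            except ValueError as exc:
                raise MddFormatError(str(exc)) from exc
        built[file_id] = handle
        return handle

    root = build(root_id)
    if forest.level_of(root) != forest.K:
        raise MddFormatError("root node is not at the top level")
    return forest, root
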