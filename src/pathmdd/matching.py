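"""Exhaustive subgraph-monomorphism enumeration on filtered candidates.

Semantics is *monomorphism* (non-induced): an injective, label-preserving
mapping of query vertices into a target such that every query edge maps onto
a target edge; extra target edges between images are allowed.

:func:`enumerate_matches` is a VF2-style depth-first state extension with
the standard feasibility rules (label equality via the candidate domains,
adjacency consistency with already-mapped vertices, and a look-ahead on
unmapped-neighbour counts).  :func:`brute_force_matches` is a deliberately
simple reference matcher — injective label-preserving assignments checked
edge by edge — kept as the independent oracle for the search code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .filtering import CandidateReport
from .graphs import GraphCollection, LabelledGraph

__all__ = [
    "MatchReport",
    "enumerate_matches",
    "brute_force_matches",
    "verify_collection",
]

MatchMapping = dict[int, int]


@dataclass
class MatchReport:
    """Per-graph match counts (and optionally the mappings themselves)."""

    per_graph: dict[int, int] = field(default_factory=dict)
    mappings: dict[int, list[MatchMapping]] | None = None

    @property
    def total(self) -> int:
        return sum(self.per_graph.values())


def _label_domains(
    query: LabelledGraph, target: LabelledGraph
) -> dict[int, set[int]]:
    """Default candidate domains: target vertices of the matching label.

    Labels are compared as strings so the two graphs may carry different
    alphabets.
    """
    by_label: dict[str, set[int]] = {}
    for v in range(target.n_vertices):
        by_label.setdefault(target.label_string(v), set()).add(v)
    return {
        qv: set(by_label.get(query.label_string(qv), set()))
        for qv in range(query.n_vertices)
    }


def enumerate_matches(
    query: LabelledGraph,
    target: LabelledGraph,
    domains: Mapping[int, set[int]] | None = None,
) -> Iterator[MatchMapping]:
    """Yield every subgraph monomorphism of *query* into *target* once.

    *domains* restricts each query vertex to a candidate set (as produced by
    filtering); restriction never changes the yielded set, only the search
    space, because filtering is sound.  With ``domains=None`` the full label
    classes are used.

    Query vertices are explored greatest-constrained-first: most
    already-mapped neighbours, then smallest candidate domain, then lowest
    index; with that order fixed, the yield sequence is deterministic.
    """
    if query.n_vertices == 0:
        return
    base = _label_domains(query, target)
    if domains is not None:
        base = {qv: base[qv] & set(domains.get(qv, set())) for qv in base}
    if any(not d for d in base.values()):
        return
    n_q = query.n_vertices
    q_adj = [query.neighbours(v) for v in range(n_q)]
    t_adj = [set(target.neighbours(v)) for v in range(target.n_vertices)]

    mapping: MatchMapping = {}
    used: set[int] = set()

    def select_next() -> int:
        best = None
        best_key = None
        for qv in range(n_q):
            if qv in mapping:
                continue
            mapped_neighbours = sum(1 for w in q_adj[qv] if w in mapping)
            key = (-mapped_neighbours, len(base[qv]), qv)
            if best_key is None or key < best_key:
                best, best_key = qv, key
        assert best is not None
        return best

    def feasible(qv: int, tv: int) -> bool:
        # adjacency consistency: every mapped query neighbour maps to a
        # target neighbour of tv (non-induced: only query edges required)
        for w in q_adj[qv]:
            img = mapping.get(w)
            if img is not None and img not in t_adj[tv]:
                return False
        # look-ahead: unmapped query neighbours must fit among unmapped
        # target neighbours of tv
        unmapped_q = sum(1 for w in q_adj[qv] if w not in mapping)
        unmapped_t = sum(1 for u in t_adj[tv] if u not in used)
        return unmapped_q <= unmapped_t

    def extend() -> Iterator[MatchMapping]:
        if len(mapping) == n_q:
            yield dict(mapping)
            return
        qv = select_next()
        for tv in sorted(base[qv]):
            if tv in used or not feasible(qv, tv):
                continue
            mapping[qv] = tv
            used.add(tv)
            yield from extend()
            del mapping[qv]
            used.discard(tv)

    yield from extend()


def brute_force_matches(
    query: LabelledGraph, target: LabelledGraph
) -> list[MatchMapping]:
    """Reference matcher: all injective label-preserving assignments,
    checked edge by edge.  Exhaustive and independent of the VF2-style
    search; intended for verification at small sizes."""
    base = _label_domains(query, target)
    n_q = query.n_vertices
    out: list[MatchMapping] = []
    mapping: MatchMapping = {}
    used: set[int] = set()

    def assign(qv: int) -> None:
        # vertices are assigned in index order, so a query edge (w, qv) is
        # checkable as soon as qv is placed: w < qv is already mapped
        if qv == n_q:
            out.append(dict(mapping))
            return
        for tv in sorted(base[qv]):
            if tv in used:
                continue
            if all(
                target.has_edge(mapping[w], tv)
                for w in query.neighbours(qv)
                if w < qv
            ):
                mapping[qv] = tv
                used.add(tv)
                assign(qv + 1)
                del mapping[qv]
                used.discard(tv)

    assign(0)
    return out


def verify_collection(
    query: LabelledGraph,
    report: CandidateReport,
    collection: GraphCollection,
    collect_mappings: bool = False,
) -> MatchReport:
    """Run match enumeration on the filtered components of every survivor.

    For each surviving graph, enumeration is restricted per component with
    the candidate domains; since a connected query's image is connected and
    lies entirely inside one component, per-component counts add up without
    double counting.  Totals equal unfiltered enumeration over the whole
    collection — filtering affects speed, never results.
    """
    if not query.is_connected():
        raise ValueError("disconnected queries are not supported")
    result = MatchReport(mappings={} if collect_mappings else None)
    for i in range(len(collection)):
        result.per_graph[i] = 0
    for i in report.surviving:
        target = collection[i]
        per_qv = report.candidates[i]
        components = report.components.get(i)
        if components is None:
            components = [set(range(target.n_vertices))]
        found: list[MatchMapping] = []
        for comp in components:
            domains = {qv: images & comp for qv, images in per_qv.items()}
            if any(not d for d in domains.values()):
                continue
            found.extend(enumerate_matches(query, target, domains))
        result.per_graph[i] = len(found)
        if collect_mappings:
            result.mappings[i] = found  # type: ignore[index]
    return result
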