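"""Synthetic benchmark graphs: scale-free and forest-fire targets, uniform
labelling and query extraction.

Two growth models are provided.  The Barabasi–Albert variant attaches each
new vertex to ``m0`` existing vertices sampled without replacement with
probability proportional to ``degree**alpha`` (alpha = 1 is classic
preferential attachment; alpha > 1 sharpens the hubs, alpha < 1 flattens
them).  The Forest-Fire variant links each new vertex to a uniformly chosen
ambassador and then recursively "burns" through the neighbourhood: at every
visited vertex it links to x further unvisited neighbours, x drawn from a
geometric distribution on {0, 1, 2, ...} with mean p/(1-p), so larger p
gives denser graphs.

Labels are assigned uniformly at random from an alphabet whose size is a
fixed fraction of the vertex count.  Queries are extracted from targets by
randomised connected expansion and induced-subgraph restriction, so every
extracted query is guaranteed at least one match in its origin graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import GraphCollection, LabelledGraph, build_collection

__all__ = [
    "GeneratorConfig",
    "generate_barabasi",
    "generate_forestfire",
    "generate_graph",
    "assign_labels",
    "extract_query",
    "generate_collection",
]


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic target graph.

    model      'barabasi' or 'forestfire'
    n          vertex count
    m0         seed-set size and attachments per step (barabasi)
    alpha      attachment exponent (barabasi); probability of an edge to
               vertex i is proportional to degree(i)**alpha
    p          burning parameter (forestfire), 0 < p < 1; the number of
               links burned per visited vertex is geometric with mean p/(1-p)
    label_pct  distinct labels as a fraction of n (alphabet size
               max(1, round(label_pct * n)))
    seed       RNG seed; identical configs produce identical graphs
    """

    model: str = "barabasi"
    n: int = 100
    m0: int = 2
    alpha: float = 1.0
    p: float = 0.3
    label_pct: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.model not in ("barabasi", "forestfire"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.model == "barabasi" and not 1 <= self.m0 <= self.n:
            raise ValueError("need n >= m0 >= 1")
        if self.model == "barabasi" and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.model == "forestfire" and not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if not 0 < self.label_pct <= 1:
            raise ValueError("label_pct must be in (0, 1]")


def _skeleton_graph(name: str, n: int, edges: set[tuple[int, int]]) -> LabelledGraph:
    """Unlabelled skeleton: every vertex carries the placeholder label."""
    placeholder = build_collection([(name, ["?"] * n, sorted(edges))])
    return placeholder[0]


def generate_barabasi(config: GeneratorConfig) -> LabelledGraph:
    """Degree-power preferential attachment growth (labels pending).

    The m0 seed vertices start as a path (connected); each later vertex
    attaches to min(m0, current size) distinct existing vertices drawn with
    probability proportional to degree**alpha.
    """
    config.validate()
    if config.model != "barabasi":
        raise ValueError("config.model must be 'barabasi'")
    rng = np.random.default_rng(config.seed)
    n, m0, alpha = config.n, config.m0, config.alpha
    edges: set[tuple[int, int]] = set()
    degree = np.zeros(n, dtype=np.float64)

    def add_edge(u: int, v: int) -> None:
        e = (u, v) if u < v else (v, u)
        if e not in edges:
            edges.add(e)
            degree[u] += 1
            degree[v] += 1

    for v in range(1, m0):
        add_edge(v - 1, v)
    for v in range(m0, n):
        k = min(m0, v)
        # sample k distinct existing vertices with prob ~ degree**alpha;
        # isolated vertices keep a minimal weight so they stay reachable
        weights = np.maximum(degree[:v], 1e-12) ** alpha
        weights /= weights.sum()
        targets = rng.choice(v, size=k, replace=False, p=weights)
        for t in targets:
            add_edge(v, int(t))
    return _skeleton_graph(f"ba_n{n}_m{m0}_a{alpha}_s{config.seed}", n, edges)


def generate_forestfire(config: GeneratorConfig) -> LabelledGraph:
    """Forward-burning forest-fire growth (labels pending).

    Each new vertex links to a uniform ambassador and burns outward: at each
    visited vertex, x unvisited neighbours are burned (linked and enqueued),
    with x geometric on {0,1,2,...} of mean p/(1-p).  Visited vertices are
    never reburned, so every fire terminates.
    """
    config.validate()
    if config.model != "forestfire":
        raise ValueError("config.model must be 'forestfire'")
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    edges: set[tuple[int, int]] = set()
    adjacency: list[list[int]] = [[] for _ in range(n)]

    def add_edge(u: int, v: int) -> None:
        e = (u, v) if u < v else (v, u)
        if e not in edges:
            edges.add(e)
            adjacency[u].append(v)
            adjacency[v].append(u)

    for v in range(1, n):
        ambassador = int(rng.integers(v))
        visited = {ambassador}
        queue = [ambassador]
        links = [ambassador]
        while queue:
            w = queue.pop(0)
            # numpy's geometric is on {1,2,...} with mean 1/q; shifting by 1
            # gives support {0,1,...} and mean p/(1-p) for q = 1-p
            x = int(rng.geometric(1.0 - p)) - 1
            if x <= 0:
                continue
            unvisited = [u for u in adjacency[w] if u not in visited]
            if not unvisited:
                continue
            burn_count = min(x, len(unvisited))
            picked = rng.choice(len(unvisited), size=burn_count, replace=False)
            for idx in sorted(int(i) for i in picked):
                u = unvisited[idx]
                visited.add(u)
                queue.append(u)
                links.append(u)
        for u in links:
            add_edge(v, u)
    return _skeleton_graph(f"ff_n{n}_p{p}_s{config.seed}", n, edges)


def generate_graph(config: GeneratorConfig) -> LabelledGraph:
    """Generate and label one target graph per *config*."""
    skeleton = (
        generate_barabasi(config)
        if config.model == "barabasi"
        else generate_forestfire(config)
    )
    return assign_labels(skeleton, config.label_pct, config.seed)


def assign_labels(
    graph: LabelledGraph, label_pct: float, seed: int
) -> LabelledGraph:
    """Relabel every vertex uniformly from an alphabet of size
    max(1, round(label_pct * n))."""
    if not 0 < label_pct <= 1:
        raise ValueError("label_pct must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = graph.n_vertices
    n_labels = max(1, round(label_pct * n))
    width = len(str(n_labels - 1))
    draws = rng.integers(n_labels, size=n)
    labels = [f"L{int(d):0{width}d}" for d in draws]
    rebuilt = build_collection([(graph.name, labels, sorted(graph.edges))])
    return rebuilt[0]


def extract_query(
    target: LabelledGraph,
    size: int,
    mode: str = "vertices",
    seed: int = 0,
    name: str | None = None,
) -> LabelledGraph:
    """Extract a connected induced subgraph of *target* as a query.

    mode='vertices': grow a random connected vertex set of *size* vertices
    by repeated uniform expansion of the frontier, then take all edges among
    the selected vertices.  mode='edges': grow the same way until the
    induced subgraph carries at least *size* edges.  Either way the query is
    an induced subgraph of the target, so at least one match is guaranteed.
    """
    if mode not in ("vertices", "edges"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    if size < 1:
        raise ValueError("size must be >= 1")
    if mode == "vertices" and size > target.n_vertices:
        raise ValueError(
            f"requested {size} vertices from a {target.n_vertices}-vertex graph"
        )
    if mode == "edges" and size > target.n_edges:
        raise ValueError(
            f"requested {size} edges from a {target.n_edges}-edge graph"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(target.n_vertices))
    selected = [start]
    selected_set = {start}
    frontier = [w for w in target.neighbours(start) if w not in selected_set]
    induced_edges = 0

    def done() -> bool:
        if mode == "vertices":
            return len(selected) >= size
        return induced_edges >= size

    while not done():
        if not frontier:
            raise ValueError(
                "extraction exhausted a connected component before reaching the budget"
            )
        idx = int(rng.integers(len(frontier)))
        v = frontier.pop(idx)
        if v in selected_set:
            continue
        induced_edges += sum(1 for w in target.neighbours(v) if w in selected_set)
        selected.append(v)
        selected_set.add(v)
        for w in target.neighbours(v):
            if w not in selected_set:
                frontier.append(w)
    relabel = {v: i for i, v in enumerate(selected)}
    labels = [target.label_string(v) for v in selected]
    edges = [
        (relabel[u], relabel[v])
        for u, v in target.edges
        if u in selected_set and v in selected_set
    ]
    qname = name if name is not None else f"q_{target.name}_s{seed}"
    return build_collection([(qname, labels, sorted(edges))])[0]


def generate_collection(
    n_graphs: int,
    seed: int,
    model: str = "barabasi",
    n_range: tuple[int, int] = (20, 60),
    label_pct: float = 0.1,
    m0: int = 2,
    alpha: float = 1.0,
    p: float = 0.3,
) -> GraphCollection:
    """Convenience: a seeded collection of independently generated targets
    sharing one interned alphabet."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_graphs):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        config = GeneratorConfig(
            model=model,
            n=n,
            m0=m0,
            alpha=alpha,
            p=p,
            label_pct=label_pct,
            seed=int(rng.integers(2**31 - 1)),
        )
        g = generate_graph(config)
        records.append((f"g{i}_{g.name}", g.label_strings(), sorted(g.edges)))
    return build_collection(records)
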