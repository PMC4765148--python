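"""Hierarchical-information-based (HIB) mapping on the GO DAG.

A query protein annotated only with non-essential GO terms would project to
a null feature vector.  Because GO terms within a taxonomy are organized in
a directed acyclic graph, a non-essential term G still carries information
about a nearby essential term E: G contributes ``f_G * w(d(G, E))`` to the
*effective* number of occurrences of E, where d is the hierarchy distance
and w a non-increasing decay with w(0) = 1.  Summing contributions over all
annotated terms yields a non-null vector whenever any annotated term lies
within the distance cutoff of any essential term.
"""

from __future__ import annotations

import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable

import networkx as nx
import obonet
import numpy as np

from .go_features import GoTerm, CATEGORIES
from .multilabel import EssentialTermSet

_NAMESPACE_TO_CATEGORY = {
    "cellular_component": "CC",
    "molecular_function": "MF",
    "biological_process": "BP",
}

DEFAULT_EDGE_TYPES = ("is_a", "part_of")


def exponential_decay(d: int) -> float:
    """Default contribution decay w(d) = 2^-d (w(0) = 1, non-increasing)."""
    return 0.5 ** d


DECAYS: dict[str, Callable[[int], float]] = {
    "exponential": exponential_decay,
    "inverse": lambda d: 1.0 / (1.0 + d),
}


@dataclass
class HibParams:
    """Distance cutoff D, decay w(d) and the hierarchy edge types used.

    ``nearest_only`` restricts each annotated term's contribution to its
    single nearest essential term instead of summing over all within D.
    ``distance_mode`` selects between shortest paths on the undirected view
    of the hierarchy (default) and ancestor-only paths (child -> parent
    direction only).
    """

    max_distance: int = 5
    decay: str | Callable[[int], float] = "exponential"
    edge_types: tuple[str, ...] = DEFAULT_EDGE_TYPES
    nearest_only: bool = False
    distance_mode: str = "undirected"
    strict: bool = False

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.distance_mode not in ("undirected", "ancestor"):
            raise ValueError("distance_mode must be 'undirected' or 'ancestor'")
        w = self.decay_fn
        if abs(w(0) - 1.0) > 1e-12:
            raise ValueError("decay must satisfy w(0) = 1")
        if any(w(d) < w(d + 1) - 1e-12 for d in range(self.max_distance + 1)):
            raise ValueError("decay must be non-increasing")

    @property
    def decay_fn(self) -> Callable[[int], float]:
        if callable(self.decay):
            return self.decay
        return DECAYS[self.decay]


@dataclass
class GoDag:
    """GO hierarchy: child -> parent edges typed is_a / part_of, per taxonomy."""

    graph: nx.MultiDiGraph
    categories: dict[str, str]  # term id -> CC/MF/BP
    n_obsolete_dropped: int = 0
    _adjacency_cache: dict = field(default_factory=dict, repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def category(self, term_id: str) -> str:
        if term_id not in self.categories:
            raise KeyError(f"unknown GO term {term_id}")
        return self.categories[term_id]

    def roots(self, category: str) -> set[str]:
        """Terms of a taxonomy with no outgoing (child -> parent) edge."""
        return {
            n for n, cat in self.categories.items()
            if cat == category and self.graph.out_degree(n) == 0
        }

    def edges(self, edge_types: tuple[str, ...] = DEFAULT_EDGE_TYPES):
        for u, v, key in self.graph.edges(keys=True):
            if key in edge_types:
                yield u, v, key

    def _adjacency(
        self, edge_types: tuple[str, ...], mode: str
    ) -> dict[str, list[str]]:
        cache_key = (tuple(sorted(edge_types)), mode)
        if cache_key not in self._adjacency_cache:
            adj: dict[str, list[str]] = {n: [] for n in self.graph.nodes}
            for u, v, _ in self.edges(edge_types):
                adj[u].append(v)
                if mode == "undirected":
                    adj[v].append(u)
            self._adjacency_cache[cache_key] = adj
        return self._adjacency_cache[cache_key]


def _build_dag(
    graph: nx.MultiDiGraph, n_obsolete: int = 0, edge_types: Iterable[str] | None = None
) -> GoDag:
    keep_types = set(edge_types or DEFAULT_EDGE_TYPES)
    out = nx.MultiDiGraph()
    categories: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        namespace = data.get("namespace")
        category = _NAMESPACE_TO_CATEGORY.get(namespace, namespace)
        if category not in CATEGORIES:
            raise ValueError(f"term {node} has missing or unknown namespace {namespace!r}")
        out.add_node(node, category=category)
        categories[node] = category
    for u, v, key in graph.edges(keys=True):
        if key not in keep_types:
            continue
        if u not in categories or v not in categories:
            continue
        if categories[u] != categories[v]:
            raise ValueError(f"edge {u} -> {v} crosses taxonomies")
        out.add_edge(u, v, key=key)
    if not nx.is_directed_acyclic_graph(out):
        cycle = nx.find_cycle(out)
        raise ValueError(f"GO hierarchy contains a cycle through {cycle[0][0]}")
    return GoDag(out, categories, n_obsolete_dropped=n_obsolete)


def parse_obo(source: str | IO[str]) -> GoDag:
    """Parse an OBO 1.2/1.4 ontology into a :class:`GoDag`.

    [Term] stanzas become nodes; ``is_a`` and ``relationship: part_of``
    lines become child -> parent edges.  Obsolete terms are dropped and
    counted in ``n_obsolete_dropped``.  Cyclic input raises, naming a
    member of the cycle.
    """
    graph = obonet.read_obo(source, ignore_obsolete=False)
    obsolete = [
        n for n, data in graph.nodes(data=True)
        if str(data.get("is_obsolete", "")).lower() == "true"
    ]
    if obsolete:
        graph = graph.subgraph(
            [n for n in graph.nodes if n not in set(obsolete)]
        ).copy()
        warnings.warn(f"dropped {len(obsolete)} obsolete GO term(s)", stacklevel=2)
    return _build_dag(graph, n_obsolete=len(obsolete))


def build_dag(
    nodes: Iterable[tuple[str, str]], edges: Iterable[tuple[str, str, str]]
) -> GoDag:
    """Construct a GoDag programmatically from (id, category) nodes and
    (child, parent, edge_type) edges."""
    graph = nx.MultiDiGraph()
    inverse = {v: k for k, v in _NAMESPACE_TO_CATEGORY.items()}
    for term_id, category in nodes:
        graph.add_node(term_id, namespace=inverse[category])
    for u, v, key in edges:
        graph.add_edge(u, v, key=key)
    return _build_dag(graph)


def dag_distance(
    dag: GoDag,
    g: str | GoTerm,
    e: str | GoTerm,
    edge_types: tuple[str, ...] = DEFAULT_EDGE_TYPES,
    distance_mode: str = "undirected",
) -> float:
    """Hierarchy distance between two terms; inf across taxonomies.

    The default is the shortest-path length in the undirected view of the
    hierarchy edges (0 when the terms coincide).
    """
    g_id = g.id if isinstance(g, GoTerm) else g
    e_id = e.id if isinstance(e, GoTerm) else e
    for tid in (g_id, e_id):
        if tid not in dag:
            raise KeyError(f"unknown GO term {tid}")
    if dag.category(g_id) != dag.category(e_id):
        return float("inf")
    if g_id == e_id:
        return 0.0
    adj = dag._adjacency(edge_types, distance_mode)
    seen = {g_id: 0}
    queue = deque([g_id])
    while queue:
        node = queue.popleft()
        for nxt in adj[node]:
            if nxt not in seen:
                seen[nxt] = seen[node] + 1
                if nxt == e_id:
                    return float(seen[nxt])
                queue.append(nxt)
    return float("inf")


def _distances_within(
    dag: GoDag, source: str, max_distance: int, edge_types, mode
) -> dict[str, int]:
    """BFS distances from ``source`` up to ``max_distance``."""
    adj = dag._adjacency(edge_types, mode)
    seen = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        d = seen[node]
        if d >= max_distance:
            continue
        for nxt in adj[node]:
            if nxt not in seen:
                seen[nxt] = d + 1
                queue.append(nxt)
    return seen


def map_to_essential(
    multiset: Counter,
    essential: EssentialTermSet,
    dag: GoDag,
    params: HibParams | None = None,
) -> np.ndarray:
    """Effective occurrence counts of the essential terms for a query.

    ``value[E] = sum_G f_G * w(d(G, E))`` over annotated terms G with
    ``d(G, E) <= max_distance`` (same taxonomy only).  Terms absent from
    the DAG are skipped with a warning unless ``params.strict``.
    """
    if essential.size == 0:
        raise ValueError("essential term set is empty")
    params = params or HibParams()
    w = params.decay_fn
    positions = {term.id: j for j, term in enumerate(essential.terms)}
    values = np.zeros(essential.size)
    for term, count in multiset.items():
        term_id = term.id if isinstance(term, GoTerm) else term
        if term_id not in dag:
            if params.strict:
                raise KeyError(f"GO term {term_id} not in the DAG")
            warnings.warn(f"skipping {term_id}: not in the DAG", stacklevel=2)
            continue
        dists = _distances_within(
            dag, term_id, params.max_distance, params.edge_types, params.distance_mode
        )
        hits = [
            (positions[t], d) for t, d in dists.items()
            if t in positions and dag.category(t) == dag.category(term_id)
        ]
        if not hits:
            continue
        if params.nearest_only:
            j, d = min(hits, key=lambda jd: (jd[1], jd[0]))
            values[j] += count * w(d)
        else:
            for j, d in hits:
                values[j] += count * w(d)
    return values


def make_hib_fallback(
    essential: EssentialTermSet, dag: GoDag, params: HibParams | None = None
):
    """A callable suitable as the ``hib`` argument of multilabel.predict."""
    def _fallback(multiset: Counter) -> np.ndarray:
        return map_to_essential(multiset, essential, dag, params)
    return _fallback
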