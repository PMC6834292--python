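"""Decomposable-graph machinery for source-set estimation.

A pathway is modelled as a graph whose nodes are genes and whose edges are
biochemical interactions.  Before any testing can happen the (possibly
directed) pathway graph is turned into a decomposable (chordal) undirected
graph by *moralization* (marry parents sharing a child, drop directions) and
*triangulation* (add fill-in edges until every cycle of length >= 4 has a
chord).  The decomposable graph is then described through its maximal
cliques ``C_1..C_k``, the separators of a junction tree, and the ``k``
perfect orderings of the cliques -- one per choice of root clique -- whose
(clique, separator) pairs are the hypothesis components the estimator tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import networkx as nx

logger = logging.getLogger("sourceset")

Node = Hashable


def _key(node: Node) -> str:
    """Deterministic sort key for arbitrary hashable node labels."""
    return str(node)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayGraph:
    """A pathway graph as supplied by the user (directed or undirected)."""

    nodes: tuple[Node, ...]
    edges: tuple[tuple[Node, Node], ...]
    directed: bool = False

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("node IDs must be unique")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u!r} not allowed")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references undeclared node")

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph | nx.DiGraph) -> "PathwayGraph":
        return cls(
            nodes=tuple(sorted(g.nodes, key=_key)),
            edges=tuple((u, v) for u, v in g.edges),
            directed=g.is_directed(),
        )

    def restrict_to(self, keep: Iterable[Node]) -> "PathwayGraph":
        """Drop nodes outside ``keep`` (e.g. genes without expression data).

        Performed *before* moralization/triangulation because the likelihood
        ratio needs data for every node of every clique.
        """
        keep = set(keep)
        dropped = [n for n in self.nodes if n not in keep]
        if dropped:
            logger.warning(
                "dropping %d graph node(s) absent from the data: %s",
                len(dropped),
                ", ".join(map(_key, sorted(dropped, key=_key))),
            )
        nodes = tuple(n for n in self.nodes if n in keep)
        edges = tuple((u, v) for u, v in self.edges if u in keep and v in keep)
        return PathwayGraph(nodes=nodes, edges=edges, directed=self.directed)


@dataclass(frozen=True)
class DecomposableGraph:
    """Chordal undirected graph with its clique/separator decomposition.

    ``cliques`` are the maximal complete subgraphs, sorted by
    (size, lexicographic node order) for stable indexing.  ``separator_edges``
    is a junction forest over clique indices: edges ``(i, j, S)`` with
    ``S = C_i & C_j`` satisfying the running-intersection property.
    ``fill_in`` records the edges added by triangulation.
    """

    nodes: tuple[Node, ...]
    edges: tuple[frozenset, ...]
    cliques: tuple[frozenset, ...]
    separator_edges: tuple[tuple[int, int, frozenset], ...]
    fill_in: tuple[frozenset, ...] = ()

    @property
    def k(self) -> int:
        return len(self.cliques)

    @property
    def p_star(self) -> int:
        return max((len(c) for c in self.cliques), default=0)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        fill = set(self.fill_in)
        for e in self.edges:
            u, v = sorted(e, key=_key)
            g.add_edge(u, v, fill_in=(e in fill))
        return g


@dataclass(frozen=True)
class PerfectOrdering:
    """One perfect ordering of the cliques, rooted at ``cliques[root_index]``.

    ``separators[j] = C_(j) & (C_(0) | ... | C_(j-1))`` with the root (and the
    first clique of every connected component) having an empty separator;
    ``residuals[j] = C_(j) - separators[j]`` partition the node set.
    """

    root_index: int
    clique_order: tuple[int, ...]  # indices into DecomposableGraph.cliques
    cliques_in_order: tuple[frozenset, ...]
    separators: tuple[frozenset, ...]
    residuals: tuple[frozenset, ...]


@dataclass(frozen=True)
class ComponentCatalogue:
    """The de-duplicated (clique, separator) hypothesis components.

    ``m = k + sum_i v(C_i)`` where ``v(C_i)`` counts the distinct non-empty
    separators with which clique ``C_i`` appears across the k orderings.
    """

    components: tuple[tuple[int, frozenset, frozenset], ...]  # (clique idx, C, S)
    v: tuple[int, ...] = field(default=())

    @property
    def m(self) -> int:
        return len(self.components)


# ---------------------------------------------------------------------------
# Moralization and triangulation
# ---------------------------------------------------------------------------


def moralize(g: PathwayGraph) -> PathwayGraph:
    """Undirected moral graph: drop directions, marry parents of each child."""
    if not g.directed:
        return g
    dg = g.to_networkx()
    moral = nx.moral_graph(dg)
    return PathwayGraph(
        nodes=tuple(sorted(moral.nodes, key=_key)),
        edges=tuple(tuple(sorted(e, key=_key)) for e in sorted(
            (tuple(sorted(e, key=_key)) for e in moral.edges))),
        directed=False,
    )


def _min_fill_order(g: nx.Graph) -> list[tuple[Node, list[frozenset]]]:
    """Greedy min-fill elimination.

    Ties are broken deterministically: fewest fill edges, then the
    lexicographically smallest sorted fill-edge set, then the smallest node
    label, so the produced fill-in (and hence the estimated source set) is
    reproducible across runs and platforms.
    """
    h = g.copy()
    out: list[tuple[Node, list[frozenset]]] = []
    while h.number_of_nodes():
        best = best_key = None
        for v in sorted(h.nodes, key=_key):
            nbrs = list(h.neighbors(v))
            deficiency = [
                frozenset((a, b))
                for i, a in enumerate(nbrs)
                for b in nbrs[i + 1:]
                if not h.has_edge(a, b)
            ]
            key = (
                len(deficiency),
                sorted(tuple(sorted(map(_key, e))) for e in deficiency),
                _key(v),
            )
            if best is None or key < best_key:
                best, best_key = (v, deficiency), key
            if not deficiency:
                break  # zero fill-in with the smallest label cannot be beaten
        v, deficiency = best
        out.append((v, deficiency))
        h.add_edges_from(tuple(e) for e in deficiency)
        h.remove_node(v)
    return out


def _build_junction_forest(
    cliques: Sequence[frozenset],
) -> tuple[tuple[int, int, frozenset], ...]:
    """Maximum-weight spanning forest of the clique-intersection graph.

    Kruskal with deterministic tie-breaking by clique index, which yields a
    junction tree (running-intersection property) on each connected component
    of a chordal graph.
    """
    candidates = sorted(
        (
            (i, j)
            for i in range(len(cliques))
            for j in range(i + 1, len(cliques))
            if cliques[i] & cliques[j]
        ),
        key=lambda ij: (-len(cliques[ij[0]] & cliques[ij[1]]), ij[0], ij[1]),
    )
    parent = list(range(len(cliques)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    forest = []
    for i, j in candidates:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            forest.append((i, j, cliques[i] & cliques[j]))
    return tuple(forest)


def triangulate(g: PathwayGraph) -> DecomposableGraph:
    """Triangulate an undirected pathway graph (greedy min-fill heuristic).

    Deterministic: elimination ties are broken by sorted node label, so the
    fill-in -- and hence the estimated source set -- is reproducible.
    Disconnected input is handled naturally (each component is chordalized
    independently by elimination).
    """
    if g.directed:
        raise ValueError("triangulate expects an undirected graph; moralize first")
    gx = nx.Graph()
    gx.add_nodes_from(g.nodes)
    gx.add_edges_from(g.edges)
    fill: list[frozenset] = []
    for _, deficiency in _min_fill_order(gx):
        fill.extend(deficiency)
    tri = gx.copy()
    tri.add_edges_from(tuple(e) for e in fill)
    assert nx.is_chordal(tri)
    cliques = sorted(
        (frozenset(c) for c in nx.find_cliques(tri)),
        key=lambda c: (len(c), sorted(map(_key, c))),
    )
    return DecomposableGraph(
        nodes=tuple(sorted(tri.nodes, key=_key)),
        edges=tuple(frozenset(e) for e in tri.edges),
        cliques=tuple(cliques),
        separator_edges=_build_junction_forest(cliques),
        fill_in=tuple(dict.fromkeys(fill)),
    )


def as_decomposable(g: nx.Graph) -> DecomposableGraph:
    """Wrap an already chordal networkx graph (raises if not chordal)."""
    if not nx.is_chordal(g):
        raise ValueError("graph is not chordal")
    return triangulate(PathwayGraph.from_networkx(g))


# ---------------------------------------------------------------------------
# Perfect orderings and hypothesis components
# ---------------------------------------------------------------------------


def _check_chordal(dg: DecomposableGraph) -> None:
    g = nx.Graph()
    g.add_nodes_from(dg.nodes)
    g.add_edges_from(tuple(e) for e in dg.edges)
    if not nx.is_chordal(g):
        raise ValueError("graph is not chordal; triangulate it first")


def _forest_adjacency(dg: DecomposableGraph) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(dg.k)}
    for i, j, _ in dg.separator_edges:
        adj[i].append(j)
        adj[j].append(i)
    for lst in adj.values():
        lst.sort()
    return adj


def _bfs_component(adj: dict[int, list[int]], root: int, seen: set[int]) -> list[int]:
    order, queue = [], [root]
    seen.add(root)
    while queue:
        c = queue.pop(0)
        order.append(c)
        for nb in adj[c]:
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return order


def perfect_orderings(dg: DecomposableGraph) -> list[PerfectOrdering]:
    """All ``k`` perfect orderings, the i-th rooted at clique ``C_i``.

    Each ordering is a breadth-first traversal of the junction forest from
    the root clique (remaining connected components are appended, each
    traversed from its lowest-index clique), which guarantees the
    running-intersection property: every separator is the intersection of a
    clique with the union of the cliques listed before it.
    """
    _check_chordal(dg)
    if dg.k == 0:
        return []
    adj = _forest_adjacency(dg)
    orderings = []
    for root in range(dg.k):
        seen: set[int] = set()
        order = _bfs_component(adj, root, seen)
        for other in range(dg.k):
            if other not in seen:
                order.extend(_bfs_component(adj, other, seen))
        visited: set = set()
        seps, resids = [], []
        for ci in order:
            c = dg.cliques[ci]
            s = frozenset(c & visited)
            seps.append(s)
            resids.append(frozenset(c - s))
            visited |= c
        orderings.append(
            PerfectOrdering(
                root_index=root,
                clique_order=tuple(order),
                cliques_in_order=tuple(dg.cliques[i] for i in order),
                separators=tuple(seps),
                residuals=tuple(resids),
            )
        )
    return orderings


def enumerate_components(dg: DecomposableGraph) -> ComponentCatalogue:
    """Distinct (clique, separator) hypothesis components over all orderings.

    Each clique appears exactly once with the empty separator (its root
    hypothesis) plus once per distinct non-empty separator it takes across
    the k orderings, so ``m = k + sum_i v(C_i)``.
    """
    seen: dict[tuple[int, frozenset], None] = {}
    for po in perfect_orderings(dg):
        for ci, s in zip(po.clique_order, po.separators):
            seen.setdefault((ci, s), None)
        # every clique also appears as a root somewhere; ensured by the loop
    comps = sorted(
        seen,
        key=lambda cs: (cs[0], len(cs[1]), sorted(map(_key, cs[1]))),
    )
    v = [0] * dg.k
    for ci, s in comps:
        if s:
            v[ci] += 1
    return ComponentCatalogue(
        components=tuple((ci, dg.cliques[ci], s) for ci, s in comps),
        v=tuple(v),
    )


# ---------------------------------------------------------------------------
# Graph file I/O
# ---------------------------------------------------------------------------


def read_graph(path: str | Path) -> PathwayGraph:
    """Read a pathway graph from GraphML or a two-column edge-list TSV.

    The TSV may carry an optional third column with per-edge
    ``directed``/``undirected`` flags; if any flag is present the whole graph
    is treated as directed (undirected rows are expanded to both arcs).
    """
    path = Path(path)
    if path.suffix.lower() in {".graphml", ".xml"}:
        g = nx.read_graphml(path)
        return PathwayGraph.from_networkx(g)
    edges: list[tuple[str, str]] = []
    flags: list[str | None] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            edges.append((parts[0].strip(), parts[1].strip()))
            flags.append(parts[2].strip().lower() if len(parts) > 2 else None)
    directed = any(f == "directed" for f in flags)
    if directed:
        expanded = []
        for (u, v), f in zip(edges, flags):
            expanded.append((u, v))
            if f == "undirected":
                expanded.append((v, u))
        edges = expanded
    nodes = tuple(dict.fromkeys(n for e in edges for n in e))
    return PathwayGraph(nodes=tuple(sorted(nodes, key=_key)), edges=tuple(edges),
                        directed=directed)


def write_decomposable_graphml(dg: DecomposableGraph, path: str | Path) -> None:
    """Write the triangulated graph as GraphML with a ``fill_in`` edge flag."""
    nx.write_graphml(dg.to_networkx(), str(path))
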