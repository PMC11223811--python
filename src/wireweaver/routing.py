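"""Strand routing methods for wireframe nanostructures.

Five routings are computed on the wireframe graph:

* **AT-DNA** -- an A-trail: an Eulerian circuit of the (reconditioned,
  even-degree) wireframe in which every junction turn is a sharp left or a
  sharp right, i.e. consecutive edges are adjacent in the vertex's rotation
  order.  Found by branch-and-bound over the two sharp-turn transition
  systems available at each junction.
* **ST-DNA** -- the scaffold traverses every edge twice (once per direction),
  going around a maximally-branching spanning tree; non-tree edges carry
  scaffold crossovers.
* **CC-DNA** -- a set of directed cycles covering every edge once in each
  direction (face boundaries when the mesh provides faces).
* **ST-RNA** -- a single strand twice around a spanning tree; every non-tree
  edge becomes a pair of hairpin half-edges that meet at the edge midpoint as
  a 180-degree kissing loop.
* **XT-RNA** -- the same construction around a Xuong tree (a spanning tree
  minimising the number of odd-sized co-tree components), which needs only
  one kissing loop per odd co-tree component -- at most one on fully
  triangulated (upper-embeddable) meshes.

Exhaustive oracles (:func:`atrail_exhaustive`, :func:`xuong_exact_bruteforce`
via the exact mode) back the heuristic searches at small problem sizes.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import RouteImportError, RoutingError, SizeError
from .graph import Edge, Route, SpanningTree, Traversal, WireframeGraph

__all__ = [
    "prim_max_branching_tree",
    "st_route",
    "st_rna_route",
    "xt_route",
    "recondition",
    "atrail_search",
    "atrail_exhaustive",
    "AtrailResult",
    "import_atrail",
    "check_sharp_turns",
    "cycle_cover",
    "check_junction_connectivity",
    "xuong_tree",
    "number_of_spanning_trees",
]


# ----------------------------------------------------------------------
# Spanning trees
# ----------------------------------------------------------------------


def prim_max_branching_tree(graph: WireframeGraph, seed_vertex: int = 0) -> SpanningTree:
    """Prim-style growth favouring maximally branching trees.

    At each step the vertex adjacent to the largest number of tree vertices
    joins the tree (ties broken by lowest vertex index), attached to its
    lowest-index tree neighbour.  On regular wireframes this reproduces the
    hub-and-spoke trees that keep scaffold paths short.
    """
    if not graph.is_connected():
        raise RoutingError("graph must be connected for spanning-tree routing")
    verts = set(graph.positions)
    if seed_vertex not in verts:
        raise RoutingError(f"seed vertex {seed_vertex} not in graph")
    adj: dict[int, dict[int, list[Edge]]] = {v: {} for v in verts}
    for e in graph.edges:
        adj[e.u].setdefault(e.v, []).append(e)
        adj[e.v].setdefault(e.u, []).append(e)
    tree_vertices = {seed_vertex}
    tree_edges: list[int] = []
    while len(tree_vertices) < len(verts):
        best = None  # (-n_tree_neighbors, vertex)
        for v in sorted(verts - tree_vertices):
            n_nbrs = sum(1 for w in adj[v] if w in tree_vertices)
            if n_nbrs == 0:
                continue
            if best is None or (-n_nbrs, v) < best:
                best = (-n_nbrs, v)
        if best is None:
            raise RoutingError("graph is disconnected")
        v = best[1]
        w = min(x for x in adj[v] if x in tree_vertices)
        e = min(adj[v][w], key=lambda e: e.id)
        tree_edges.append(e.id)
        tree_vertices.add(v)
    return SpanningTree(graph, frozenset(tree_edges))


def number_of_spanning_trees(graph: WireframeGraph) -> int:
    """Kirchhoff matrix-tree count (simple graphs)."""
    verts = sorted(graph.positions)
    index = {v: i for i, v in enumerate(verts)}
    n = len(verts)
    lap = np.zeros((n, n))
    for e in graph.edges:
        i, j = index[e.u], index[e.v]
        lap[i, i] += 1
        lap[j, j] += 1
        lap[i, j] -= 1
        lap[j, i] -= 1
    if n <= 1:
        return 1
    minor = lap[1:, 1:]
    return int(round(np.linalg.det(minor)))


def xuong_tree(
    graph: WireframeGraph, mode: str = "auto", budget: int = 100_000
) -> SpanningTree:
    """Spanning tree minimising the number of odd-edge-count co-tree components.

    ``exact`` enumerates all spanning trees (guaranteed minimum, refused above
    ``budget`` trees); ``heuristic`` improves a Prim tree by edge swaps and is
    never worse than that starting tree; ``auto`` picks exact when the tree
    count fits the budget.  The number of odd components lower-bounds at the
    cycle rank's parity (Betti number mod 2).
    """
    if not graph.is_connected():
        raise RoutingError("graph must be connected")
    keys = {e.key for e in graph.edges}
    if len(keys) != len(graph.edges):
        raise RoutingError("xuong_tree expects a simple graph (no parallel edges)")
    n_trees = number_of_spanning_trees(graph)
    if mode == "auto":
        mode = "exact" if n_trees <= budget else "heuristic"
    if mode == "exact":
        if n_trees > budget:
            raise SizeError(
                f"{n_trees} spanning trees exceed the exact-mode budget "
                f"({budget}); use mode='heuristic'"
            )
        return _xuong_exact(graph)
    if mode == "heuristic":
        return _xuong_heuristic(graph)
    raise ValueError(f"unknown mode {mode!r}")


def _xuong_exact(graph: WireframeGraph) -> SpanningTree:
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.positions))
    eid_of = {}
    for e in graph.edges:
        g.add_edge(e.u, e.v)
        eid_of[e.key] = e.id
    betti = graph.n_edges - graph.n_vertices + 1
    lower_bound = betti % 2
    best: SpanningTree | None = None
    best_count = None
    for tree_graph in nx.SpanningTreeIterator(g):
        ids = frozenset(eid_of[(min(a, b), max(a, b))] for a, b in tree_graph.edges())
        tree = SpanningTree(graph, ids)
        count = tree.odd_component_count()
        if best_count is None or count < best_count:
            best, best_count = tree, count
            if count == lower_bound:
                break
    assert best is not None
    return best


def _xuong_heuristic(graph: WireframeGraph) -> SpanningTree:
    tree = prim_max_branching_tree(graph, seed_vertex=min(graph.positions))
    count = tree.odd_component_count()
    improved = True
    while improved:
        improved = False
        tree_ids = set(tree.edge_ids)
        g = nx.Graph()
        for eid in tree_ids:
            e = graph.edge(eid)
            g.add_edge(e.u, e.v, eid=eid)
        for cid in sorted(tree.cotree_ids):
            ce = graph.edge(cid)
            path = nx.shortest_path(g, ce.u, ce.v)
            for a, b in zip(path, path[1:]):
                fid = g.edges[a, b]["eid"]
                cand = SpanningTree(graph, frozenset(tree_ids - {fid} | {cid}))
                c = cand.odd_component_count()
                if c < count:
                    tree, count = cand, c
                    improved = True
                    break
            if improved:
                break
    return tree


# ----------------------------------------------------------------------
# Tree-boundary walks (ST-DNA, ST-RNA, XT-RNA)
# ----------------------------------------------------------------------


def _tree_walk(
    graph: WireframeGraph,
    tree: SpanningTree,
    on_nontree,
    root: int | None = None,
) -> list[Traversal]:
    """Boundary walk around the spanning tree following the rotation order.

    Tree edges are traversed down and back up; every rotation slot occupied by
    a non-tree edge is handed to ``on_nontree(vertex, edge_id, walk)``, which
    appends whatever traversals the method prescribes for that slot.
    """
    if root is None:
        root = min(graph.positions)
    tree_ids = tree.edge_ids
    walk: list[Traversal] = []

    def slots_after(v: int, eid: int | None) -> list[int]:
        r = graph.rotation[v]
        if eid is None:
            return list(r)
        i = r.index(eid)
        return [r[(i + 1 + k) % len(r)] for k in range(len(r) - 1)]

    def visit(v: int, enter: int | None) -> None:
        for f in slots_after(v, enter):
            e = graph.edge(f)
            w = e.other(v)
            if f in tree_ids:
                walk.append(Traversal(f, v, w, kind="tree"))
                visit(w, f)
                walk.append(Traversal(f, w, v, kind="tree"))
            else:
                on_nontree(v, f, walk)

    visit(root, None)
    return walk


def _longest_edge(graph: WireframeGraph, exclude: set[int]) -> int | None:
    candidates = [e.id for e in graph.edges if e.id not in exclude]
    if not candidates:
        return None
    return max(candidates, key=lambda eid: (graph.length(eid), -eid))


def st_route(graph: WireframeGraph, tree: SpanningTree) -> Route:
    """Scaffold route twice around a spanning tree (ST-DNA).

    Single closed walk; every edge traversed exactly twice, once per
    direction.  Non-tree edges are taken as a full out-and-back excursion at
    their first rotation slot and annotated for scaffold crossovers.
    """
    visited: set[int] = set()

    def on_nontree(v: int, f: int, walk: list[Traversal]) -> None:
        if f in visited:
            return
        visited.add(f)
        w = graph.edge(f).other(v)
        walk.append(Traversal(f, v, w, kind="crossover"))
        walk.append(Traversal(f, w, v, kind="crossover"))

    walk = _tree_walk(graph, tree, on_nontree)
    return Route(walks=[walk], method="st-dna", annotations={"tree": sorted(tree.edge_ids)})


def st_rna_route(graph: WireframeGraph, tree: SpanningTree) -> Route:
    """Single RNA strand twice around a spanning tree (ST-RNA).

    Every non-tree edge is represented as two hairpin half-edges meeting at
    the edge midpoint, flagged for a 180-degree kissing-loop pair.  The open
    3'-to-5' nick is annotated at the longest ordinary (non-kissing-loop)
    edge.
    """

    def on_nontree(v: int, f: int, walk: list[Traversal]) -> None:
        w = graph.edge(f).other(v)
        walk.append(Traversal(f, v, w, kind="cotree", half=True, kissing_loop=True))

    walk = _tree_walk(graph, tree, on_nontree)
    kl_edges = sorted(tree.cotree_ids)
    return Route(
        walks=[walk],
        method="st-rna",
        annotations={
            "tree": sorted(tree.edge_ids),
            "kissing_loops": kl_edges,
            "nick_edge": _longest_edge(graph, exclude=set(kl_edges)),
        },
    )


def xt_route(graph: WireframeGraph, tree: SpanningTree) -> Route:
    """Single strand route around a Xuong tree (XT-RNA).

    Even-sized co-tree components are traversed as ordinary duplex
    excursions; exactly one edge per odd-sized component is flagged as a
    kissing loop.  The nick is annotated at the longest non-kissing-loop
    edge.
    """
    comps = tree.cotree_components()
    kl_edges = {min(c) for c in comps if len(c) % 2 == 1}
    visited: set[int] = set()

    def on_nontree(v: int, f: int, walk: list[Traversal]) -> None:
        w = graph.edge(f).other(v)
        if f in kl_edges:
            walk.append(Traversal(f, v, w, kind="cotree", half=True, kissing_loop=True))
        else:
            if f in visited:
                return
            visited.add(f)
            walk.append(Traversal(f, v, w, kind="cotree"))
            walk.append(Traversal(f, w, v, kind="cotree"))

    walk = _tree_walk(graph, tree, on_nontree)
    return Route(
        walks=[walk],
        method="xt-rna",
        annotations={
            "tree": sorted(tree.edge_ids),
            "kissing_loops": sorted(kl_edges),
            "odd_components": tree.odd_component_count(),
            "nick_edge": _longest_edge(graph, exclude=kl_edges),
        },
    )


# ----------------------------------------------------------------------
# Reconditioning (T-join) and A-trails
# ----------------------------------------------------------------------


def recondition(graph: WireframeGraph) -> WireframeGraph:
    """Double edges so every vertex degree is even (minimum-length T-join).

    Odd-degree vertices are matched pairwise by a minimum-weight perfect
    matching over shortest-path distances; the edges on the matched paths are
    doubled (an edge used by an even number of paths cancels out).  Original
    edges are never removed.
    """
    if not graph.is_connected():
        raise RoutingError("graph must be connected")
    odd = sorted(v for v in graph.positions if graph.degree(v) % 2 == 1)
    if not odd:
        return graph
    g = nx.Graph()
    for e in graph.edges:
        w = graph.length(e.id)
        if not g.has_edge(e.u, e.v) or g.edges[e.u, e.v]["weight"] > w:
            g.add_edge(e.u, e.v, weight=w, eid=e.id)
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    complete = nx.Graph()
    for a, b in itertools.combinations(odd, 2):
        complete.add_edge(a, b, weight=dist[a][b])
    matching = nx.min_weight_matching(complete)
    usage: dict[int, int] = {}
    for a, b in sorted(tuple(sorted(p)) for p in matching):
        path = nx.dijkstra_path(g, a, b)
        for x, y in zip(path, path[1:]):
            eid = g.edges[x, y]["eid"]
            usage[eid] = usage.get(eid, 0) + 1
    doubled = sorted(eid for eid, n in usage.items() if n % 2 == 1)
    return graph.with_doubled_edges(doubled)


def _vertex_configs(graph: WireframeGraph, v: int) -> list[list[tuple[int, int]]]:
    """The (at most two) sharp-turn transition systems at a junction.

    The rotation order e0..e_{d-1} admits the pairings (e0 e1)(e2 e3)... and
    (e1 e2)...(e_{d-1} e0); a strand entering on one edge of a pair leaves on
    the other, i.e. every turn is to an immediate rotation neighbour.
    """
    r = graph.rotation[v]
    d = len(r)
    if d % 2 != 0:
        raise RoutingError(f"vertex {v} has odd degree {d}; recondition first")
    cfg0 = [(r[2 * i], r[2 * i + 1]) for i in range(d // 2)]
    cfg1 = [(r[(2 * i + 1) % d], r[(2 * i + 2) % d]) for i in range(d // 2)]
    if d == 2:
        return [cfg0]
    return [cfg0, cfg1]


def _end_id(graph: WireframeGraph, eid: int, v: int) -> int:
    e = graph.edge(eid)
    return 2 * eid + (0 if v == e.u else 1)


class _Dsu:
    """Union-find with rollback, tracking edge count per component."""

    def __init__(self, n_ends: int, edge_pairs: list[tuple[int, int]]):
        self.parent = list(range(n_ends))
        self.size = [1] * n_ends
        self.edges = [0] * n_ends
        self.history: list[tuple[int, int, int]] = []
        for a, b in edge_pairs:
            self.union(a, b, count_edge=True)
        self.base_mark = len(self.history)

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            x = self.parent[x]
        return x

    def union(self, a: int, b: int, count_edge: bool = False) -> bool:
        """Union; returns False if a cycle closed (already same component)."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.size[ra] > self.size[rb]:
            ra, rb = rb, ra
        self.history.append((ra, rb, self.edges[rb]))
        self.parent[ra] = rb
        self.size[rb] += self.size[ra]
        self.edges[rb] += self.edges[ra] + (1 if count_edge else 0)
        return True

    def mark(self) -> int:
        return len(self.history)

    def rollback(self, mark: int) -> None:
        while len(self.history) > mark:
            ra, rb, old_edges = self.history.pop()
            self.parent[ra] = ra
            self.size[rb] -= self.size[ra]
            self.edges[rb] = old_edges


@dataclass
class AtrailResult:
    """Outcome of an A-trail search: the circuit (if any), a proof flag when
    the configuration space was exhausted, and search statistics."""

    route: Route | None
    found: bool
    exhausted: bool
    nodes: int
    elapsed: float
    turn_config: dict[int, int] = field(default_factory=dict)


def atrail_search(
    graph: WireframeGraph, time_limit: float | None = None
) -> AtrailResult:
    """Branch-and-bound search for an A-trail.

    Requires an even-degree (reconditioned) connected wireframe with a
    rotation system.  Vertices are assigned in decreasing-degree order; a
    partial assignment is pruned as soon as the chosen transitions seal a
    circuit that does not contain every edge (union-find with rollback).
    """
    if not graph.is_connected():
        raise RoutingError("graph must be connected")
    for v in graph.positions:
        if graph.degree(v) % 2 != 0:
            raise RoutingError(f"vertex {v} has odd degree; recondition first")
    verts = sorted(graph.positions, key=lambda v: (-graph.degree(v), v))
    verts = [v for v in verts if graph.degree(v) > 0]
    configs = {v: _vertex_configs(graph, v) for v in verts}
    n_edges = graph.n_edges
    total_pairs = sum(graph.degree(v) // 2 for v in verts)
    max_end = 2 * max(e.id for e in graph.edges) + 2
    dsu = _Dsu(max_end, [(2 * e.id, 2 * e.id + 1) for e in graph.edges])
    start = time.monotonic()
    nodes = 0
    chosen: dict[int, int] = {}
    transitions: dict[int, int] = {}
    found_cfg: dict[int, int] | None = None
    timed_out = False

    def apply_config(v: int, cfg: list[tuple[int, int]], applied_before: int):
        """Apply a vertex's pairings; returns (ok, n_applied, success)."""
        applied = 0
        for ea, eb in cfg:
            a, b = _end_id(graph, ea, v), _end_id(graph, eb, v)
            merged = dsu.union(a, b)
            if not merged:  # a circuit sealed
                root = dsu.find(a)
                if (
                    applied_before + applied + 1 == total_pairs
                    and dsu.edges[root] == n_edges
                ):
                    applied += 1
                    return True, applied, True
                return False, applied, False
            applied += 1
        return True, applied, False

    def rec(i: int, applied_before: int) -> bool:
        nonlocal nodes, found_cfg, timed_out
        if time_limit is not None and time.monotonic() - start > time_limit:
            timed_out = True
            return False
        v = verts[i]
        for ci, cfg in enumerate(configs[v]):
            nodes += 1
            mark = dsu.mark()
            ok, applied, success = apply_config(v, cfg, applied_before)
            if success:
                chosen[v] = ci
                for ea, eb in cfg:
                    a, b = _end_id(graph, ea, v), _end_id(graph, eb, v)
                    transitions[a] = b
                    transitions[b] = a
                found_cfg = dict(chosen)
                return True
            if ok and i + 1 < len(verts):
                chosen[v] = ci
                for ea, eb in cfg:
                    a, b = _end_id(graph, ea, v), _end_id(graph, eb, v)
                    transitions[a] = b
                    transitions[b] = a
                if rec(i + 1, applied_before + applied):
                    return True
                for ea, eb in cfg:
                    a, b = _end_id(graph, ea, v), _end_id(graph, eb, v)
                    transitions.pop(a, None)
                    transitions.pop(b, None)
                chosen.pop(v, None)
            dsu.rollback(mark)
            if timed_out:
                return False
        return False

    found = rec(0, 0) if verts else False
    elapsed = time.monotonic() - start
    if not found:
        return AtrailResult(
            route=None,
            found=False,
            exhausted=not timed_out,
            nodes=nodes,
            elapsed=elapsed,
        )
    route = _extract_circuit(graph, transitions)
    route.method = "at-dna"
    route.annotations["turn_config"] = dict(found_cfg or {})
    return AtrailResult(
        route=route,
        found=True,
        exhausted=False,
        nodes=nodes,
        elapsed=elapsed,
        turn_config=dict(found_cfg or {}),
    )


def _extract_circuit(graph: WireframeGraph, transitions: dict[int, int]) -> Route:
    e0 = graph.edges[0]
    walk: list[Traversal] = []
    cur_eid, frm = e0.id, e0.u
    while True:
        e = graph.edge(cur_eid)
        to = e.other(frm)
        walk.append(Traversal(cur_eid, frm, to, kind="atrail"))
        arrive_end = _end_id(graph, cur_eid, to)
        nxt_end = transitions[arrive_end]
        nxt_eid = nxt_end // 2
        cur_eid, frm = nxt_eid, to
        if cur_eid == e0.id and frm == e0.u:
            break
        if len(walk) > graph.n_edges:
            raise RoutingError("transition system does not form a single circuit")
    if len(walk) != graph.n_edges:
        raise RoutingError("circuit does not cover every edge")
    walk = _annotate_turns(graph, walk)
    return Route(walks=[walk], method="at-dna")


def _annotate_turns(graph: WireframeGraph, walk: list[Traversal]) -> list[Traversal]:
    from dataclasses import replace

    out = []
    for t, nxt in zip(walk, walk[1:] + walk[:1]):
        v = t.to
        r = graph.rotation[v]
        i, j = r.index(t.edge_id), r.index(nxt.edge_id)
        d = len(r)
        turn = None
        if (i + 1) % d == j:
            turn = "right"
        elif (j + 1) % d == i:
            turn = "left"
        out.append(replace(t, turn=turn))
    return out


def atrail_exhaustive(
    graph: WireframeGraph, max_configs: int = 1 << 20, find_all: bool = False
) -> list[Route]:
    """Oracle: enumerate every sharp-turn transition-system combination.

    Independent of the branch-and-bound path: it simply counts the circuits
    of each full configuration.  Intended for graphs with at most ~20
    junctions."""
    verts = sorted(v for v in graph.positions if graph.degree(v) > 0)
    configs = {v: _vertex_configs(graph, v) for v in verts}
    n_combos = 1
    for v in verts:
        n_combos *= len(configs[v])
    if n_combos > max_configs:
        raise SizeError(f"{n_combos} configurations exceed the oracle budget")
    n_edges = graph.n_edges
    results: list[Route] = []
    for combo in itertools.product(*(range(len(configs[v])) for v in verts)):
        transitions: dict[int, int] = {}
        for v, ci in zip(verts, combo):
            for ea, eb in configs[v][ci]:
                a, b = _end_id(graph, ea, v), _end_id(graph, eb, v)
                transitions[a] = b
                transitions[b] = a
        # count circuit length from edge 0
        try:
            route = _extract_circuit(graph, transitions)
        except RoutingError:
            continue
        route.method = "at-dna"
        route.annotations["turn_config"] = {v: ci for v, ci in zip(verts, combo)}
        results.append(route)
        if not find_all:
            break
    return results


def check_sharp_turns(graph: WireframeGraph, route: Route) -> list[str]:
    """Return a list of sharp-turn violations (empty = valid A-trail turns)."""
    problems = []
    for walk in route.walks:
        for t, nxt in zip(walk, walk[1:] + walk[:1]):
            v = t.to
            r = graph.rotation[v]
            i, j = r.index(t.edge_id), r.index(nxt.edge_id)
            d = len(r)
            if (i + 1) % d != j and (j + 1) % d != i:
                problems.append(
                    f"at vertex {v}: edge {t.edge_id} -> edge {nxt.edge_id} "
                    "is not a sharp turn"
                )
    return problems


def import_atrail(graph: WireframeGraph, pairs: list[tuple[int, int]]) -> Route:
    """Validate a manually supplied A-trail (ordered vertex-pair sequence).

    The sequence must be a closed walk covering every (multi-)edge exactly
    once.  The sharp-turn property is checked and reported as a warning, not
    an error: imported trails on toroidal meshes may legitimately break it.
    """
    if not pairs:
        raise RouteImportError("empty edge sequence")
    available: dict[tuple[int, int], list[int]] = {}
    for e in graph.edges:
        available.setdefault(e.key, []).append(e.id)
    for key in available:
        available[key].sort()
    walk: list[Traversal] = []
    for a, b in pairs:
        key = (min(a, b), max(a, b))
        if key not in available or not available[key]:
            raise RouteImportError(f"edge ({a},{b}) missing or over-used")
        eid = available[key].pop(0)
        walk.append(Traversal(eid, a, b, kind="atrail"))
    if any(ids for ids in available.values()):
        missing = sorted(k for k, ids in available.items() if ids)
        raise RouteImportError(f"sequence does not cover edges {missing}")
    for t, nxt in zip(walk, walk[1:] + walk[:1]):
        if t.to != nxt.frm:
            raise RouteImportError(
                f"not a closed walk: traversal ends at {t.to}, next starts at {nxt.frm}"
            )
    route = Route(walks=[walk], method="at-dna")
    warnings = check_sharp_turns(graph, route)
    route.walks = [_annotate_turns(graph, walk)]
    route.annotations["warnings"] = warnings
    return route


# ----------------------------------------------------------------------
# Cycle cover (CC-DNA)
# ----------------------------------------------------------------------


def cycle_cover(
    graph: WireframeGraph, faces: list[list[int]] | None = None
) -> Route:
    """Directed cycles covering every edge once in each direction (CC-DNA).

    With faces (consistent outward winding), the cover is the set of
    face-boundary cycles, which double-cover the edges of a closed manifold
    antiparallel by construction.  Without faces, the cover traces the faces
    of the rotation-system embedding: entering a junction on edge ``e``, the
    strand leaves on the rotation successor of ``e``, so the transition
    pairing at every junction chains all its arms into one cycle (the
    junction's arms stay connected).
    """
    if not graph.is_connected():
        raise RoutingError("graph must be connected")
    by_key: dict[tuple[int, int], list[int]] = {}
    for e in graph.edges:
        by_key.setdefault(e.key, []).append(e.id)
    if faces is not None:
        walks = []
        for ring in faces:
            walk = []
            for i in range(len(ring)):
                a, b = ring[i], ring[(i + 1) % len(ring)]
                ids = by_key.get((min(a, b), max(a, b)))
                if not ids:
                    raise RoutingError(f"face edge ({a},{b}) not in graph")
                walk.append(Traversal(ids[0], a, b, kind="face"))
            walks.append(walk)
        return Route(walks=walks, method="cc-dna")
    # face tracing of the rotation-system embedding
    unused: set[tuple[int, int]] = set()
    for e in graph.edges:
        unused.add((e.id, e.u))
        unused.add((e.id, e.v))

    def next_dart(eid: int, arrive: int) -> tuple[int, int]:
        r = graph.rotation[arrive]
        nxt = r[(r.index(eid) + 1) % len(r)]
        return (nxt, arrive)

    walks = []
    while unused:
        eid, frm = min(unused)
        walk = []
        while (eid, frm) in unused:
            unused.remove((eid, frm))
            to = graph.edge(eid).other(frm)
            walk.append(Traversal(eid, frm, to, kind="edge"))
            eid, frm = next_dart(eid, to)
        walks.append(walk)
    return Route(walks=walks, method="cc-dna")


def check_junction_connectivity(route: Route, graph: WireframeGraph) -> None:
    """Verify the arms of every junction are connected by the cover's
    transition pairing (viewed as a local graph on incident edges)."""
    local: dict[int, nx.Graph] = {v: nx.Graph() for v in graph.positions}
    for v in graph.positions:
        for e in graph.incident(v):
            local[v].add_node(e.id)
    for walk in route.walks:
        for t, nxt in zip(walk, walk[1:] + walk[:1]):
            v = t.end
            if nxt.frm != v:
                raise RoutingError("walk not closed")
            local[v].add_edge(t.edge_id, nxt.edge_id)
    for v, g in local.items():
        if g.number_of_nodes() > 1 and not nx.is_connected(g):
            raise RoutingError(f"junction {v}: arms split into disconnected groups")
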