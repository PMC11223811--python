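"""Wireframe graph, routes and their validators.

The routing layer works on a *wireframe graph*: the vertices and edges of the
input mesh, with 3D positions, possibly with parallel edge copies added by
reconditioning, plus a rotation system (cyclic edge order around each vertex).
A *route* is one or more closed walks of directed edge traversals; every
design method's output is expressed this way and checked by the coverage
validators below.

A traversal may be a *half* traversal: the strand leaves a vertex towards the
edge midpoint and comes straight back (the hairpin half-edges of the RNA
methods).  For walk-adjacency purposes a half traversal ends where it started.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import RoutingError

__all__ = [
    "Edge",
    "WireframeGraph",
    "Traversal",
    "Route",
    "SpanningTree",
    "coverage_counts",
    "check_walks_closed",
    "check_double_coverage",
    "check_single_coverage",
    "route_to_text",
    "route_from_text",
]


@dataclass(frozen=True)
class Edge:
    """Undirected edge of the wireframe (multigraph: ids are unique, vertex
    pairs may repeat after reconditioning)."""

    id: int
    u: int
    v: int

    def other(self, w: int) -> int:
        if w == self.u:
            return self.v
        if w == self.v:
            return self.u
        raise ValueError(f"vertex {w} not on edge {self.id}")

    @property
    def key(self) -> tuple[int, int]:
        return (min(self.u, self.v), max(self.u, self.v))


class WireframeGraph:
    """Vertices with positions, (multi-)edges, rotation system, lengths."""

    def __init__(
        self,
        positions: dict[int, np.ndarray],
        edges: list[Edge],
        rotation: dict[int, list[int]] | None = None,
    ):
        self.positions = {v: np.asarray(p, dtype=float) for v, p in positions.items()}
        self.edges = list(edges)
        self._by_id = {e.id: e for e in self.edges}
        if rotation is None:
            rotation = self._default_rotation()
        self.rotation = {v: list(eids) for v, eids in rotation.items()}
        for e in self.edges:
            if self.length(e.id) <= 0:
                raise RoutingError(f"edge {e.id} has non-positive length")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_mesh(cls, mesh) -> "WireframeGraph":
        from .mesh import rotation_system

        positions = {i: mesh.vertices[i] for i in range(mesh.n_vertices)}
        edge_ids: dict[tuple[int, int], int] = {}
        edges = []
        for eid, (a, b) in enumerate(mesh.edges):
            edges.append(Edge(eid, a, b))
            edge_ids[(a, b)] = eid
        rot_nbrs = rotation_system(mesh)
        rotation = {
            v: [edge_ids[(min(v, w), max(v, w))] for w in nbrs]
            for v, nbrs in rot_nbrs.items()
        }
        return cls(positions, edges, rotation)

    @classmethod
    def from_edges(
        cls, positions: dict[int, np.ndarray], pairs: list[tuple[int, int]]
    ) -> "WireframeGraph":
        """Abstract wireframe from a vertex-pair list; rotation falls back to
        the angular order of edge directions (best-fit plane per vertex)."""
        edges = [Edge(i, a, b) for i, (a, b) in enumerate(pairs)]
        return cls(positions, edges)

    def _default_rotation(self) -> dict[int, list[int]]:
        rot: dict[int, list[int]] = {v: [] for v in self.positions}
        for v in self.positions:
            incident = [e for e in self.edges if v in (e.u, e.v)]
            if not incident:
                continue
            dirs = []
            for e in incident:
                d = self.positions[e.other(v)] - self.positions[v]
                n = np.linalg.norm(d)
                dirs.append(d / n if n > 0 else d)
            dirs = np.array(dirs)
            if len(incident) == 1:
                rot[v] = [incident[0].id]
                continue
            _, _, vt = np.linalg.svd(dirs - dirs.mean(axis=0))
            normal = vt[-1] if len(incident) > 2 else np.cross(dirs[0], dirs[1])
            if np.linalg.norm(normal) < 1e-12:
                normal = vt[-1]
            normal = normal / max(np.linalg.norm(normal), 1e-12)
            ref = dirs[0] - np.dot(dirs[0], normal) * normal
            if np.linalg.norm(ref) < 1e-12:
                ref = np.cross(normal, [1.0, 0.0, 0.0])
            ref /= np.linalg.norm(ref)
            ref2 = np.cross(normal, ref)
            ang = np.arctan2(dirs @ ref2, dirs @ ref)
            order = sorted(
                range(len(incident)), key=lambda i: (ang[i], incident[i].id)
            )
            rot[v] = [incident[i].id for i in order]
        return rot

    # -- queries ---------------------------------------------------------
    def edge(self, eid: int) -> Edge:
        return self._by_id[eid]

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def length(self, eid: int) -> float:
        e = self._by_id[eid]
        return float(np.linalg.norm(self.positions[e.u] - self.positions[e.v]))

    def incident(self, v: int) -> list[Edge]:
        return [e for e in self.edges if v in (e.u, e.v)]

    def degree(self, v: int) -> int:
        return sum(2 if e.u == e.v else 1 for e in self.incident(v))

    def is_connected(self) -> bool:
        verts = [v for v in self.positions if self.degree(v) > 0] or list(
            self.positions
        )
        seen = {verts[0]}
        stack = [verts[0]]
        adj: dict[int, set[int]] = {v: set() for v in self.positions}
        for e in self.edges:
            adj[e.u].add(e.v)
            adj[e.v].add(e.u)
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == len(verts)

    def with_doubled_edges(self, eids: list[int]) -> "WireframeGraph":
        """Return a copy with a parallel twin of each listed edge, inserted
        right after the original in both endpoints' rotation orders."""
        edges = list(self.edges)
        rotation = {v: list(r) for v, r in self.rotation.items()}
        next_id = max((e.id for e in edges), default=-1) + 1
        for eid in eids:
            orig = self._by_id[eid]
            twin = Edge(next_id, orig.u, orig.v)
            edges.append(twin)
            for v in {orig.u, orig.v}:
                idx = rotation[v].index(eid)
                rotation[v].insert(idx + 1, twin.id)
            next_id += 1
        return WireframeGraph(self.positions, edges, rotation)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(self.positions)
        for e in self.edges:
            g.add_edge(e.u, e.v, key=e.id, weight=self.length(e.id), eid=e.id)
        return g


@dataclass(frozen=True)
class Traversal:
    """One directed pass over an edge.

    ``half`` marks an out-and-back hairpin excursion towards the edge
    midpoint: the walk continues from ``frm`` afterwards.
    """

    edge_id: int
    frm: int
    to: int
    kind: str = "edge"  # tree | cotree | crossover | edge | face
    half: bool = False
    kissing_loop: bool = False
    turn: str | None = None  # A-trail: "left" | "right"

    @property
    def end(self) -> int:
        """Vertex at which the walk continues after this traversal."""
        return self.frm if self.half else self.to

    def reversed(self) -> "Traversal":
        return replace(self, frm=self.to, to=self.frm)


@dataclass
class Route:
    """One or more closed walks plus method-level annotations."""

    walks: list[list[Traversal]]
    method: str = ""
    annotations: dict = field(default_factory=dict)

    @property
    def n_traversals(self) -> int:
        return sum(len(w) for w in self.walks)

    def all_traversals(self) -> list[Traversal]:
        return [t for w in self.walks for t in w]


@dataclass
class SpanningTree:
    """Tree edge subset of a wireframe graph, with co-tree component info."""

    graph: WireframeGraph
    edge_ids: frozenset[int]

    def __post_init__(self):
        n_active = len(
            {v for e in self.graph.edges for v in (e.u, e.v)}
        ) or self.graph.n_vertices
        if len(self.edge_ids) != n_active - 1:
            raise RoutingError(
                f"spanning tree must have V-1 = {n_active - 1} edges, "
                f"got {len(self.edge_ids)}"
            )

    @property
    def cotree_ids(self) -> frozenset[int]:
        return frozenset(e.id for e in self.graph.edges) - self.edge_ids

    def cotree_components(self) -> list[list[int]]:
        """Connected components of the co-tree, as lists of edge ids."""
        cotree = [self.graph.edge(eid) for eid in sorted(self.cotree_ids)]
        parent: dict[int, int] = {}

        def find(x: int) -> int:
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for e in cotree:
            parent.setdefault(e.u, e.u)
            parent.setdefault(e.v, e.v)
            union(e.u, e.v)
        comps: dict[int, list[int]] = {}
        for e in cotree:
            comps.setdefault(find(e.u), []).append(e.id)
        return sorted(comps.values(), key=lambda c: min(c))

    def odd_component_count(self) -> int:
        return sum(1 for c in self.cotree_components() if len(c) % 2 == 1)


# -- validators ----------------------------------------------------------


def check_walks_closed(route: Route) -> None:
    for wi, walk in enumerate(route.walks):
        if not walk:
            raise RoutingError(f"walk {wi} is empty")
        for t, nxt in zip(walk, walk[1:] + walk[:1]):
            if t.end != nxt.frm:
                raise RoutingError(
                    f"walk {wi} broken: traversal ends at {t.end}, "
                    f"next starts at {nxt.frm}"
                )


def coverage_counts(route: Route) -> dict[int, dict[tuple[int, int], int]]:
    """Per edge id: directed traversal counts keyed by (frm, to).

    Half traversals count as a directed pass in their stated direction."""
    counts: dict[int, dict[tuple[int, int], int]] = {}
    for t in route.all_traversals():
        d = counts.setdefault(t.edge_id, {})
        d[(t.frm, t.to)] = d.get((t.frm, t.to), 0) + 1
    return counts


def check_double_coverage(route: Route, graph: WireframeGraph) -> None:
    """Every edge traversed exactly twice, once per direction."""
    counts = coverage_counts(route)
    for e in graph.edges:
        d = counts.get(e.id, {})
        fwd = d.get((e.u, e.v), 0)
        rev = d.get((e.v, e.u), 0)
        if fwd != 1 or rev != 1:
            raise RoutingError(
                f"edge {e.id} ({e.u},{e.v}) covered {fwd}x forward / {rev}x "
                "reverse; expected exactly once each way"
            )


def check_single_coverage(route: Route, graph: WireframeGraph) -> None:
    """Every (multi-)edge traversed exactly once in either direction."""
    counts = coverage_counts(route)
    for e in graph.edges:
        total = sum(counts.get(e.id, {}).values())
        if total != 1:
            raise RoutingError(
                f"edge {e.id} ({e.u},{e.v}) traversed {total}x; expected once"
            )


# -- plain-text route exchange -------------------------------------------


def route_to_text(route: Route) -> str:
    """One ``u v`` pair per traversal; ``#`` comments carry annotations."""
    lines = [f"# method: {route.method or 'unknown'}"]
    for wi, walk in enumerate(route.walks):
        lines.append(f"# walk {wi}")
        for t in walk:
            flags = []
            if t.half:
                flags.append("half")
            if t.kissing_loop:
                flags.append("kl")
            suffix = ("  # " + ",".join(flags)) if flags else ""
            lines.append(f"{t.frm} {t.to}{suffix}")
    return "\n".join(lines) + "\n"


def route_from_text(text: str) -> list[tuple[int, int]]:
    """Parse a ``u v`` per-line edge sequence (comments ignored)."""
    pairs: list[tuple[int, int]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise RoutingError(f"bad route line {raw!r}")
        pairs.append((int(parts[0]), int(parts[1])))
    return pairs
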