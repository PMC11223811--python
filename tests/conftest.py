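"""Shared fixtures: canonical meshes and small abstract wireframe graphs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wireweaver import WireframeGraph, make_mesh


@pytest.fixture
def tetra_mesh():
    return make_mesh("tetrahedron")


@pytest.fixture
def tetra_graph(tetra_mesh):
    return WireframeGraph.from_mesh(tetra_mesh)


@pytest.fixture
def octa_graph():
    return WireframeGraph.from_mesh(make_mesh("octahedron"))


def ring_positions(n: int, radius: float = 1.0, z: float = 0.0):
    return {
        i: np.array(
            [radius * math.cos(2 * math.pi * i / n),
             radius * math.sin(2 * math.pi * i / n), z]
        )
        for i in range(n)
    }


@pytest.fixture
def path_graph():
    """P4: a path on 4 vertices (its own unique spanning tree)."""
    pos = {i: np.array([float(i), 0.1 * (i % 2), 0.0]) for i in range(4)}
    return WireframeGraph.from_edges(pos, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def cycle_graph():
    """C4: a 4-cycle (Betti number 1)."""
    pos = ring_positions(4)
    return WireframeGraph.from_edges(pos, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def wheel_graph():
    """W5: hub 0 plus a 4-vertex rim."""
    pos = {0: np.array([0.0, 0.0, 0.0])}
    rim = ring_positions(4)
    for i in range(4):
        pos[i + 1] = rim[i]
    edges = [(0, i) for i in range(1, 5)] + [(1, 2), (2, 3), (3, 4), (4, 1)]
    return WireframeGraph.from_edges(pos, edges)


@pytest.fixture
def bowtie_graph():
    """Two triangles sharing one degree-4 cut vertex."""
    pos = {
        0: np.array([0.0, 0.0, 0.0]),
        1: np.array([-1.0, 0.6, 0.0]),
        2: np.array([-1.0, -0.6, 0.0]),
        3: np.array([1.0, 0.6, 0.0]),
        4: np.array([1.0, -0.6, 0.0]),
    }
    return WireframeGraph.from_edges(
        pos, [(0, 1), (1, 2), (2, 0), (0, 3), (3, 4), (4, 0)]
    )


@pytest.fixture
def two_triangles_graph():
    """Two triangles sharing an edge (Betti number 2)."""
    pos = {
        0: np.array([0.0, 0.0, 0.0]),
        1: np.array([1.0, 0.0, 0.0]),
        2: np.array([0.5, 1.0, 0.0]),
        3: np.array([0.5, -1.0, 0.0]),
    }
    return WireframeGraph.from_edges(
        pos, [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3)]
    )


# ----------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check)
# ----------------------------------------------------------------------


def lrs_bruteforce(strands) -> int:
    """Longest repeated substring via the O(n^2) common-extension table.

    Strands are joined with unique separator characters so no match can
    cross a strand boundary; dp[i, j] is the length of the common substring
    starting at positions i and j, and any repeat shows up as dp[i, j] > 0
    for i != j.
    """
    strands = [s for s in strands if s]
    if not strands:
        return 0
    text = ""
    for i, s in enumerate(strands):
        if i:
            text += chr(1 + i)  # unique separator, never matches anything
        text += s
    arr = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
    n = len(arr)
    eq = arr[:, None] == arr[None, :]
    np.fill_diagonal(eq, False)
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    for i in range(n - 1, -1, -1):
        dp[i, :-1] = np.where(eq[i], dp[i + 1, 1:] + 1, 0)
    return int(dp.max())


def spanning_trees_bruteforce(graph: WireframeGraph):
    """All spanning trees by testing every (V-1)-edge subset."""
    import itertools

    verts = sorted(graph.positions)
    n = len(verts)
    trees = []
    for combo in itertools.combinations(graph.edges, n - 1):
        parent = {v: v for v in verts}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for e in combo:
            ra, rb = find(e.u), find(e.v)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            trees.append(frozenset(e.id for e in combo))
    return trees


def eulerian_circuits_bruteforce(graph: WireframeGraph, start: int = 0):
    """All Eulerian circuits from a fixed start vertex, by backtracking.

    Returned as lists of (edge_id, frm, to); only for tiny graphs.
    """
    edges = graph.edges
    used = [False] * len(edges)
    incident = {v: [e for e in edges if v in (e.u, e.v)] for v in graph.positions}
    circuits = []
    walk = []

    def rec(v):
        if all(used):
            if v == start:
                circuits.append(list(walk))
            return
        for e in incident[v]:
            if used[[x.id for x in edges].index(e.id)]:
                continue
            idx = next(i for i, x in enumerate(edges) if x.id == e.id)
            used[idx] = True
            w = e.other(v)
            walk.append((e.id, v, w))
            rec(w)
            walk.pop()
            used[idx] = False

    rec(start)
    return circuits


def is_sharp_turn_circuit(graph: WireframeGraph, circuit) -> bool:
    """Check the sharp-turn property directly against the rotation system."""
    for (e1, _, v), (e2, frm, _) in zip(circuit, circuit[1:] + circuit[:1]):
        if frm != v:
            return False
        r = graph.rotation[v]
        i, j = r.index(e1), r.index(e2)
        d = len(r)
        if (i + 1) % d != j and (j + 1) % d != i:
            return False
    return True
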