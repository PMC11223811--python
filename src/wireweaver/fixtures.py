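"""Canonical test meshes, generated programmatically.

Every mesh here is a closed orientable manifold with known vertex/edge/face
counts, so tests and examples never need external files.  Platonic solids are
emitted at unit circumradius; the quad torus uses major/minor radii 2 / 0.7
mesh units.  Face windings are made globally consistent and outward-facing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .mesh import Mesh, write_obj

__all__ = ["FixtureSpec", "make_mesh", "make_obj", "SHAPES"]

SHAPES = ("tetrahedron", "cube", "octahedron", "icosahedron", "prism", "torus")


@dataclass
class FixtureSpec:
    """Shape request: id, uniform edge scale, torus ring counts."""

    shape: str
    scale: float = 1.0
    torus_m: int = 4
    torus_n: int = 4


def _orient(vertices: np.ndarray, faces: list[list[int]]) -> list[list[int]]:
    """Make face windings consistent and outward (positive enclosed volume)."""
    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for fi, ring in enumerate(faces):
        for i in range(len(ring)):
            a, b = ring[i], ring[(i + 1) % len(ring)]
            edge_to_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
    oriented = [list(r) for r in faces]
    seen = {0}
    stack = [0]
    while stack:
        fi = stack.pop()
        ring = oriented[fi]
        directed = {(ring[i], ring[(i + 1) % len(ring)]) for i in range(len(ring))}
        for i in range(len(ring)):
            a, b = ring[i], ring[(i + 1) % len(ring)]
            for fj in edge_to_faces[(min(a, b), max(a, b))]:
                if fj in seen:
                    continue
                other = oriented[fj]
                other_dir = {
                    (other[k], other[(k + 1) % len(other)]) for k in range(len(other))
                }
                if (a, b) in other_dir:  # same direction -> flip neighbour
                    oriented[fj] = other[::-1]
                seen.add(fj)
                stack.append(fj)
        del directed
    volume = 0.0
    for ring in oriented:
        pts = vertices[ring]
        for i in range(1, len(ring) - 1):
            volume += np.dot(pts[0], np.cross(pts[i], pts[i + 1])) / 6.0
    if volume < 0:
        oriented = [r[::-1] for r in oriented]
    return oriented


def _tetrahedron() -> Mesh:
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / math.sqrt(3)
    f = [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]
    return Mesh(v, _orient(v, f))


def _cube() -> Mesh:
    v = (
        np.array(
            [
                [-1, -1, -1],
                [1, -1, -1],
                [1, 1, -1],
                [-1, 1, -1],
                [-1, -1, 1],
                [1, -1, 1],
                [1, 1, 1],
                [-1, 1, 1],
            ],
            dtype=float,
        )
        / math.sqrt(3)
    )
    f = [
        [0, 1, 2, 3],
        [4, 5, 6, 7],
        [0, 1, 5, 4],
        [1, 2, 6, 5],
        [2, 3, 7, 6],
        [3, 0, 4, 7],
    ]
    return Mesh(v, _orient(v, f))


def _octahedron() -> Mesh:
    v = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    f = [
        [0, 2, 4],
        [2, 1, 4],
        [1, 3, 4],
        [3, 0, 4],
        [0, 2, 5],
        [2, 1, 5],
        [1, 3, 5],
        [3, 0, 5],
    ]
    return Mesh(v, _orient(v, f))


def _icosahedron() -> Mesh:
    phi = (1 + math.sqrt(5)) / 2
    raw = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            raw.append([0, s1, s2 * phi])
            raw.append([s1, s2 * phi, 0])
            raw.append([s2 * phi, 0, s1])
    v = np.array(raw, dtype=float)
    v /= np.linalg.norm(v[0])
    from scipy.spatial import ConvexHull

    hull = ConvexHull(v)
    f = [list(s) for s in hull.simplices]
    return Mesh(v, _orient(v, f))


def _prism() -> Mesh:
    h = 0.5
    r = math.sqrt(1 - h * h)
    top = [[r * math.cos(a), r * math.sin(a), h] for a in (0, 2 * math.pi / 3, 4 * math.pi / 3)]
    bot = [[p[0], p[1], -h] for p in top]
    v = np.array(top + bot, dtype=float)
    f = [
        [0, 1, 2],
        [3, 4, 5],
        [0, 1, 4, 3],
        [1, 2, 5, 4],
        [2, 0, 3, 5],
    ]
    return Mesh(v, _orient(v, f))


def _torus(m: int, n: int) -> Mesh:
    if m < 3 or n < 3:
        raise ParameterError("torus ring counts must both be >= 3")
    R, r = 2.0, 0.7
    verts = []
    for i in range(m):
        th = 2 * math.pi * i / m
        for j in range(n):
            ph = 2 * math.pi * j / n
            verts.append(
                [
                    (R + r * math.cos(ph)) * math.cos(th),
                    (R + r * math.cos(ph)) * math.sin(th),
                    r * math.sin(ph),
                ]
            )
    v = np.array(verts, dtype=float)

    def vid(i: int, j: int) -> int:
        return (i % m) * n + (j % n)

    f = [
        [vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)]
        for i in range(m)
        for j in range(n)
    ]
    return Mesh(v, _orient(v, f))


def make_mesh(spec: FixtureSpec | str) -> Mesh:
    """Build a fixture mesh.  Accepts a shape name or a :class:`FixtureSpec`."""
    if isinstance(spec, str):
        spec = FixtureSpec(shape=spec)
    builders = {
        "tetrahedron": _tetrahedron,
        "cube": _cube,
        "octahedron": _octahedron,
        "icosahedron": _icosahedron,
        "prism": _prism,
    }
    if spec.shape == "torus":
        mesh = _torus(spec.torus_m, spec.torus_n)
    elif spec.shape in builders:
        mesh = builders[spec.shape]()
    else:
        raise ParameterError(f"unknown fixture shape {spec.shape!r}; choose from {SHAPES}")
    if spec.scale != 1.0:
        mesh = Mesh(mesh.vertices * spec.scale, mesh.faces)
    return mesh


def make_obj(spec: FixtureSpec | str) -> str:
    """Fixture mesh as canonical OBJ text."""
    if isinstance(spec, str):
        spec = FixtureSpec(shape=spec)
    return write_obj(make_mesh(spec), comment=f"wireweaver fixture: {spec.shape}")
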