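"""Polygon-mesh surface representation.

A wireframe nanostructure design starts from a polygon surface mesh in
Wavefront OBJ format.  This module reads and writes the OBJ dialect emitted by
the usual modelling suites (Blender, Maya), derives the edge set, analyses the
surface topology (closedness, orientability, genus via the Euler
characteristic), and computes the *rotation system* -- the cyclic order of
edges around each vertex induced by the surface embedding.  The rotation
system is what makes "sharp left / sharp right" turns at a junction
well-defined for A-trail routing.

Faces are used exactly as given: no triangulation, no vertex welding (an
optional ``merge_epsilon`` welds coincident vertices on request, off by
default, because welding can silently change the topology).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, GeometryError

__all__ = [
    "Mesh",
    "TopologyReport",
    "parse_obj",
    "write_obj",
    "analyze_topology",
    "rotation_system",
]


@dataclass
class Mesh:
    """Vertices and ordered face rings, with derived edges.

    ``vertices`` is an (V, 3) float array in the input's (arbitrary) mesh
    units; conversion to nanometers happens only in the cylinder model via the
    user's scale parameter.  ``faces`` preserve the input winding order and use
    0-based indices.
    """

    vertices: np.ndarray
    faces: list[list[int]] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of unordered vertex pairs appearing in some face."""
        seen = set()
        for ring in self.faces:
            n = len(ring)
            for i in range(n):
                a, b = ring[i], ring[(i + 1) % n]
                seen.add((min(a, b), max(a, b)))
        return sorted(seen)

    def directed_edge_uses(self) -> dict[tuple[int, int], int]:
        """Count how many times each directed edge (a, b) is used by a face."""
        uses: dict[tuple[int, int], int] = {}
        for ring in self.faces:
            n = len(ring)
            for i in range(n):
                d = (ring[i], ring[(i + 1) % n])
                uses[d] = uses.get(d, 0) + 1
        return uses

    def vertex_degrees(self) -> dict[int, int]:
        deg: dict[int, int] = {v: 0 for v in range(self.n_vertices)}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


@dataclass
class TopologyReport:
    """Surface diagnosis of a mesh.

    ``genus`` is defined (non-None) only for connected, closed, orientable
    manifolds, where V - E + F = 2 - 2g.
    """

    is_closed_manifold: bool
    is_orientable: bool
    connected: bool
    genus: int | None
    odd_degree_vertex_count: int
    n_vertices: int = 0
    n_edges: int = 0
    n_faces: int = 0


def parse_obj(text: str, merge_epsilon: float | None = None) -> Mesh:
    """Parse a Wavefront OBJ document into a :class:`Mesh`.

    Accepts ``v`` and ``f`` records and comments; silently skips ``vn``,
    ``vt``, ``o``, ``g``, ``s``, ``usemtl`` and ``mtllib``.  Face entries of
    the form ``v/vt/vn`` keep only the vertex index.  OBJ's 1-based and
    negative (relative) indices are both accepted; internal indices are
    0-based.

    Parameters
    ----------
    merge_epsilon:
        If given, vertices closer than this distance are welded together
        (first occurrence wins).  Off by default.
    """
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    skip = {"vn", "vt", "vp", "o", "g", "s", "usemtl", "mtllib", "l", "p"}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "v":
            if len(parts) < 4:
                raise FormatError(f"line {lineno}: vertex needs 3 coordinates")
            try:
                vertices.append([float(x) for x in parts[1:4]])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad vertex coordinate") from exc
        elif tag == "f":
            ring: list[int] = []
            for token in parts[1:]:
                head = token.split("/", 1)[0]
                try:
                    idx = int(head)
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: bad face index {token!r}") from exc
                if idx > 0:
                    idx -= 1
                elif idx < 0:
                    idx = len(vertices) + idx
                else:
                    raise FormatError(f"line {lineno}: face index 0 is invalid")
                ring.append(idx)
            if len(ring) < 3 or len(set(ring)) < 3:
                raise FormatError(
                    f"line {lineno}: face needs at least 3 distinct vertices"
                )
            faces.append(ring)
        elif tag in skip:
            continue
        # unknown records are ignored, matching common OBJ readers
    if not vertices or not faces:
        raise FormatError("OBJ document must contain at least one 'v' and one 'f'")
    nv = len(vertices)
    for ring in faces:
        for idx in ring:
            if not (0 <= idx < nv):
                raise FormatError(f"face index {idx + 1} out of range (V={nv})")
    verts = np.asarray(vertices, dtype=float)
    mesh = Mesh(vertices=verts, faces=faces)
    if merge_epsilon is not None:
        mesh = _weld(mesh, merge_epsilon)
    return mesh


def _weld(mesh: Mesh, eps: float) -> Mesh:
    remap: dict[int, int] = {}
    kept: list[int] = []
    for i, p in enumerate(mesh.vertices):
        for j in kept:
            if np.linalg.norm(p - mesh.vertices[j]) <= eps:
                remap[i] = j
                break
        else:
            remap[i] = i
            kept.append(i)
    new_index = {old: k for k, old in enumerate(kept)}
    verts = mesh.vertices[kept]
    faces = [[new_index[remap[i]] for i in ring] for ring in mesh.faces]
    return Mesh(vertices=verts, faces=faces)


def write_obj(mesh: Mesh, comment: str | None = None) -> str:
    """Serialize back to OBJ text (1-based indices, 6-decimal coordinates)."""
    lines: list[str] = []
    if comment:
        lines.append(f"# {comment}")
    for p in mesh.vertices:
        lines.append("v " + " ".join(f"{x:.6f}" for x in p))
    for ring in mesh.faces:
        lines.append("f " + " ".join(str(i + 1) for i in ring))
    return "\n".join(lines) + "\n"


def _connected(mesh: Mesh) -> bool:
    edges = mesh.edges
    if mesh.n_vertices == 0:
        return False
    adj: dict[int, list[int]] = {v: [] for v in range(mesh.n_vertices)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == mesh.n_vertices


def analyze_topology(mesh: Mesh) -> TopologyReport:
    """Diagnose the surface: closed-manifold / orientable flags and genus.

    A mesh is reported closed-manifold when every undirected edge is shared by
    exactly two faces; orientable when, additionally, the two faces use the
    edge in opposite directions (each directed edge appears exactly once).
    Genus follows from the Euler characteristic on connected closed
    orientable surfaces.
    """
    uses = mesh.directed_edge_uses()
    edges = mesh.edges
    closed = True
    orientable = True
    for a, b in edges:
        fwd = uses.get((a, b), 0)
        rev = uses.get((b, a), 0)
        if fwd + rev != 2:
            closed = False
        if fwd > 1 or rev > 1:
            orientable = False
    connected = _connected(mesh)
    genus: int | None = None
    if closed and orientable and connected:
        chi = mesh.n_vertices - len(edges) + len(mesh.faces)
        if chi % 2 == 0 and chi <= 2:
            genus = (2 - chi) // 2
        else:  # inconsistent surface; leave genus undefined
            genus = None
    odd = sum(1 for d in mesh.vertex_degrees().values() if d % 2 == 1)
    return TopologyReport(
        is_closed_manifold=closed,
        is_orientable=orientable,
        connected=connected,
        genus=genus,
        odd_degree_vertex_count=odd,
        n_vertices=mesh.n_vertices,
        n_edges=len(edges),
        n_faces=len(mesh.faces),
    )


def rotation_system(mesh: Mesh) -> dict[int, list[int]]:
    """Cyclic order of neighbour vertices around each vertex.

    For a closed orientable manifold the order is read off the face
    incidence: at a face corner ``(a, v, b)`` the edges ``(v, a)`` and
    ``(v, b)`` are consecutive, and chaining corners around ``v`` yields a
    single cycle through all incident edges.  Reversing the global face
    orientation reverses every cycle.

    For non-manifold or faceless inputs the fallback is geometric: incident
    edge directions are projected onto the plane perpendicular to an estimated
    vertex normal (average incident face normal, or the best-fit plane normal
    of the edge directions) and sorted by angle.
    """
    report = analyze_topology(mesh)
    for a, b in mesh.edges:
        if np.linalg.norm(mesh.vertices[a] - mesh.vertices[b]) == 0.0:
            raise GeometryError(f"zero-length edge ({a}, {b})")
    if report.is_closed_manifold and report.is_orientable:
        return _rotation_from_faces(mesh)
    return _rotation_angular(mesh)


def _rotation_from_faces(mesh: Mesh) -> dict[int, list[int]]:
    succ: dict[int, dict[int, int]] = {v: {} for v in range(mesh.n_vertices)}
    for ring in mesh.faces:
        n = len(ring)
        for i in range(n):
            a, v, b = ring[i - 1], ring[i], ring[(i + 1) % n]
            # corner (a, v, b): around v, edge (v, b) follows edge (v, a)
            succ[v][a] = b
    rot: dict[int, list[int]] = {}
    for v, nxt in succ.items():
        if not nxt:
            rot[v] = []
            continue
        start = min(nxt)
        cycle = [start]
        cur = nxt[start]
        while cur != start:
            cycle.append(cur)
            cur = nxt[cur]
            if len(cycle) > len(nxt):
                raise GeometryError(
                    f"vertex {v}: face incidence does not close into one cycle"
                )
        if len(cycle) != len(nxt):
            raise GeometryError(
                f"vertex {v}: edge umbrella splits into several fans (non-manifold)"
            )
        rot[v] = cycle
    return rot


def _vertex_normals(mesh: Mesh) -> dict[int, np.ndarray]:
    normals: dict[int, np.ndarray] = {v: np.zeros(3) for v in range(mesh.n_vertices)}
    for ring in mesh.faces:
        pts = mesh.vertices[ring]
        n = np.zeros(3)
        for i in range(len(ring)):  # Newell's method, robust for any polygon
            p, q = pts[i], pts[(i + 1) % len(ring)]
            n += np.cross(p, q)
        for v in ring:
            normals[v] += n
    return normals


def _rotation_angular(mesh: Mesh) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {v: [] for v in range(mesh.n_vertices)}
    for a, b in mesh.edges:
        adj[a].append(b)
        adj[b].append(a)
    face_normals = _vertex_normals(mesh)
    rot: dict[int, list[int]] = {}
    for v, nbrs in adj.items():
        if not nbrs:
            rot[v] = []
            continue
        dirs = np.array(
            [mesh.vertices[w] - mesh.vertices[v] for w in nbrs], dtype=float
        )
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(norms == 0):
            raise GeometryError(f"zero-length edge at vertex {v}")
        dirs /= norms[:, None]
        normal = face_normals[v]
        if np.linalg.norm(normal) < 1e-12:
            # best-fit plane of the edge directions
            _, _, vt = np.linalg.svd(dirs)
            normal = vt[-1]
        normal = normal / np.linalg.norm(normal)
        ref = dirs[0] - np.dot(dirs[0], normal) * normal
        if np.linalg.norm(ref) < 1e-12:
            ref = np.cross(normal, [1.0, 0.0, 0.0])
            if np.linalg.norm(ref) < 1e-12:
                ref = np.cross(normal, [0.0, 1.0, 0.0])
        ref /= np.linalg.norm(ref)
        ref2 = np.cross(normal, ref)
        angles = np.arctan2(dirs @ ref2, dirs @ ref)
        order = sorted(range(len(nbrs)), key=lambda i: (angles[i], nbrs[i]))
        rot[v] = [nbrs[i] for i in order]
    return rot
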