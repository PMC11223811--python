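"""Cylinder model: one rigid double helix per routed duplex segment.

Each duplex is abstracted as a cylinder with a 4x4 rigid transform (local Y =
helix axis), a base-pair count, a radius, and four connection points -- the
two 5' and two 3' strand ends.  The user's *scale* parameter converts mesh
units to nanometers: at a scale of 1 nm, an edge of length 1 becomes a
cylinder of nominal length 1 nm.  DNA cylinders are 2.0 nm in diameter
(B-form), RNA cylinders 2.3 nm (A-form).

Cylinders meeting at a junction are shortened by a vertex clearance
d = r / tan(alpha/2) (alpha = smallest angle to a neighbouring edge) so their
bodies do not overlap, and may optionally be relaxed as damped spring-linked
rigid bodies to shorten the inter-helix linkers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError, RelaxationError
from .graph import Route, Traversal, WireframeGraph

__all__ = [
    "HelixGeometry",
    "DesignParameters",
    "Cylinder",
    "CylinderLink",
    "CylinderModel",
    "build_cylinder_model",
    "round_to_turns",
    "relax",
    "spring_objective",
]

CONNECTION_POINTS = ("first5", "first3", "second5", "second3")

PAIRED_METHODS = {"cc-dna", "st-rna", "xt-rna"}  # both strands routed


@dataclass(frozen=True)
class HelixGeometry:
    """Geometric constants of a double helix.

    Diameters follow the B-DNA (2.0 nm) and A-RNA (2.3 nm) conventions; rise
    and twist are the standard helical parameters (DNA: 0.332 nm/bp at 10.5
    bp/turn; RNA: 0.281 nm/bp at 11.0 bp/turn).  ``groove_offset_deg`` is the
    angular offset between the two backbones of a base pair (minor groove).
    """

    nucleic_acid: str
    diameter: float
    rise_per_bp: float
    bp_per_turn: float
    backbone_radius_factor: float = 0.9
    groove_offset_deg: float = 120.0

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def twist_per_bp(self) -> float:
        """Degrees of helical twist per base pair (360 / bp_per_turn)."""
        return 360.0 / self.bp_per_turn

    @classmethod
    def dna(cls) -> "HelixGeometry":
        return cls("DNA", diameter=2.0, rise_per_bp=0.332, bp_per_turn=10.5,
                   groove_offset_deg=120.0)

    @classmethod
    def rna(cls) -> "HelixGeometry":
        return cls("RNA", diameter=2.3, rise_per_bp=0.281, bp_per_turn=11.0,
                   groove_offset_deg=139.0)


@dataclass
class DesignParameters:
    """User-facing design knobs shared across the pipeline.

    ``scale`` is in nm per mesh unit; ``min_overlap`` (nt) bounds the shortest
    binding domain a nick may leave behind.  Linker counts follow
    k = max(0, round(gap / linker_spacing) - 1), capped, unless
    ``linker_fixed`` pins them.
    """

    method: str = "st-dna"
    scale: float = 10.0
    min_overlap: int = 8
    linker_spacing: float = 0.6
    linker_max: int = 5
    linker_fixed: int | None = None
    linker_base: str | None = "T"  # None = free (designable) linker bases
    gc_bounds: tuple[float, float] = (0.0, 1.0)
    forbidden: tuple[str, ...] = ()
    kl_loop_len: int = 7
    seed: int = 0
    relax: bool = False
    relax_iterations: int = 500
    relax_dt: float = 0.01
    relax_stiffness: float = 1.0
    relax_damping: float = 0.5

    def __post_init__(self):
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")
        if self.min_overlap < 1:
            raise ParameterError("min_overlap must be >= 1")
        lo, hi = self.gc_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ParameterError("GC bounds must satisfy 0 <= lo <= hi <= 1")


@dataclass
class Cylinder:
    """One double helix: rigid transform, extent and connection points.

    The transform maps local coordinates (helix along +Y, starting at y=0) to
    world nm coordinates.  ``frm``/``to`` are the wireframe vertices the axis
    runs between; strand 1 runs 5'->3' from the ``frm`` end to the ``to``
    end, strand 2 antiparallel.
    """

    id: int
    edge_id: int
    frm: int
    to: int
    transform: np.ndarray
    nominal_length: float
    length: float
    bp_count: int
    radius: float
    role: str = "duplex"  # duplex | kissing_loop
    tree: bool | None = None
    kind: str = ""

    def conn_local(self, name: str, geom: HelixGeometry) -> np.ndarray:
        """Template-frame position of a connection point."""
        n = self.bp_count
        rb = geom.backbone_radius_factor * self.radius
        twist = math.radians(geom.twist_per_bp)
        groove = math.radians(geom.groove_offset_deg)

        def bb(i: int, second: bool) -> np.ndarray:
            phi = i * twist + (groove if second else 0.0)
            return np.array([rb * math.cos(phi), i * geom.rise_per_bp,
                             rb * math.sin(phi)])

        if name == "first5":
            return bb(0, False)
        if name == "first3":
            return bb(n - 1, False)
        if name == "second5":
            return bb(n - 1, True)
        if name == "second3":
            return bb(0, True)
        raise KeyError(name)

    def conn_world(self, name: str, geom: HelixGeometry) -> np.ndarray:
        p = self.conn_local(name, geom)
        return self.transform[:3, :3] @ p + self.transform[:3, 3]

    def axis_segment(self) -> tuple[np.ndarray, np.ndarray]:
        start = self.transform[:3, 3]
        axis = self.transform[:3, 1]
        return start, start + axis * max(self.length, 1e-9)


@dataclass(frozen=True)
class CylinderLink:
    """Directed 3'->5' connection between two cylinder strand ends."""

    from_cyl: int
    from_point: str
    to_cyl: int
    to_point: str
    junction: tuple[float, float, float]
    kind: str = "route"  # route | staple


@dataclass
class TraversalSlot:
    """Where a route traversal lands in the cylinder model."""

    cyl_id: int
    strand: str  # "first" | "second"
    in_point: str
    out_point: str
    half_side: int | None = None  # vertex for half traversals


@dataclass
class CylinderModel:
    cylinders: list[Cylinder]
    links: list[CylinderLink]
    scale: float
    geom: HelixGeometry
    method: str
    slots: list[list[TraversalSlot]] = field(default_factory=list)

    def cylinder(self, cid: int) -> Cylinder:
        return self.cylinders[cid]

    def neighbor_map(self) -> dict[tuple[int, str], tuple[int, str]]:
        """Symmetric view of the link graph keyed by (cylinder, point)."""
        m: dict[tuple[int, str], tuple[int, str]] = {}
        for ln in self.links:
            m[(ln.from_cyl, ln.from_point)] = (ln.to_cyl, ln.to_point)
            m[(ln.to_cyl, ln.to_point)] = (ln.from_cyl, ln.from_point)
        return m


def round_to_turns(bp_count: int, geom: HelixGeometry) -> int:
    """Round a base-pair count to an integer number of helical turns.

    Round-half-down at both steps; never below one full turn.  Used by the
    ST-DNA method to support its stapling pattern.
    """
    if bp_count < 1:
        raise ParameterError("bp_count must be >= 1")
    turns = max(1, math.ceil(bp_count / geom.bp_per_turn - 0.5))
    target = turns * geom.bp_per_turn
    return max(1, math.ceil(target - 0.5))


def _min_junction_angle(graph: WireframeGraph, v: int, eid: int) -> float:
    e = graph.edge(eid)
    d0 = graph.positions[e.other(v)] - graph.positions[v]
    d0 = d0 / np.linalg.norm(d0)
    best = math.pi
    for other in graph.incident(v):
        if other.id == eid or other.key == e.key:
            # a parallel copy (two-helix bundle / doubled edge) is offset
            # laterally and does not constrain the end along the axis
            continue
        d1 = graph.positions[other.other(v)] - graph.positions[v]
        d1 = d1 / np.linalg.norm(d1)
        ang = math.acos(float(np.clip(np.dot(d0, d1), -1.0, 1.0)))
        best = min(best, ang)
    return best


def _frame(graph: WireframeGraph, frm: int, to: int, eid: int) -> np.ndarray:
    """Right-handed orthonormal frame with Y along the edge.

    The X axis is seeded from the direction to the first *other* rotation
    neighbour at ``frm`` (mesh-intrinsic, so rigid motions of the mesh carry
    the frame along); isolated edges fall back to a global reference.
    """
    y = graph.positions[to] - graph.positions[frm]
    y = y / np.linalg.norm(y)
    ref = None
    for nbr_eid in graph.rotation.get(frm, []):
        if nbr_eid == eid:
            continue
        e = graph.edge(nbr_eid)
        cand = graph.positions[e.other(frm)] - graph.positions[frm]
        cand = cand - np.dot(cand, y) * y
        if np.linalg.norm(cand) > 1e-9:
            ref = cand
            break
    if ref is None:
        ref = np.array([0.0, 0.0, 1.0])
        ref = ref - np.dot(ref, y) * y
        if np.linalg.norm(ref) < 1e-9:
            ref = np.array([1.0, 0.0, 0.0])
            ref = ref - np.dot(ref, y) * y
    x = ref / np.linalg.norm(ref)
    z = np.cross(x, y)
    m = np.eye(4)
    m[:3, 0] = x
    m[:3, 1] = y
    m[:3, 2] = z
    return m


def build_cylinder_model(
    route: Route,
    graph: WireframeGraph,
    params: DesignParameters,
    geom: HelixGeometry,
) -> CylinderModel:
    """Position one cylinder per routed duplex segment.

    Methods that route both strands of each duplex (CC-DNA, ST-RNA, XT-RNA)
    get one cylinder per edge, its two strands taken by the two antiparallel
    traversals (or the two hairpin half-edges of a kissing loop).  Scaffolded
    DNA methods get one cylinder per traversal; edges visited twice carry a
    side-by-side two-helix bundle.
    """
    method = route.method or params.method
    paired = method in PAIRED_METHODS
    pos_nm = {v: graph.positions[v] * params.scale for v in graph.positions}

    cylinders: list[Cylinder] = []
    slots: list[list[TraversalSlot]] = []
    cyl_of_edge: dict[int, int] = {}
    edge_copies: dict[tuple[int, int], int] = {}
    key_counts: dict[tuple[int, int], int] = {}
    for t in route.all_traversals():
        k = graph.edge(t.edge_id).key
        key_counts[k] = key_counts.get(k, 0) + 1
    too_short: list[tuple[int, int]] = []

    def make_cylinder(t: Traversal, lateral: int) -> Cylinder:
        eid = t.edge_id
        frm, to = t.frm, t.to
        nominal = float(np.linalg.norm(pos_nm[to] - pos_nm[frm]))
        r = geom.radius
        d_frm = _clearance(graph, frm, eid, r, params.scale)
        d_to = _clearance(graph, to, eid, r, params.scale)
        usable = nominal - d_frm - d_to
        bp = max(1, math.floor(usable / geom.rise_per_bp))
        if method == "st-dna":
            bp = round_to_turns(bp, geom)
        role = "kissing_loop" if t.kissing_loop else "duplex"
        min_bp = 2 * (params.kl_loop_len + 1) if role == "kissing_loop" else 1
        if bp < min_bp or usable <= 0:
            too_short.append((eid, bp))
        helix_len = (bp - 1) * geom.rise_per_bp
        pad = max(0.0, (usable - helix_len)) / 2.0
        m = _frame(graph, frm, to, eid)
        direction = m[:3, 1]
        start = pos_nm[frm] + direction * (d_frm + pad)
        if lateral:
            offset_dir = m[:3, 0]
            start = start + offset_dir * (r * (1 if lateral == 1 else -1))
        m = m.copy()
        m[:3, 3] = start
        return Cylinder(
            id=len(cylinders),
            edge_id=eid,
            frm=frm,
            to=to,
            transform=m,
            nominal_length=nominal,
            length=helix_len,
            bp_count=bp,
            radius=r,
            role=role,
            tree=(t.kind == "tree") if t.kind in ("tree", "cotree", "crossover") else None,
            kind=t.kind,
        )

    for walk in route.walks:
        walk_slots: list[TraversalSlot] = []
        for t in walk:
            if paired:
                if t.edge_id in cyl_of_edge:
                    cid = cyl_of_edge[t.edge_id]
                    cyl = cylinders[cid]
                    if t.half:
                        side = t.frm
                        if side == cyl.frm:
                            slot = TraversalSlot(cid, "first", "first5", "second3", side)
                        else:
                            slot = TraversalSlot(cid, "second", "second5", "first3", side)
                    elif t.frm == cyl.frm:
                        slot = TraversalSlot(cid, "first", "first5", "first3")
                    else:
                        slot = TraversalSlot(cid, "second", "second5", "second3")
                else:
                    cyl = make_cylinder(t, lateral=0)
                    cylinders.append(cyl)
                    cyl_of_edge[t.edge_id] = cyl.id
                    if t.half:
                        slot = TraversalSlot(cyl.id, "first", "first5", "second3", t.frm)
                    else:
                        slot = TraversalSlot(cyl.id, "first", "first5", "first3")
            else:
                key = graph.edge(t.edge_id).key
                n_prev = edge_copies.get(key, 0)
                edge_copies[key] = n_prev + 1
                # repeat visits of a vertex pair sit beside the first
                # (two-helix bundle / doubled edge)
                lateral = 0 if key_counts[key] == 1 else (1 if n_prev == 0 else 2)
                cyl = make_cylinder(t, lateral=lateral)
                cylinders.append(cyl)
                slot = TraversalSlot(cyl.id, "first", "first5", "first3")
            walk_slots.append(slot)
        slots.append(walk_slots)

    if too_short:
        listing = ", ".join(f"edge {eid} ({bp} bp)" for eid, bp in too_short[:10])
        raise ParameterError(
            f"scale {params.scale} nm leaves segments below the method minimum: {listing}"
        )

    links: list[CylinderLink] = []
    for wi, walk in enumerate(route.walks):
        ws = slots[wi]
        for i, t in enumerate(walk):
            nxt_i = (i + 1) % len(walk)
            junction = tuple(pos_nm[t.end])
            a, b = ws[i], ws[nxt_i]
            links.append(
                CylinderLink(a.cyl_id, a.out_point, b.cyl_id, b.in_point, junction, "route")
            )
            if not paired:
                # complementary (staple) side mirrors the scaffold links
                links.append(
                    CylinderLink(
                        b.cyl_id, "second3", a.cyl_id, "second5", junction, "staple"
                    )
                )
    return CylinderModel(
        cylinders=cylinders,
        links=links,
        scale=params.scale,
        geom=geom,
        method=method,
        slots=slots,
    )


def _clearance(
    graph: WireframeGraph, v: int, eid: int, radius: float, scale: float
) -> float:
    alpha = _min_junction_angle(graph, v, eid)
    if alpha >= math.pi - 1e-9:
        return 0.0
    alpha = max(alpha, 1e-3)
    d = radius / math.tan(alpha / 2.0)
    nominal = graph.length(eid) * scale
    return float(np.clip(d, 0.0, 0.45 * nominal))


# ----------------------------------------------------------------------
# Relaxation
# ----------------------------------------------------------------------


def spring_objective(model: CylinderModel) -> float:
    """Sum of squared distances between linked connection points (nm^2)."""
    total = 0.0
    for ln in model.links:
        pa = model.cylinders[ln.from_cyl].conn_world(ln.from_point, model.geom)
        pb = model.cylinders[ln.to_cyl].conn_world(ln.to_point, model.geom)
        total += float(np.sum((pa - pb) ** 2))
    return total


def _segment_distance(p1, q1, p2, q2) -> float:
    """Closest distance between segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = np.dot(d1, d1), np.dot(d2, d2), np.dot(d2, r)
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = np.dot(d1, r)
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = np.dot(d1, d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm((p1 + d1 * s) - (p2 + d2 * t)))


def _max_penetration(model: CylinderModel, pairs) -> float:
    worst = 0.0
    for i, j in pairs:
        ci, cj = model.cylinders[i], model.cylinders[j]
        a0, a1 = ci.axis_segment()
        b0, b1 = cj.axis_segment()
        dist = _segment_distance(a0, a1, b0, b1)
        worst = max(worst, (ci.radius + cj.radius) - dist)
    return worst


def relax(
    model: CylinderModel,
    iterations: int | None = None,
    seed: int = 0,
    dt: float | None = None,
    stiffness: float = 1.0,
    damping: float = 0.5,
) -> CylinderModel:
    """Damped rigid-body spring relaxation of the cylinder model.

    Springs pull linked connection points together while a sphere-swept
    segment collision term keeps non-linked cylinders from overlapping.  The
    best (lowest spring objective) visited state is returned, so the spring
    objective never increases relative to the input.  Cylinder pairs that
    share a wireframe vertex are exempt from the collision term: their
    spacing is governed by the vertex clearance.
    """
    iterations = 500 if iterations is None else iterations
    dt = 0.01 if dt is None else dt
    geom = model.geom
    cyls = [replace(c, transform=c.transform.copy()) for c in model.cylinders]
    work = CylinderModel(cyls, model.links, model.scale, geom, model.method, model.slots)
    n = len(cyls)
    linked = {(min(l.from_cyl, l.to_cyl), max(l.from_cyl, l.to_cyl)) for l in model.links}
    collision_pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if (i, j) not in linked
        and not ({cyls[i].frm, cyls[i].to} & {cyls[j].frm, cyls[j].to})
    ]
    vel = np.zeros((n, 3))
    ang = np.zeros((n, 3))
    masses = np.array([max(c.length, 0.5) for c in cyls])
    inertia = masses * (np.array([c.length for c in cyls]) ** 2 / 12.0 + 0.25)
    inertia = np.maximum(inertia, 0.1)

    def state_key(obj: float, pen: float) -> tuple[float, float]:
        # feasibility first (penetration beyond the 0.1 nm tolerance),
        # spring objective second
        return (max(pen - 0.1, 0.0), obj)

    init_obj = spring_objective(work)
    init_pen = _max_penetration(work, collision_pairs)
    best_key = state_key(init_obj, init_pen)
    best_tfms = [c.transform.copy() for c in cyls]

    for _ in range(iterations):
        forces = np.zeros((n, 3))
        torques = np.zeros((n, 3))
        centers = np.array([c.transform[:3, 3] + c.transform[:3, 1] * c.length / 2 for c in cyls])
        for ln in work.links:
            pa = cyls[ln.from_cyl].conn_world(ln.from_point, geom)
            pb = cyls[ln.to_cyl].conn_world(ln.to_point, geom)
            f = stiffness * (pb - pa)
            forces[ln.from_cyl] += f
            forces[ln.to_cyl] -= f
            torques[ln.from_cyl] += np.cross(pa - centers[ln.from_cyl], f)
            torques[ln.to_cyl] += np.cross(pb - centers[ln.to_cyl], -f)
        for i, j in collision_pairs:
            ci, cj = cyls[i], cyls[j]
            a0, a1 = ci.axis_segment()
            b0, b1 = cj.axis_segment()
            dist = _segment_distance(a0, a1, b0, b1)
            overlap = (ci.radius + cj.radius) - dist
            if overlap > 0:
                sep = centers[i] - centers[j]
                norm = np.linalg.norm(sep)
                direction = sep / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
                f = 5.0 * stiffness * overlap * direction
                forces[i] += f
                forces[j] -= f
        vel = (vel + dt * forces / masses[:, None]) * max(0.0, 1.0 - damping * dt)
        ang = (ang + dt * torques / inertia[:, None]) * max(0.0, 1.0 - damping * dt)
        if not (np.all(np.isfinite(vel)) and np.all(np.isfinite(ang))):
            raise RelaxationError("relaxation diverged; reduce the time step")
        for i, c in enumerate(cyls):
            center = centers[i] + dt * vel[i]
            rotvec = ang[i] * dt
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            R = rot @ c.transform[:3, :3]
            t = center - R[:, 1] * c.length / 2
            c.transform[:3, :3] = R
            c.transform[:3, 3] = t
        obj = spring_objective(work)
        if not math.isfinite(obj):
            raise RelaxationError("relaxation diverged; reduce the time step")
        pen = _max_penetration(work, collision_pairs)
        key = state_key(obj, pen)
        if key < best_key:
            best_key = key
            best_tfms = [c.transform.copy() for c in cyls]

    for c, tf in zip(cyls, best_tfms):
        c.transform = tf
    return work
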