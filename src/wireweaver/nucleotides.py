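"""Nucleotide-level model: oriented bases, backbone connectivity, pairing.

Each cylinder is expanded into a template double helix along the local Y axis
(two antiparallel strands, one base pair per ``rise_per_bp``), mapped to world
coordinates by the cylinder's 4x4 transform.  Strand ends are then joined by
short unpaired linker segments placed by spherical linear interpolation
around the junction vertex, after which the model consists of long cyclic
strands.  Kissing-loop cylinders are rewired mid-helix into two hairpins
whose terminal bases pair across the gap.  Finally, nicks break the cycles
into staple-length oligos subject to a minimum binding-domain length.

Orientation vectors use the oxDNA convention: ``a1`` points from the backbone
towards the base (the helix axis here), ``a3`` along the helix axis in the
strand's 3'-to-5' direction, so paired bases have anti-aligned ``a3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cylinders import CylinderModel, DesignParameters, HelixGeometry
from .errors import GeometryError, ParameterError

__all__ = [
    "Nucleotide",
    "Strand",
    "NucleotideModel",
    "generate_template_helix",
    "instantiate_nucleotides",
    "add_linkers",
    "reroute_kissing_loops",
    "nick_strands",
]


@dataclass
class Nucleotide:
    id: int
    position: np.ndarray
    a1: np.ndarray
    a3: np.ndarray
    base: str = "N"
    prev: int = -1
    next: int = -1
    pair: int = -1
    cylinder_id: int = -1
    is_linker: bool = False
    is_kl: bool = False
    role: str = "strand"  # scaffold | staple | strand


@dataclass
class Strand:
    """Ordered nucleotide ids, 5' to 3'."""

    ids: list[int]
    circular: bool
    role: str = "strand"

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class TemplateHelix:
    """Two antiparallel strands along local +Y, fully paired."""

    pos1: np.ndarray
    a1_1: np.ndarray
    a3_1: np.ndarray
    pos2: np.ndarray
    a1_2: np.ndarray
    a3_2: np.ndarray

    @property
    def bp_count(self) -> int:
        return len(self.pos1)


def generate_template_helix(bp_count: int, geom: HelixGeometry) -> TemplateHelix:
    """Template double helix with ``bp_count`` base pairs along local +Y.

    Strand 1 runs 5'->3' with increasing Y; strand 2 is returned in its own
    5'->3' order (decreasing Y), so strand-2 index j pairs strand-1 index
    ``bp_count - 1 - j``.
    """
    if bp_count < 1:
        raise ParameterError("bp_count must be >= 1")
    n = bp_count
    rb = geom.backbone_radius_factor * geom.radius
    twist = math.radians(geom.twist_per_bp)
    groove = math.radians(geom.groove_offset_deg)
    i = np.arange(n)
    phi1 = i * twist
    phi2 = phi1 + groove
    y = i * geom.rise_per_bp

    def strand(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos = np.stack([rb * np.cos(phi), y, rb * np.sin(phi)], axis=1)
        a1 = np.stack([-np.cos(phi), np.zeros(n), -np.sin(phi)], axis=1)
        return pos, a1

    pos1, a1_1 = strand(phi1)
    a3_1 = np.tile([0.0, -1.0, 0.0], (n, 1))  # 3'->5' points down for strand 1
    pos2_by_bp, a1_2_by_bp = strand(phi2)
    pos2 = pos2_by_bp[::-1].copy()  # 5'->3' order for strand 2
    a1_2 = a1_2_by_bp[::-1].copy()
    a3_2 = np.tile([0.0, 1.0, 0.0], (n, 1))
    return TemplateHelix(pos1, a1_1, a3_1, pos2, a1_2, a3_2)


@dataclass
class NucleotideModel:
    nucleotides: list[Nucleotide] = field(default_factory=list)
    method: str = ""
    geom: HelixGeometry | None = None
    fragments: dict[int, tuple[list[int], list[int]]] = field(default_factory=dict)
    cyl_roles: dict[int, str] = field(default_factory=dict)
    cyl_edges: dict[int, int] = field(default_factory=dict)
    nick_edge: int | None = None
    nicks: list[tuple[int, int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    kl_groups: list[list[tuple[int, int]]] = field(default_factory=list)

    def nuc(self, nid: int) -> Nucleotide:
        return self.nucleotides[nid]

    @property
    def n_nucleotides(self) -> int:
        return len(self.nucleotides)

    def strands(self) -> list[Strand]:
        """Strands rebuilt from backbone pointers (cycles and linear runs)."""
        seen: set[int] = set()
        strands: list[Strand] = []
        # linear strands start at a 5' end (no prev)
        for nt in self.nucleotides:
            if nt.prev == -1 and nt.id not in seen:
                ids = []
                cur = nt.id
                while cur != -1 and cur not in seen:
                    seen.add(cur)
                    ids.append(cur)
                    cur = self.nucleotides[cur].next
                strands.append(Strand(ids, circular=False, role=self._role(ids)))
        for nt in self.nucleotides:
            if nt.id in seen:
                continue
            ids = []
            cur = nt.id
            while cur not in seen:
                seen.add(cur)
                ids.append(cur)
                cur = self.nucleotides[cur].next
            strands.append(Strand(ids, circular=True, role=self._role(ids)))
        return strands

    def _role(self, ids: list[int]) -> str:
        roles = {self.nucleotides[i].role for i in ids}
        if "scaffold" in roles:
            return "scaffold"
        if "staple" in roles:
            return "staple"
        return "strand"

    def check_pairing(self) -> None:
        for nt in self.nucleotides:
            if nt.pair != -1:
                other = self.nucleotides[nt.pair]
                if other.pair != nt.id:
                    raise GeometryError(
                        f"pairing not an involution at {nt.id}/{other.id}"
                    )


def instantiate_nucleotides(cyl_model: CylinderModel) -> NucleotideModel:
    """Expand every cylinder into two world-space antiparallel strands.

    No pairing or connectivity crosses cylinders yet; linkers come next.
    """
    geom = cyl_model.geom
    paired_methods = {"cc-dna", "st-rna", "xt-rna"}
    model = NucleotideModel(method=cyl_model.method, geom=geom)
    for cyl in cyl_model.cylinders:
        R = cyl.transform[:3, :3]
        t = cyl.transform[:3, 3]
        if abs(np.linalg.det(R)) < 1e-9:
            raise GeometryError(f"cylinder {cyl.id}: singular transform")
        tmpl = generate_template_helix(cyl.bp_count, geom)
        n = tmpl.bp_count
        role1 = "strand" if cyl_model.method in paired_methods else "scaffold"
        role2 = "strand" if cyl_model.method in paired_methods else "staple"
        ids1, ids2 = [], []
        for k in range(n):
            nid = len(model.nucleotides)
            model.nucleotides.append(
                Nucleotide(
                    id=nid,
                    position=R @ tmpl.pos1[k] + t,
                    a1=R @ tmpl.a1_1[k],
                    a3=R @ tmpl.a3_1[k],
                    cylinder_id=cyl.id,
                    role=role1,
                )
            )
            ids1.append(nid)
        for k in range(n):
            nid = len(model.nucleotides)
            model.nucleotides.append(
                Nucleotide(
                    id=nid,
                    position=R @ tmpl.pos2[k] + t,
                    a1=R @ tmpl.a1_2[k],
                    a3=R @ tmpl.a3_2[k],
                    cylinder_id=cyl.id,
                    role=role2,
                )
            )
            ids2.append(nid)
        for k in range(n):  # backbone within each fragment
            if k + 1 < n:
                model.nucleotides[ids1[k]].next = ids1[k + 1]
                model.nucleotides[ids1[k + 1]].prev = ids1[k]
                model.nucleotides[ids2[k]].next = ids2[k + 1]
                model.nucleotides[ids2[k + 1]].prev = ids2[k]
            # strand-2 index j pairs strand-1 index n-1-j
            model.nucleotides[ids1[k]].pair = ids2[n - 1 - k]
            model.nucleotides[ids2[n - 1 - k]].pair = ids1[k]
        model.fragments[cyl.id] = (ids1, ids2)
        model.cyl_roles[cyl.id] = cyl.role
        model.cyl_edges[cyl.id] = cyl.edge_id
    return model


def reroute_kissing_loops(
    model: NucleotideModel, cyl_model: CylinderModel, kl_loop_len: int = 7
) -> NucleotideModel:
    """Rewire kissing-loop cylinders into two hairpins that pair terminally.

    The duplex is split at mid-helix; each half keeps its own stem pairing
    and becomes a hairpin anchored at one wireframe vertex.  The ``kl_loop_len``
    bases adjacent to the split on each hairpin are re-paired *across* the two
    hairpins (the 180-degree kissing interaction); their former partners
    become unpaired flanking bases.
    """
    for cyl in cyl_model.cylinders:
        if cyl.role != "kissing_loop":
            continue
        s1, s2 = model.fragments[cyl.id]
        n = len(s1)
        if n < 2 * (kl_loop_len + 1):
            raise ParameterError(
                f"kissing-loop cylinder {cyl.id} has {n} bp; needs at least "
                f"{2 * (kl_loop_len + 1)}"
            )
        m = n // 2
        # split both strands at the midpoint ...
        model.nucleotides[s1[m - 1]].next = -1
        model.nucleotides[s1[m]].prev = -1
        model.nucleotides[s2[n - m - 1]].next = -1
        model.nucleotides[s2[n - m]].prev = -1
        # ... and close each hairpin with a cross-strand bond at the split
        model.nucleotides[s1[m - 1]].next = s2[n - m]
        model.nucleotides[s2[n - m]].prev = s1[m - 1]
        model.nucleotides[s2[n - m - 1]].next = s1[m]
        model.nucleotides[s1[m]].prev = s2[n - m - 1]
        group: list[tuple[int, int]] = []
        for j in range(kl_loop_len):
            a = s1[m - 1 - j]       # hairpin at the frm vertex
            b = s2[n - m - 1 - j]   # hairpin at the to vertex
            for x in (a, b):
                old = model.nucleotides[x].pair
                if old != -1:
                    model.nucleotides[old].pair = -1
                model.nucleotides[x].pair = -1
            na, nb = model.nucleotides[a], model.nucleotides[b]
            na.pair, nb.pair = b, a
            na.is_kl = nb.is_kl = True
            group.append((a, b))
        model.kl_groups.append(group)
    return model


def _slerp_points(
    pa: np.ndarray, pb: np.ndarray, center: np.ndarray, k: int
) -> list[np.ndarray]:
    u = pa - center
    v = pb - center
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        return [pa + (pb - pa) * (j / (k + 1)) for j in range(1, k + 1)]
    cosang = float(np.clip(np.dot(u / nu, v / nv), -1.0, 1.0))
    ang = math.acos(cosang)
    if ang < 1e-6 or ang > math.pi - 1e-3:  # collinear or antipodal: fall back
        return [pa + (pb - pa) * (j / (k + 1)) for j in range(1, k + 1)]
    out = []
    for j in range(1, k + 1):
        t = j / (k + 1)
        w1 = math.sin((1 - t) * ang) / math.sin(ang)
        w2 = math.sin(t * ang) / math.sin(ang)
        direction = w1 * (u / nu) + w2 * (v / nv)
        direction /= np.linalg.norm(direction)
        mag = (1 - t) * nu + t * nv
        out.append(center + direction * mag)
    return out


def _slerp_vec(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    na = a / max(np.linalg.norm(a), 1e-12)
    nb = b / max(np.linalg.norm(b), 1e-12)
    cosang = float(np.clip(np.dot(na, nb), -1.0, 1.0))
    ang = math.acos(cosang)
    if ang < 1e-6 or ang > math.pi - 1e-3:
        v = (1 - t) * na + t * nb
        n = np.linalg.norm(v)
        return v / n if n > 1e-9 else na
    w1 = math.sin((1 - t) * ang) / math.sin(ang)
    w2 = math.sin(t * ang) / math.sin(ang)
    v = w1 * na + w2 * nb
    return v / np.linalg.norm(v)


def _conn_nucleotide(model: NucleotideModel, cyl_id: int, point: str) -> int:
    s1, s2 = model.fragments[cyl_id]
    return {"first5": s1[0], "first3": s1[-1], "second5": s2[0], "second3": s2[-1]}[point]


def add_linkers(
    model: NucleotideModel,
    cyl_model: CylinderModel,
    params: DesignParameters,
) -> NucleotideModel:
    """Join linked 3'->5' strand ends with unpaired slerp-placed linkers.

    The linker count defaults to ``max(0, round(gap / spacing) - 1)`` capped
    at ``linker_max``; positions interpolate direction (about the junction
    vertex) and radius; orientation vectors are slerped between the end
    nucleotides.  Antipodal geometry falls back to linear interpolation.
    """
    for ln in cyl_model.links:
        a_id = _conn_nucleotide(model, ln.from_cyl, ln.from_point)
        b_id = _conn_nucleotide(model, ln.to_cyl, ln.to_point)
        na, nb = model.nucleotides[a_id], model.nucleotides[b_id]
        if na.next != -1 or nb.prev != -1:
            raise GeometryError(
                f"connection {ln.from_cyl}.{ln.from_point} -> "
                f"{ln.to_cyl}.{ln.to_point}: strand end already connected"
            )
        gap = float(np.linalg.norm(na.position - nb.position))
        if params.linker_fixed is not None:
            k = params.linker_fixed
        else:
            k = max(0, round(gap / params.linker_spacing) - 1)
            k = min(k, params.linker_max)
        center = np.asarray(ln.junction, dtype=float)
        pts = _slerp_points(na.position, nb.position, center, k)
        role = "staple" if ln.kind == "staple" else na.role
        prev = a_id
        for j, p in enumerate(pts, start=1):
            t = j / (k + 1)
            nid = len(model.nucleotides)
            model.nucleotides.append(
                Nucleotide(
                    id=nid,
                    position=p,
                    a1=_slerp_vec(na.a1, nb.a1, t),
                    a3=_slerp_vec(na.a3, nb.a3, t),
                    is_linker=True,
                    role=role,
                )
            )
            model.nucleotides[prev].next = nid
            model.nucleotides[nid].prev = prev
            prev = nid
        model.nucleotides[prev].next = b_id
        nb.prev = prev
    return model


# ----------------------------------------------------------------------
# Nicking
# ----------------------------------------------------------------------


def _cut(model: NucleotideModel, x: int) -> tuple[int, int] | None:
    y = model.nucleotides[x].next
    if y == -1:
        return None
    model.nucleotides[x].next = -1
    model.nucleotides[y].prev = -1
    model.nicks.append((x, y))
    return (x, y)


def _heal(model: NucleotideModel, nick: tuple[int, int]) -> None:
    x, y = nick
    model.nucleotides[x].next = y
    model.nucleotides[y].prev = x
    model.nicks.remove((x, y))


def _domains(model: NucleotideModel, strands: list[Strand]):
    """Contiguous binding domains: maximal runs of a strand paired to
    consecutive (antiparallel) bases of one partner strand."""
    strand_of = {}
    index_of = {}
    for si, s in enumerate(strands):
        for pos, nid in enumerate(s.ids):
            strand_of[nid] = si
            index_of[nid] = pos
    doms = []
    for si, s in enumerate(strands):
        run_start = None
        prev_partner = None
        for pos, nid in enumerate(s.ids):
            p = model.nucleotides[nid].pair
            ok = p != -1
            if ok and run_start is not None and prev_partner is not None:
                same = strand_of[p] == strand_of[prev_partner]
                consecutive = index_of[p] == index_of[prev_partner] - 1
                if not (same and consecutive):
                    doms.append((si, run_start, pos - 1))
                    run_start = pos
            elif ok and run_start is None:
                run_start = pos
            elif not ok and run_start is not None:
                doms.append((si, run_start, pos - 1))
                run_start = None
            prev_partner = p if ok else None
        if run_start is not None:
            doms.append((si, run_start, len(s.ids) - 1))
    return doms


def _auto_candidates(model: NucleotideModel, min_overlap: int) -> list[int]:
    """Nick candidates (cut-after nucleotide ids) per design method."""
    out: list[int] = []
    if model.method in ("at-dna", "st-dna"):
        # staple-side helix ends
        for cid, (_, s2) in sorted(model.fragments.items()):
            out.append(s2[-1])
    elif model.method == "cc-dna":
        # staggered nicking: one mid-edge cut per duplex, never both strands,
        # choosing per duplex the covering cycle with fewer nicks so far so
        # that every cycle gets opened
        strand_of: dict[int, int] = {}
        for si, s in enumerate(model.strands()):
            for nid in s.ids:
                strand_of[nid] = si
        nicks_per_strand: dict[int, int] = {}
        for cid, (s1, s2) in sorted(model.fragments.items()):
            n = len(s1)
            m = n // 2
            if n < 2:
                continue
            cand1, cand2 = s1[m - 1], s2[n - m - 1]
            k1 = nicks_per_strand.get(strand_of[cand1], 0)
            k2 = nicks_per_strand.get(strand_of[cand2], 0)
            pick = cand1 if k1 <= k2 else cand2
            nicks_per_strand[strand_of[pick]] = nicks_per_strand.get(strand_of[pick], 0) + 1
            out.append(pick)
    return out


def nick_strands(
    model: NucleotideModel,
    min_overlap: int,
    candidates: list[int] | None = None,
) -> NucleotideModel:
    """Break cyclic strands into oligos without compromising binding stability.

    As many candidate nicks as possible are inserted (helix ends for
    scaffolded methods, staggered mid-edge cuts for the cycle cover), then
    repaired greedily: while some resulting binding domain is shorter than
    ``min_overlap``, the nick bounding the shortest illegal domain is removed.
    Scaffold strands are never nicked.  RNA methods instead receive the single
    prescribed nick at the longest wireframe edge via
    :func:`apply_single_nick`.
    """
    if min_overlap < 1:
        raise ParameterError("min_overlap must be >= 1")
    if model.method in ("st-rna", "xt-rna"):
        return apply_single_nick(model)
    if candidates is None:
        candidates = _auto_candidates(model, min_overlap)
    applied: list[tuple[int, int]] = []
    for x in candidates:
        nick = _cut(model, x)
        if nick:
            applied.append(nick)
    unfixable_marks: set[tuple[int, int, int]] = set()
    while True:
        strands = model.strands()
        doms = _domains(model, strands)
        violations = sorted(
            (
                (j - i + 1, si, i, j)
                for (si, i, j) in doms
                if j - i + 1 < min_overlap
                and (si, i, j) not in unfixable_marks
                # circular strands are unaffected by nicking and their domain
                # list is split at an arbitrary wrap point; only the nicked
                # (linear) strands are constrained
                and not strands[si].circular
            )
        )
        if not violations:
            break
        length, si, i, j = violations[0]
        bounding = _bounding_nicks(model, strands, si, i, j)
        bounding = [nk for nk in bounding if nk in applied]
        if not bounding:
            unfixable_marks.add((si, i, j))
            model.warnings.append(
                f"domain of {length} nt < min_overlap {min_overlap} cannot be "
                "repaired by removing nicks"
            )
            continue
        nick = min(bounding)
        _heal(model, nick)
        applied.remove(nick)
        unfixable_marks.clear()
    for s in model.strands():
        if s.circular and s.role == "staple":
            if len(s.ids) < 2 * min_overlap:
                model.warnings.append(
                    f"cycle of {len(s.ids)} nt left circular (< 2 x min_overlap)"
                )
    return model


def _bounding_nicks(model, strands, si, i, j) -> list[tuple[int, int]]:
    s = strands[si]
    out = []
    first, last = s.ids[i], s.ids[j]
    p_first = model.nucleotides[first].pair
    p_last = model.nucleotides[last].pair
    for x, y in model.nicks:
        if y == first or x == last:
            out.append((x, y))
        if p_first != -1 and x == p_first:
            out.append((x, y)) if (x, y) not in out else None
        if p_last != -1 and y == p_last:
            out.append((x, y)) if (x, y) not in out else None
    return out


def apply_single_nick(model: NucleotideModel) -> NucleotideModel:
    """Open 3'-to-5' nick mid-helix on the longest ordinary edge (RNA)."""
    if model.nick_edge is None:
        model.warnings.append("no nick edge annotated; model left circular")
        return model
    target = None
    for cid, eid in model.cyl_edges.items():
        if eid == model.nick_edge and model.cyl_roles.get(cid) != "kissing_loop":
            target = cid
            break
    if target is None:
        model.warnings.append("nick edge has no ordinary duplex; left circular")
        return model
    s1, _ = model.fragments[target]
    _cut(model, s1[len(s1) // 2 - 1])
    return model
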