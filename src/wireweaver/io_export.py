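"""Exports: oxDNA topology/configuration pair, UNF JSON, strand CSV.

The oxDNA writer targets the legacy two-file format (.top + .dat) for widest
tool compatibility.  Conventions, documented here because the classic format
is underspecified:

* nucleotides are indexed in strand order and 5'->3' within each strand
  (classic oxDNA lists 3'->5'; readers that follow neighbour indices are
  unaffected, and :func:`read_oxdna` reads this writer's files back exactly);
* each topology row is ``strand_id base three_prime_neighbor
  five_prime_neighbor`` with -1 for open ends; circular strands wrap;
* coordinates are written in oxDNA simulation length units
  (1 unit = 0.8518 nm); the model's nm coordinates are converted on write
  and restored on read;
* ``a1`` points backbone->base, ``a3`` along the strand's 3'->5' axis;
  velocities and angular velocities are written as zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import BoxError, FormatError, SequenceError
from .nucleotides import Nucleotide, NucleotideModel

__all__ = ["OxDnaPair", "write_oxdna", "read_oxdna", "write_unf", "write_csv"]

NM_PER_OXDNA = 0.8518


@dataclass
class OxDnaPair:
    topology: str
    configuration: str


def _bbox_diag(model: NucleotideModel) -> float:
    pos = np.array([nt.position for nt in model.nucleotides])
    return float(np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)))


def write_oxdna(model: NucleotideModel, box_size: float | None = None) -> OxDnaPair:
    """Serialize to the legacy oxDNA topology + configuration pair.

    ``box_size`` is the cubic box edge in nm; the default is 1.5x the
    bounding-box diagonal.  A nucleotide outside the box (centred on the
    model centroid) raises :class:`BoxError` with a suggested size.
    """
    if not model.nucleotides:
        raise SequenceError("empty model")
    pos = np.array([nt.position for nt in model.nucleotides])
    centroid = pos.mean(axis=0)
    needed = 2.0 * float(np.abs(pos - centroid).max()) + 1.0
    if box_size is None:
        box_size = max(1.5 * _bbox_diag(model), needed)
    if needed > box_size:
        raise BoxError(
            f"nucleotides outside the {box_size:.1f} nm box; use >= {needed:.1f} nm"
        )
    strands = model.strands()
    order: list[int] = [nid for s in strands for nid in s.ids]
    index = {nid: i for i, nid in enumerate(order)}
    top_lines = [f"{len(order)} {len(strands)}"]
    for si, s in enumerate(strands, start=1):
        n = len(s.ids)
        for k, nid in enumerate(s.ids):
            nt = model.nuc(nid)
            if s.circular:
                n3 = index[s.ids[(k + 1) % n]]
                n5 = index[s.ids[(k - 1) % n]]
            else:
                n3 = index[s.ids[k + 1]] if k + 1 < n else -1
                n5 = index[s.ids[k - 1]] if k > 0 else -1
            top_lines.append(f"{si} {nt.base} {n3} {n5}")
    box_ox = box_size / NM_PER_OXDNA
    conf_lines = [
        "t = 0",
        f"b = {box_ox:.8f} {box_ox:.8f} {box_ox:.8f}",
        "E = 0 0 0",
    ]
    for nid in order:
        nt = model.nuc(nid)
        p = nt.position / NM_PER_OXDNA
        row = list(p) + list(nt.a1) + list(nt.a3) + [0.0] * 6
        conf_lines.append(" ".join(f"{x:.8f}" for x in row))
    return OxDnaPair("\n".join(top_lines) + "\n", "\n".join(conf_lines) + "\n")


def read_oxdna(pair: OxDnaPair) -> NucleotideModel:
    """Parse an oxDNA pair written by :func:`write_oxdna` back into a model.

    Restores bases, backbone connectivity (including circular closure) and
    nm coordinates/orientations; pairing information is not part of the
    format and is left empty.
    """
    top = [l for l in pair.topology.splitlines() if l.strip()]
    if not top:
        raise FormatError("empty topology")
    try:
        n, n_strands = (int(x) for x in top[0].split())
    except ValueError as exc:
        raise FormatError("bad topology header") from exc
    rows = top[1:]
    if len(rows) != n:
        raise FormatError(f"topology header says {n} records, found {len(rows)}")
    conf = [l for l in pair.configuration.splitlines() if l.strip()]
    if len(conf) < 3 + n:
        raise FormatError("configuration too short")
    model = NucleotideModel()
    strand_ids = []
    for i, row in enumerate(rows):
        parts = row.split()
        if len(parts) != 4:
            raise FormatError(f"bad topology row {row!r}")
        sid, base, n3, n5 = int(parts[0]), parts[1], int(parts[2]), int(parts[3])
        strand_ids.append(sid)
        vals = [float(x) for x in conf[3 + i].split()]
        if len(vals) < 9:
            raise FormatError(f"bad configuration row {i}")
        model.nucleotides.append(
            Nucleotide(
                id=i,
                position=np.array(vals[0:3]) * NM_PER_OXDNA,
                a1=np.array(vals[3:6]),
                a3=np.array(vals[6:9]),
                base=base,
                next=n3,
                prev=n5,
            )
        )
    if len(set(strand_ids)) != n_strands:
        raise FormatError(
            f"header says {n_strands} strands, rows reference {len(set(strand_ids))}"
        )
    for nt in model.nucleotides:
        for nbr, back in ((nt.next, "prev"), (nt.prev, "next")):
            if nbr != -1:
                if not (0 <= nbr < n):
                    raise FormatError(f"neighbor index {nbr} out of range")
                if getattr(model.nucleotides[nbr], back) != nt.id:
                    raise FormatError(
                        f"non-reciprocal neighbor link {nt.id} <-> {nbr}"
                    )
    return model


def write_unf(model: NucleotideModel, meta: dict | None = None) -> dict:
    """UNF JSON document (documented subset of the schema, version pinned).

    The subset covers format/version identification, the nucleic-acid type,
    and per-strand nucleotide records with geometry and connectivity --
    enough for structural round-trips and downstream conversion.
    """
    meta = meta or {}
    strands = model.strands()
    na_type = model.geom.nucleic_acid if model.geom else meta.get("naType", "DNA")
    strands_json = []
    for si, s in enumerate(strands):
        nucleotides = []
        for nid in s.ids:
            nt = model.nuc(nid)
            nucleotides.append(
                {
                    "id": nt.id,
                    "nbAbbrev": nt.base,
                    "pair": nt.pair,
                    "prev": nt.prev,
                    "next": nt.next,
                    "position": [float(x) for x in nt.position],
                    "a1": [float(x) for x in nt.a1],
                    "a3": [float(x) for x in nt.a3],
                }
            )
        strands_json.append(
            {
                "id": si,
                "naType": na_type,
                "role": s.role,
                "isCyclic": s.circular,
                "fivePrimeId": s.ids[0],
                "threePrimeId": s.ids[-1],
                "nucleotides": nucleotides,
            }
        )
    return {
        "format": "unf",
        "version": "1.0.0",
        "name": meta.get("name", "wireweaver design"),
        "author": meta.get("author", ""),
        "idCounter": model.n_nucleotides,
        "lengthUnits": "nm",
        "structures": (
            [{"id": 0, "naType": na_type, "strands": strands_json}]
            if strands_json
            else []
        ),
    }


def write_csv(model: NucleotideModel, allow_n: bool = False) -> str:
    """Strand table (RFC-4180): name, length, 5'->3' sequence, role.

    Circular strands are marked in the role column.  Unassigned (N) bases are
    an error unless ``allow_n`` is set.
    """
    import csv
    import io as _io

    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["name", "length", "sequence", "role"])
    for si, s in enumerate(model.strands()):
        seq = "".join(model.nuc(nid).base for nid in s.ids)
        if "N" in seq and not allow_n:
            raise SequenceError(
                f"strand {si} has unassigned bases; assign sequences first "
                "or pass allow_n=True"
            )
        role = s.role + (";circular" if s.circular else "")
        writer.writerow([f"strand_{si:03d}", len(s.ids), seq, role])
    return buf.getvalue()


def unf_to_json(doc: dict) -> str:
    return json.dumps(doc, indent=1)
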