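"""Primary-structure design.

Scaffolded DNA methods copy a scaffold sequence (user-supplied FASTA or a
seeded random scaffold) along the scaffold route and set every staple base to
the Watson-Crick complement of its partner.  The scaffold-free cycle-cover
method designs all strands with a Focused Metropolis Search that minimises
the length of the longest repeated substring -- fully complementary
non-specific pairings require a repeated substring, so shrinking the longest
repeat suppresses off-target binding -- under hard constraints on GC content
and forbidden subsequences.  RNA methods draw kissing-loop sequences from a
pre-generated pair table and can round-trip a NUPACK-style design file.
"""

from __future__ import annotations

import io
import math
import random
from dataclasses import dataclass, field
from importlib import resources

from .errors import (
    CapacityError,
    ConstraintError,
    FormatError,
    SequenceError,
)
from .nucleotides import NucleotideModel, Strand

__all__ = [
    "SequenceConstraints",
    "KissingLoopTable",
    "wc_complement",
    "random_sequence",
    "read_fasta",
    "assign_scaffold",
    "assign_random",
    "longest_repeated_substring",
    "fms_optimize",
    "FmsReport",
    "load_kissing_loop_table",
    "assign_kissing_loops",
    "export_nupack",
    "import_nupack",
]

_DNA = {"A": "T", "T": "A", "C": "G", "G": "C"}
_RNA = {"A": "U", "U": "A", "C": "G", "G": "C"}


def wc_complement(base: str, alphabet: str = "DNA") -> str:
    table = _DNA if alphabet.upper() == "DNA" else _RNA
    try:
        return table[base.upper()]
    except KeyError as exc:
        raise SequenceError(f"base {base!r} not in the {alphabet} alphabet") from exc


def random_sequence(n: int, seed: int = 0, alphabet: str = "DNA") -> str:
    rng = random.Random(seed)
    letters = "ACGT" if alphabet.upper() == "DNA" else "ACGU"
    return "".join(rng.choice(letters) for _ in range(n))


def read_fasta(text_or_path: str) -> str:
    """First record of a FASTA document (raw single-sequence text accepted)."""
    from Bio import SeqIO

    text = text_or_path
    if "\n" not in text_or_path and not text_or_path.startswith(">"):
        try:
            with open(text_or_path) as fh:
                text = fh.read()
        except OSError:
            pass
    if text.lstrip().startswith(">"):
        record = next(SeqIO.parse(io.StringIO(text), "fasta"), None)
        if record is None:
            raise FormatError("no FASTA record found")
        return str(record.seq).upper()
    seq = "".join(text.split()).upper()
    if not seq:
        raise FormatError("empty sequence")
    return seq


@dataclass
class SequenceConstraints:
    """Hard constraints for sequence design.

    ``gc_bounds`` bound the G+C fraction of every designed strand (linker
    positions excluded when ``linker_base`` pins them); ``forbidden`` lists
    subsequences that must not occur in any strand.
    """

    gc_bounds: tuple[float, float] = (0.0, 1.0)
    forbidden: tuple[str, ...] = ()
    linker_base: str | None = "T"
    alphabet: str = "DNA"

    def __post_init__(self):
        lo, hi = self.gc_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConstraintError("GC bounds must satisfy 0 <= lo <= hi <= 1")
        if any(not f for f in self.forbidden):
            raise ConstraintError("forbidden subsequences must be non-empty")
        self.forbidden = tuple(f.upper() for f in self.forbidden)

    @property
    def letters(self) -> str:
        return "ACGT" if self.alphabet.upper() == "DNA" else "ACGU"


# ----------------------------------------------------------------------
# Scaffold / random assignment
# ----------------------------------------------------------------------


def _scaffold_strand(model: NucleotideModel) -> Strand:
    scaffolds = [s for s in model.strands() if s.role == "scaffold"]
    if len(scaffolds) != 1:
        raise SequenceError(
            f"expected exactly one scaffold strand, found {len(scaffolds)}"
        )
    return scaffolds[0]


def assign_scaffold(
    model: NucleotideModel, scaffold: str, linker_base: str | None = "T"
) -> NucleotideModel:
    """Write the scaffold sequence 5'->3' and complement the staples.

    The scaffold must be at least as long as the scaffold route; unpaired
    staple linker bases are set per ``linker_base`` (None leaves them N).
    """
    alphabet = model.geom.nucleic_acid if model.geom else "DNA"
    letters = set("ACGT" if alphabet == "DNA" else "ACGU")
    scaffold = scaffold.upper()
    bad = set(scaffold) - letters
    if bad:
        raise SequenceError(
            f"scaffold contains {sorted(bad)} not in the {alphabet} alphabet"
        )
    strand = _scaffold_strand(model)
    if len(scaffold) < len(strand.ids):
        raise SequenceError(
            f"scaffold too short: {len(scaffold)} nt < required {len(strand.ids)} nt"
        )
    for base, nid in zip(scaffold, strand.ids):
        nt = model.nuc(nid)
        nt.base = base
        if nt.pair != -1:
            model.nuc(nt.pair).base = wc_complement(base, alphabet)
    if linker_base is not None:
        for nt in model.nucleotides:
            if nt.is_linker and nt.role == "staple":
                nt.base = linker_base
    return model


def assign_random(
    model: NucleotideModel, seed: int = 0, linker_base: str | None = "T"
) -> NucleotideModel:
    """Random Watson-Crick-consistent assignment of every position."""
    alphabet = model.geom.nucleic_acid if model.geom else "DNA"
    letters = "ACGT" if alphabet == "DNA" else "ACGU"
    rng = random.Random(seed)
    for nt in model.nucleotides:
        if nt.base != "N":
            continue
        if nt.is_linker and linker_base is not None:
            nt.base = linker_base if alphabet == "DNA" or linker_base != "T" else "U"
            continue
        nt.base = rng.choice(letters)
        if nt.pair != -1:
            model.nuc(nt.pair).base = wc_complement(nt.base, alphabet)
    return model


# ----------------------------------------------------------------------
# Longest repeated substring + Focused Metropolis Search
# ----------------------------------------------------------------------


def longest_repeated_substring(strands) -> int:
    """Length of the longest string occurring at least twice within strands.

    Occurrences must lie entirely inside single strands (either two positions
    of one strand or positions in two strands); they may overlap.  Computed
    by binary search over the answer with a per-length substring set.
    """
    strands = [s for s in strands if s]
    if not strands:
        return 0

    def has_repeat(L: int) -> bool:
        seen: set[str] = set()
        for s in strands:
            for i in range(len(s) - L + 1):
                w = s[i : i + L]
                if w in seen:
                    return True
                seen.add(w)
        return False

    lo, hi = 0, max(len(s) for s in strands)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if has_repeat(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _find_repeat_occurrence(strands: list[str], L: int) -> tuple[int, int] | None:
    """(strand index, start) of the *second* occurrence of some length-L repeat."""
    if L < 1:
        return None
    seen: dict[str, tuple[int, int]] = {}
    for si, s in enumerate(strands):
        for i in range(len(s) - L + 1):
            w = s[i : i + L]
            if w in seen:
                return (si, i)
            seen[w] = (si, i)
    return None


@dataclass
class FmsReport:
    """Focused Metropolis Search trace: best objective per iteration."""

    history: list[int] = field(default_factory=list)
    final_objective: int = 0
    iterations: int = 0
    accepted: int = 0


def _gc_ok(s: str, fixed_mask: list[bool], lo: float, hi: float) -> bool:
    free = [c for c, fixed in zip(s, fixed_mask) if not fixed]
    if not free:
        return True
    gc = sum(1 for c in free if c in "GC") / len(free)
    return lo - 1e-9 <= gc <= hi + 1e-9


def fms_optimize(
    model: NucleotideModel,
    constraints: SequenceConstraints,
    seed: int = 0,
    max_iters: int = 2000,
) -> FmsReport:
    """Focused Metropolis Search over the free sequence positions.

    A uniformly random free position is mutated -- but with probability 0.9
    the position is drawn from inside a current occurrence of a longest
    repeated substring ("focused") -- the Watson-Crick complement is
    propagated, hard constraints (GC bounds per strand, forbidden
    subsequences) reject the move outright, and the repeat-length objective
    is accepted if it does not increase, otherwise with probability
    exp(-delta / T), T = 0.5.  The best assignment seen is written back to
    the model; the best-so-far objective is monotone non-increasing.
    """
    alphabet = constraints.alphabet
    letters = constraints.letters
    rng = random.Random(seed)
    strands = model.strands()
    loc: dict[int, tuple[int, int]] = {}
    for si, s in enumerate(strands):
        for pos, nid in enumerate(s.ids):
            loc[nid] = (si, pos)
    # fixed (non-designable) positions: pinned linkers
    fixed: set[int] = set()
    for nt in model.nucleotides:
        if nt.is_linker and constraints.linker_base is not None:
            base = constraints.linker_base
            if alphabet == "RNA" and base == "T":
                base = "U"
            nt.base = base
            fixed.add(nt.id)
    free_reps = [
        nt.id
        for nt in model.nucleotides
        if nt.id not in fixed and (nt.pair == -1 or nt.id < nt.pair)
    ]
    if not free_reps:
        raise ConstraintError("no designable positions")

    seqs = [[model.nuc(nid).base for nid in s.ids] for s in strands]
    fixed_masks = [[nid in fixed for nid in s.ids] for s in strands]

    def set_base(nid: int, base: str) -> None:
        si, pos = loc[nid]
        seqs[si][pos] = base
        p = model.nuc(nid).pair
        if p != -1:
            sj, pj = loc[p]
            seqs[sj][pj] = wc_complement(base, alphabet)

    # initial assignment: randomize unset positions, then repair constraints
    for nid in free_reps:
        if seqs[loc[nid][0]][loc[nid][1]] == "N":
            set_base(nid, rng.choice(letters))
    for nt in model.nucleotides:  # any leftover N (unpaired, non-rep) positions
        si, pos = loc[nt.id]
        if seqs[si][pos] == "N":
            set_base(nt.id, rng.choice(letters))
    if not _repair(seqs, fixed_masks, loc, model, constraints, rng, set_base, free_reps):
        raise ConstraintError(
            "could not find an initial assignment satisfying the constraints"
        )

    def strings() -> list[str]:
        return ["".join(s) for s in seqs]

    def violates(ss: list[str]) -> bool:
        lo_gc, hi_gc = constraints.gc_bounds
        for s, mask in zip(ss, fixed_masks):
            if not _gc_ok(s, mask, lo_gc, hi_gc):
                return True
            for f in constraints.forbidden:
                if f in s:
                    return True
        return False

    cur = strings()
    cur_obj = longest_repeated_substring(cur)
    best_obj = cur_obj
    best = list(cur)
    report = FmsReport(history=[best_obj])
    T = 0.5
    for _ in range(max_iters):
        report.iterations += 1
        nid = None
        if cur_obj >= 1 and rng.random() < 0.9:
            occ = _find_repeat_occurrence(cur, cur_obj)
            if occ is not None:
                si, start = occ
                pos = start + rng.randrange(cur_obj)
                cand = strands[si].ids[pos]
                rep = cand if (model.nuc(cand).pair == -1 or cand < model.nuc(cand).pair) else model.nuc(cand).pair
                if rep not in fixed:
                    nid = rep
        if nid is None:
            nid = free_reps[rng.randrange(len(free_reps))]
        si, pos = loc[nid]
        old = seqs[si][pos]
        new = rng.choice([c for c in letters if c != old])
        set_base(nid, new)
        cand_strings = strings()
        if violates(cand_strings):
            set_base(nid, old)
            report.history.append(best_obj)
            continue
        new_obj = longest_repeated_substring(cand_strings)
        delta = new_obj - cur_obj
        if delta <= 0 or rng.random() < math.exp(-delta / T):
            cur, cur_obj = cand_strings, new_obj
            report.accepted += 1
            if cur_obj < best_obj:
                best_obj, best = cur_obj, list(cur)
        else:
            set_base(nid, old)
        report.history.append(best_obj)

    for s, seq in zip(strands, best):
        for nid, base in zip(s.ids, seq):
            model.nuc(nid).base = base
    report.final_objective = best_obj
    return report


def _repair(seqs, fixed_masks, loc, model, constraints, rng, set_base, free_reps,
            max_rounds: int = 2000) -> bool:
    lo_gc, hi_gc = constraints.gc_bounds
    letters = constraints.letters
    for _ in range(max_rounds):
        ss = ["".join(s) for s in seqs]
        bad = False
        for si, (s, mask) in enumerate(zip(ss, fixed_masks)):
            if not _gc_ok(s, mask, lo_gc, hi_gc):
                bad = True
                free_pos = [i for i, f in enumerate(mask) if not f]
                gc = sum(1 for i in free_pos if s[i] in "GC") / max(len(free_pos), 1)
                want_gc = gc < lo_gc
                pool = [i for i in free_pos if (s[i] in "AT" + "AU") == want_gc]
                if not pool:
                    return False
                i = rng.choice(pool)
                nid = _strand_nid(model, loc, si, i)
                rep = nid if (model.nuc(nid).pair == -1 or nid < model.nuc(nid).pair) else model.nuc(nid).pair
                target = rng.choice("GC") if want_gc else rng.choice(
                    "AT" if constraints.alphabet == "DNA" else "AU"
                )
                # mutating via the representative may flip the partner instead
                set_base(rep, target if rep == nid else wc_complement(target, constraints.alphabet))
                break
            for f in constraints.forbidden:
                j = s.find(f)
                if j >= 0:
                    bad = True
                    i = j + rng.randrange(len(f))
                    if fixed_masks[si][i]:
                        candidates = [x for x in range(j, j + len(f)) if not fixed_masks[si][x]]
                        if not candidates:
                            return False
                        i = rng.choice(candidates)
                    nid = _strand_nid(model, loc, si, i)
                    rep = nid if (model.nuc(nid).pair == -1 or nid < model.nuc(nid).pair) else model.nuc(nid).pair
                    old = seqs[si][i]
                    set_base(rep, rng.choice([c for c in letters if c != old]))
                    break
            if bad:
                break
        if not bad:
            return True
    return False


def _strand_nid(model, loc, si, pos) -> int:
    for nid, (s, p) in loc.items():
        if s == si and p == pos:
            return nid
    raise KeyError((si, pos))


# ----------------------------------------------------------------------
# Kissing-loop table
# ----------------------------------------------------------------------


@dataclass
class KissingLoopTable:
    """Pre-generated kissing-loop sequence pairs (id, loop, partner loop)."""

    entries: list[tuple[str, str, str]]

    def __len__(self) -> int:
        return len(self.entries)


def load_kissing_loop_table(path: str | None = None) -> KissingLoopTable:
    """Load a kissing-loop pair table (TSV: id, seq_a, seq_b).

    The packaged default is a synthetic fixture of 180-degree kissing-loop
    pairs (mutually reverse-complementary 7-mers, all entries distinct); it
    is user-replaceable by passing a path to a table in the same format.
    """
    if path is None:
        text = (
            resources.files("wireweaver").joinpath("data/kissing_loops.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    entries = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise FormatError(f"bad kissing-loop table line {raw!r}")
        entries.append((parts[0], parts[1].upper(), parts[2].upper()))
    if not entries:
        raise FormatError("kissing-loop table is empty")
    return KissingLoopTable(entries)


def assign_kissing_loops(
    model: NucleotideModel, table: KissingLoopTable
) -> NucleotideModel:
    """Give each kissing-loop pair a distinct table entry.

    The loop bases of the first hairpin take ``seq_a`` 5'->3'; partners are
    set to the Watson-Crick complement, which reproduces the table's
    ``seq_b`` read along the opposite hairpin.
    """
    groups = model.kl_groups
    if len(groups) > len(table):
        raise CapacityError(
            f"{len(groups)} kissing loops but only {len(table)} table entries"
        )
    alphabet = model.geom.nucleic_acid if model.geom else "RNA"
    for gi, group in enumerate(groups):
        _, seq_a, _ = table.entries[gi]
        if len(seq_a) < len(group):
            raise CapacityError(
                f"table entry {gi} is shorter than the loop ({len(group)} nt)"
            )
        for j, (a, b) in enumerate(group):
            model.nuc(a).base = seq_a[j]
            model.nuc(b).base = wc_complement(seq_a[j], alphabet)
    return model


# ----------------------------------------------------------------------
# NUPACK-style design file exchange
# ----------------------------------------------------------------------


def export_nupack(model: NucleotideModel) -> str:
    """Design-file text: dot-paren secondary structure + base constraints.

    Kissing-loop interactions are pseudoknots and therefore expressed as
    fixed-sequence positions rather than brackets; all other positions are
    ``N`` unless pinned.  Pairings that cross (true pseudoknots beyond the
    kissing loops) cannot be expressed and raise an error listing the pairs.
    """
    if model.geom is None or model.geom.nucleic_acid != "RNA":
        raise SequenceError("NUPACK export is defined for RNA models")
    lines = [
        "# wireweaver design export (minimal NUPACK-style dialect)",
        "material = rna",
    ]
    for si, s in enumerate(strands := model.strands()):
        index = {nid: i for i, nid in enumerate(s.ids)}
        structure = ["."] * len(s.ids)
        stack: list[int] = []
        offending: list[tuple[int, int]] = []
        for i, nid in enumerate(s.ids):
            nt = model.nuc(nid)
            if nt.pair == -1 or nt.is_kl or nt.pair not in index:
                continue
            j = index[nt.pair]
            if j > i:
                structure[i] = "("
                stack.append(j)
            else:
                structure[i] = ")"
                if not stack or stack[-1] != i:
                    offending.append((j, i))
                else:
                    stack.pop()
        if offending or stack:
            raise SequenceError(
                f"strand {si}: pseudoknotted pairings not expressible: "
                f"{offending or stack}"
            )
        seq = [
            model.nuc(nid).base if model.nuc(nid).is_kl and model.nuc(nid).base != "N"
            else "N"
            for nid in s.ids
        ]
        lines.append(f"structure s{si} = {''.join(structure)}")
        lines.append(f"sequence s{si} = {''.join(seq)}")
    return "\n".join(lines) + "\n"


def import_nupack(model: NucleotideModel, text: str) -> NucleotideModel:
    """Read sequences from a design file back onto the model's strands."""
    seqs: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line or "=" not in line:
            continue
        head, value = (x.strip() for x in line.split("=", 1))
        if head.startswith("sequence "):
            seqs[head.split()[1]] = value.upper()
    strands = model.strands()
    for si, s in enumerate(strands):
        name = f"s{si}"
        if name not in seqs:
            raise FormatError(f"design file lacks a sequence for strand {name}")
        seq = seqs[name]
        if len(seq) != len(s.ids):
            raise SequenceError(
                f"strand {name}: sequence length {len(seq)} != strand length {len(s.ids)}"
            )
        for nid, base in zip(s.ids, seq):
            model.nuc(nid).base = base
    return model
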