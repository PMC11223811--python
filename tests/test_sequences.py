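"""Sequence design: complements, repeats, FMS, kissing loops, NUPACK files."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wireweaver import (
    DesignParameters,
    HelixGeometry,
    SequenceConstraints,
    add_linkers,
    assign_kissing_loops,
    assign_random,
    assign_scaffold,
    build_cylinder_model,
    export_nupack,
    fms_optimize,
    import_nupack,
    instantiate_nucleotides,
    load_kissing_loop_table,
    longest_repeated_substring,
    make_mesh,
    nick_strands,
    reroute_kissing_loops,
)
from wireweaver.cylinders import Cylinder, CylinderModel
from wireweaver.errors import CapacityError, SequenceError
from wireweaver.pipeline import _complementarity_ok, route_mesh
from wireweaver.sequences import KissingLoopTable, random_sequence, read_fasta, wc_complement

from .conftest import lrs_bruteforce


def dna_pipeline(method="st-dna", shape="tetrahedron"):
    mesh = make_mesh(shape)
    graph, route = route_mesh(mesh, method)
    geom = HelixGeometry.rna() if method.endswith("rna") else HelixGeometry.dna()
    params = DesignParameters(method=method, scale=10.0)
    cyl = build_cylinder_model(route, graph, params, geom)
    model = instantiate_nucleotides(cyl)
    if method.endswith("rna"):
        reroute_kissing_loops(model, cyl)
    add_linkers(model, cyl, params)
    model.nick_edge = route.annotations.get("nick_edge")
    nick_strands(model, params.min_overlap)
    return model


def duplex_model(bp=4):
    geom = HelixGeometry.dna()
    cyl = Cylinder(0, 0, 0, 1, np.eye(4), 1.0, (bp - 1) * geom.rise_per_bp,
                   bp, geom.radius)
    return instantiate_nucleotides(CylinderModel([cyl], [], 10.0, geom, "cc-dna"))


class TestScaffoldAssignment:
    def test_tetra_scaffold_complementarity(self):
        model = dna_pipeline()
        need = sum(1 for nt in model.nucleotides if nt.role == "scaffold")
        assign_scaffold(model, random_sequence(need + 500, seed=3))
        assert _complementarity_ok(model)
        assert all(nt.base != "N" for nt in model.nucleotides)

    def test_short_scaffold_reports_required_length(self):
        model = dna_pipeline()
        with pytest.raises(SequenceError, match="required"):
            assign_scaffold(model, "ACGT" * 10)

    def test_rna_letter_rejected_in_dna_mode(self):
        model = dna_pipeline()
        with pytest.raises(SequenceError):
            assign_scaffold(model, "ACGU" * 2000)

    def test_reverse_complement_on_tiny_duplex(self):
        model = duplex_model(bp=4)
        # make strand 1 a standalone scaffold against a staple partner
        for nt in model.nucleotides:
            nt.role = "scaffold" if nt.cylinder_id == 0 and nt.id < 4 else "staple"
        assign_scaffold(model, "ACGT")
        s1, s2 = model.fragments[0]
        seq2 = "".join(model.nuc(n).base for n in s2)
        assert seq2 == "ACGT"  # reverse complement of ACGT is ACGT read 5'->3'


class TestWcComplement:
    def test_tables(self):
        assert wc_complement("A", "DNA") == "T"
        assert wc_complement("A", "RNA") == "U"
        assert wc_complement("G") == "C"

    def test_bad_letter(self):
        with pytest.raises(SequenceError):
            wc_complement("X")


class TestLongestRepeatedSubstring:
    @pytest.mark.parametrize(
        "strands,expected",
        [
            (["ACGTACGT"], 4),
            (["ACGT"], 0),
            (["ACGTT", "ACGAA"], 3),
            (["AAAA"], 3),          # overlapping occurrences count
            (["ACG", "ACG"], 3),    # across strands
            ([], 0),
        ],
    )
    def test_examples(self, strands, expected):
        assert longest_repeated_substring(strands) == expected
        assert lrs_bruteforce(strands) == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.text(alphabet="ACGT", min_size=0, max_size=40), min_size=1, max_size=4)
    )
    def test_agrees_with_bruteforce(self, strands):
        assert longest_repeated_substring(strands) == lrs_bruteforce(strands)


class TestFms:
    def test_reaches_bruteforce_optimum_on_tiny_duplex(self):
        # oracle: exhaust all 4^4 assignments of a 4-bp duplex
        best = min(
            lrs_bruteforce(
                ["".join(x), "".join(wc_complement(c) for c in reversed(x))]
            )
            for x in itertools.product("ACGT", repeat=4)
        )
        model = duplex_model(bp=4)
        report = fms_optimize(model, SequenceConstraints(linker_base=None),
                              seed=5, max_iters=400)
        assert report.final_objective == best

    def test_forbidden_subsequence_absent(self):
        model = dna_pipeline("cc-dna")
        constraints = SequenceConstraints(forbidden=("GGGG",))
        fms_optimize(model, constraints, seed=2, max_iters=150)
        for s in model.strands():
            seq = "".join(model.nuc(n).base for n in s.ids)
            assert "GGGG" not in seq

    def test_gc_bounds_respected(self):
        model = dna_pipeline("cc-dna")
        constraints = SequenceConstraints(gc_bounds=(0.35, 0.65))
        fms_optimize(model, constraints, seed=2, max_iters=150)
        for s in model.strands():
            free = [model.nuc(n).base for n in s.ids if not model.nuc(n).is_linker]
            gc = sum(b in "GC" for b in free) / len(free)
            assert 0.35 - 1e-9 <= gc <= 0.65 + 1e-9

    def test_seeded_runs_reproducible(self):
        outs = []
        for _ in range(2):
            model = dna_pipeline("cc-dna")
            fms_optimize(model, SequenceConstraints(), seed=9, max_iters=120)
            outs.append([nt.base for nt in model.nucleotides])
        assert outs[0] == outs[1]

    def test_best_objective_monotone_and_complementary(self):
        model = dna_pipeline("cc-dna")
        report = fms_optimize(model, SequenceConstraints(), seed=4, max_iters=200)
        assert all(a >= b for a, b in zip(report.history, report.history[1:]))
        assert _complementarity_ok(model)


class TestKissingLoops:
    def test_table_loads_and_is_consistent(self):
        table = load_kissing_loop_table()
        assert len(table) >= 20
        seqs = [a for _, a, _ in table.entries]
        assert len(set(seqs)) == len(seqs)
        for _, a, b in table.entries:
            rc = "".join(wc_complement(c, "RNA") for c in reversed(a))
            assert b == rc

    def test_assignment_uses_distinct_entries(self):
        model = dna_pipeline("st-rna")
        table = load_kissing_loop_table()
        assign_kissing_loops(model, table)
        loops = []
        for group in model.kl_groups:
            loops.append("".join(model.nuc(a).base for a, _ in group))
        assert len(set(loops)) == len(loops) == 3
        assert loops[0] == table.entries[0][1][: len(loops[0])]

    def test_zero_loops_noop(self):
        model = dna_pipeline("st-dna")
        before = [nt.base for nt in model.nucleotides]
        assign_kissing_loops(model, load_kissing_loop_table())
        assert [nt.base for nt in model.nucleotides] == before

    def test_capacity_error(self):
        model = dna_pipeline("st-rna")
        small = KissingLoopTable(entries=[("KL01", "GGAUCCG", "CGGAUCC")])
        with pytest.raises(CapacityError):
            assign_kissing_loops(model, small)


class TestNupack:
    def test_structure_matches_length_and_balance(self):
        model = dna_pipeline("st-rna")
        assign_kissing_loops(model, load_kissing_loop_table())
        text = export_nupack(model)
        lines = {l.split("=")[0].strip(): l.split("=", 1)[1].strip()
                 for l in text.splitlines() if "=" in l}
        strand = model.strands()[0]
        assert len(lines["structure s0"]) == len(strand.ids)
        assert lines["structure s0"].count("(") == lines["structure s0"].count(")")

    def test_kissing_loop_letters_at_right_offsets(self):
        model = dna_pipeline("st-rna")
        assign_kissing_loops(model, load_kissing_loop_table())
        text = export_nupack(model)
        seq_line = next(
            l.split("=", 1)[1].strip() for l in text.splitlines()
            if l.startswith("sequence s0")
        )
        strand = model.strands()[0]
        for i, nid in enumerate(strand.ids):
            nt = model.nuc(nid)
            if nt.is_kl:
                assert seq_line[i] == nt.base
            else:
                assert seq_line[i] == "N"

    def test_import_wrong_length_rejected(self):
        model = dna_pipeline("st-rna")
        text = export_nupack(model)
        short = text.replace("sequence s0 = N", "sequence s0 = ")
        with pytest.raises(SequenceError):
            import_nupack(model, short)

    def test_round_trip_assigns_bases(self):
        model = dna_pipeline("st-rna")
        assign_random(model, seed=1, linker_base=None)
        text = export_nupack(model)
        filled = text.replace("N", "A")
        import_nupack(model, filled)
        assert all(nt.base != "N" for nt in model.nucleotides)

    def test_dna_model_rejected(self):
        model = dna_pipeline("st-dna")
        with pytest.raises(SequenceError):
            export_nupack(model)


def test_read_fasta_and_random_sequence():
    assert read_fasta(">s1 desc\nACGT\nTTAA\n") == "ACGTTTAA"
    assert read_fasta("acg t\n") == "ACGT"
    seq = random_sequence(100, seed=1)
    assert len(seq) == 100 and set(seq) <= set("ACGT")
    assert random_sequence(100, seed=1) == seq
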