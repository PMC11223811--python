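"""Nucleotide model: template helices, linkers, kissing loops, nicking."""

import numpy as np
import pytest

from wireweaver import (
    DesignParameters,
    HelixGeometry,
    add_linkers,
    build_cylinder_model,
    generate_template_helix,
    instantiate_nucleotides,
    make_mesh,
    nick_strands,
    reroute_kissing_loops,
)
from wireweaver.cylinders import Cylinder, CylinderLink, CylinderModel
from wireweaver.errors import ParameterError
from wireweaver.pipeline import route_mesh
from scipy.spatial.transform import Rotation


def build_nuc_model(method="st-dna", shape="tetrahedron", scale=10.0):
    mesh = make_mesh(shape)
    graph, route = route_mesh(mesh, method)
    geom = HelixGeometry.rna() if method.endswith("rna") else HelixGeometry.dna()
    params = DesignParameters(method=method, scale=scale)
    cyl = build_cylinder_model(route, graph, params, geom)
    model = instantiate_nucleotides(cyl)
    if method.endswith("rna"):
        reroute_kissing_loops(model, cyl, kl_loop_len=params.kl_loop_len)
    add_linkers(model, cyl, params)
    model.nick_edge = route.annotations.get("nick_edge")
    return model, cyl, route


class TestTemplateHelix:
    def test_single_base_pair(self):
        geom = HelixGeometry.dna()
        tmpl = generate_template_helix(1, geom)
        assert tmpl.bp_count == 1
        dist = np.linalg.norm(tmpl.pos1[0] - tmpl.pos2[0])
        assert 0 < dist < geom.diameter

    def test_full_turn_returns_to_azimuth(self):
        geom = HelixGeometry.rna()  # integer 11 bp/turn
        tmpl = generate_template_helix(12, geom)
        # base 0 and base 11 are one full turn apart: same x/z azimuth
        assert np.allclose(tmpl.pos1[0][[0, 2]], tmpl.pos1[11][[0, 2]], atol=1e-9)

    def test_axial_extent(self):
        tmpl = generate_template_helix(10, HelixGeometry.dna())
        extent = tmpl.pos1[:, 1].max() - tmpl.pos1[:, 1].min()
        assert extent == pytest.approx(9 * 0.332)

    def test_antiparallel_orientation(self):
        tmpl = generate_template_helix(5, HelixGeometry.dna())
        assert np.dot(tmpl.a3_1[0], tmpl.a3_2[0]) == pytest.approx(-1.0)


class TestInstantiate:
    def _single(self, transform, bp=6):
        geom = HelixGeometry.dna()
        cyl = Cylinder(0, 0, 0, 1, transform, 1.0, (bp - 1) * geom.rise_per_bp,
                       bp, geom.radius)
        return CylinderModel([cyl], [], 10.0, geom, "st-dna")

    def test_identity_transform_equals_template(self):
        model = instantiate_nucleotides(self._single(np.eye(4)))
        tmpl = generate_template_helix(6, HelixGeometry.dna())
        s1, _ = model.fragments[0]
        for k, nid in enumerate(s1):
            assert np.allclose(model.nuc(nid).position, tmpl.pos1[k])

    def test_translation_shifts_everything(self):
        t = np.eye(4)
        t[:3, 3] = [5.0, -1.0, 2.0]
        shifted = instantiate_nucleotides(self._single(t))
        base = instantiate_nucleotides(self._single(np.eye(4)))
        for a, b in zip(base.nucleotides, shifted.nucleotides):
            assert np.allclose(b.position - a.position, [5.0, -1.0, 2.0])

    def test_counts_two_cylinders(self):
        geom = HelixGeometry.dna()
        cyls = [
            Cylinder(0, 0, 0, 1, np.eye(4), 1.0, 9 * 0.332, 10, 1.0),
            Cylinder(1, 1, 1, 2, np.eye(4), 1.0, 6 * 0.332, 7, 1.0),
        ]
        model = instantiate_nucleotides(CylinderModel(cyls, [], 10.0, geom, "st-dna"))
        assert model.n_nucleotides == 2 * (10 + 7)

    def test_pairing_involution_and_antiparallelism(self):
        model, _, _ = build_nuc_model("st-dna")
        model.check_pairing()
        for nt in model.nucleotides:
            if nt.pair != -1 and not nt.is_kl:
                other = model.nuc(nt.pair)
                assert float(np.dot(nt.a3, other.a3)) < 0


class TestLinkers:
    def _linked_pair(self, gap, k_fixed=None):
        geom = HelixGeometry.dna()
        length = 9 * geom.rise_per_bp
        t1, t2 = np.eye(4), np.eye(4)
        t2[:3, 3] = [0.0, length + gap, 0.0]
        cyls = [
            Cylinder(0, 0, 0, 1, t1, 1.0, length, 10, 1.0),
            Cylinder(1, 1, 1, 2, t2, 1.0, length, 10, 1.0),
        ]
        junction = (0.0, length + gap / 2, 0.3)
        links = [CylinderLink(0, "first3", 1, "first5", junction, "route")]
        cm = CylinderModel(cyls, links, 10.0, geom, "st-dna")
        model = instantiate_nucleotides(cm)
        params = DesignParameters(method="st-dna", linker_fixed=k_fixed)
        return add_linkers(model, cm, params), cm

    def test_fixed_zero_linkers_direct_bond(self):
        model, _ = self._linked_pair(gap=1.0, k_fixed=0)
        assert model.n_nucleotides == 40
        s1a, _ = model.fragments[0]
        s1b, _ = model.fragments[1]
        assert model.nuc(s1a[-1]).next == s1b[0]

    def test_two_linkers_monotone_along_gap(self):
        model, _ = self._linked_pair(gap=2.0, k_fixed=2)
        linkers = [nt for nt in model.nucleotides if nt.is_linker]
        assert len(linkers) == 2
        ys = [nt.position[1] for nt in linkers]
        assert ys == sorted(ys)
        assert all(np.isfinite(nt.position).all() for nt in linkers)

    def test_auto_count_follows_gap(self):
        model, _ = self._linked_pair(gap=2.4)  # round(2.4/0.6)-1 = 3
        n_linkers = sum(nt.is_linker for nt in model.nucleotides)
        assert 1 <= n_linkers <= 5

    def test_antipodal_fallback_no_nans(self):
        # junction exactly between the two end points: slerp degenerates
        geom = HelixGeometry.dna()
        length = 9 * geom.rise_per_bp
        t1, t2 = np.eye(4), np.eye(4)
        t2[:3, 3] = [0.0, length + 2.0, 0.0]
        cyls = [
            Cylinder(0, 0, 0, 1, t1, 1.0, length, 10, 1.0),
            Cylinder(1, 1, 1, 2, t2, 1.0, length, 10, 1.0),
        ]
        cm = CylinderModel(
            cyls,
            [CylinderLink(0, "first3", 1, "first5", (0.8, length + 1.0, 0.45), "route")],
            10.0, geom, "st-dna",
        )
        model = instantiate_nucleotides(cm)
        add_linkers(model, cm, DesignParameters(method="st-dna", linker_fixed=3))
        assert all(np.isfinite(nt.position).all() for nt in model.nucleotides)


class TestKissingLoops:
    def test_st_rna_k4_three_pairs(self):
        model, _, _ = build_nuc_model("st-rna")
        assert len(model.kl_groups) == 3

    def test_xt_rna_k4_one_pair(self):
        model, _, _ = build_nuc_model("xt-rna")
        assert len(model.kl_groups) == 1

    def test_no_flags_model_unchanged(self):
        mesh = make_mesh("tetrahedron")
        graph, route = route_mesh(mesh, "st-dna")
        params = DesignParameters(method="st-dna", scale=10.0)
        cyl = build_cylinder_model(route, graph, params, HelixGeometry.dna())
        model = instantiate_nucleotides(cyl)
        before = [(nt.prev, nt.next, nt.pair) for nt in model.nucleotides]
        reroute_kissing_loops(model, cyl)
        assert [(nt.prev, nt.next, nt.pair) for nt in model.nucleotides] == before

    def test_kissing_pairs_cross_hairpins_and_involution(self):
        model, _, _ = build_nuc_model("st-rna")
        model.check_pairing()
        for group in model.kl_groups:
            for a, b in group:
                assert model.nuc(a).pair == b and model.nuc(b).pair == a
                assert model.nuc(a).is_kl and model.nuc(b).is_kl

    def test_too_short_cylinder_rejected(self):
        with pytest.raises(ParameterError):
            build_nuc_model("st-rna", scale=3.0)

    def test_strand_count_preserved(self):
        model, _, _ = build_nuc_model("st-rna")
        strands = model.strands()
        assert len(strands) == 1 and strands[0].circular


def synthetic_staple_cycle(bp=20, n_cyl=3):
    """Three duplexes whose staple sides chain into one 60-nt cycle while the
    scaffold sides stay as three separate linear partners."""
    geom = HelixGeometry.dna()
    length = (bp - 1) * geom.rise_per_bp
    cyls = []
    links = []
    for i in range(n_cyl):
        t = np.eye(4)
        t[:3, 3] = [4.0 * i, 0.0, 0.0]
        cyls.append(Cylinder(i, i, i, i + 1, t, 1.0, length, bp, 1.0))
    for i in range(n_cyl):
        j = (i + 1) % n_cyl
        links.append(
            CylinderLink(i, "second3", j, "second5", (4.0 * i + 2.0, 0.0, 0.0), "staple")
        )
    cm = CylinderModel(cyls, links, 10.0, geom, "at-dna")
    model = instantiate_nucleotides(cm)
    add_linkers(model, cm, DesignParameters(method="at-dna", linker_fixed=0))
    return model


class TestNicking:
    def test_sixty_nt_cycle_three_domains_gives_three_staples(self):
        model = synthetic_staple_cycle(bp=20)
        before = model.n_nucleotides
        nick_strands(model, min_overlap=8)
        staples = [s for s in model.strands() if s.role == "staple"]
        assert len(staples) == 3
        assert all(len(s.ids) == 20 for s in staples)
        assert model.n_nucleotides == before  # conservation
        assert len(model.nicks) == 3

    def test_min_overlap_too_large_leaves_cycle_circular_with_warning(self):
        model = synthetic_staple_cycle(bp=20)
        nick_strands(model, min_overlap=100)
        staples = [s for s in model.strands() if s.role == "staple"]
        assert len(staples) == 1 and staples[0].circular
        assert model.warnings

    def test_scaffold_never_nicked(self):
        model, _, _ = build_nuc_model("st-dna")
        nick_strands(model, min_overlap=8)
        scaffold = [s for s in model.strands() if s.role == "scaffold"]
        assert len(scaffold) == 1 and scaffold[0].circular

    def test_staples_meet_min_overlap(self):
        model, _, _ = build_nuc_model("st-dna", shape="octahedron")
        nick_strands(model, min_overlap=8)
        from wireweaver.nucleotides import _domains

        strands = model.strands()
        for si, i, j in _domains(model, strands):
            if not strands[si].circular:
                assert j - i + 1 >= 8

    def test_strand_count_equals_nick_count_plus_open_cycles(self):
        model, _, _ = build_nuc_model("cc-dna")
        n_cycles = len(model.strands())
        nick_strands(model, min_overlap=8)
        strands = model.strands()
        circular = sum(1 for s in strands if s.circular)
        assert len(strands) == len(model.nicks) + circular

    def test_rna_single_nick_on_longest_edge(self):
        mesh = make_mesh("tetrahedron")
        mesh.vertices[0] *= 1.6
        graph, route = route_mesh(mesh, "st-rna")
        params = DesignParameters(method="st-rna", scale=10.0)
        cyl = build_cylinder_model(route, graph, params, HelixGeometry.rna())
        model = instantiate_nucleotides(cyl)
        reroute_kissing_loops(model, cyl)
        add_linkers(model, cyl, params)
        model.nick_edge = route.annotations["nick_edge"]
        nick_strands(model, params.min_overlap)
        strands = model.strands()
        assert len(strands) == 1 and not strands[0].circular
        assert len(model.nicks) == 1
        x, _ = model.nicks[0]
        assert model.cyl_edges[model.nuc(x).cylinder_id] == route.annotations["nick_edge"]


class TestEquivariance:
    def test_end_to_end_rigid_motion(self):
        R = Rotation.from_euler("zyx", [1.0, 0.3, -0.7]).as_matrix()
        shift = np.array([1.0, 2.0, 3.0])
        mesh1 = make_mesh("tetrahedron")
        mesh2 = make_mesh("tetrahedron")
        mesh2.vertices = mesh2.vertices @ R.T + shift
        models = []
        for mesh in (mesh1, mesh2):
            model, _, _ = (lambda m: build_nuc_model_from(m))(mesh)
            models.append(model)
        p1 = np.array([nt.position for nt in models[0].nucleotides])
        p2 = np.array([nt.position for nt in models[1].nucleotides])
        assert np.allclose(p1 @ R.T + shift * 10.0, p2, atol=1e-6)


def build_nuc_model_from(mesh, method="st-dna", scale=10.0):
    graph, route = route_mesh(mesh, method)
    params = DesignParameters(method=method, scale=scale)
    cyl = build_cylinder_model(route, graph, params, HelixGeometry.dna())
    model = instantiate_nucleotides(cyl)
    add_linkers(model, cyl, params)
    return model, cyl, route
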