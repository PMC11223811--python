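"""Cylinder model: geometry constants, scale law, transforms, relaxation."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wireweaver import (
    DesignParameters,
    HelixGeometry,
    WireframeGraph,
    build_cylinder_model,
    cycle_cover,
    make_mesh,
    relax,
    round_to_turns,
    spring_objective,
)
from wireweaver.cylinders import Cylinder, CylinderLink, CylinderModel
from wireweaver.errors import ParameterError
from wireweaver.pipeline import route_mesh


def tetra_model(method="st-dna", scale=10.0):
    mesh = make_mesh("tetrahedron")
    graph, route = route_mesh(mesh, method)
    geom = HelixGeometry.rna() if method.endswith("rna") else HelixGeometry.dna()
    params = DesignParameters(method=method, scale=scale)
    return build_cylinder_model(route, graph, params, geom), graph, route


class TestHelixGeometry:
    def test_dna_diameter_two_nm(self):
        geom = HelixGeometry.dna()
        assert geom.diameter == 2.0 and geom.radius == 1.0

    def test_rna_diameter(self):
        assert HelixGeometry.rna().diameter == 2.3

    def test_twist_consistent_with_bp_per_turn(self):
        for geom in (HelixGeometry.dna(), HelixGeometry.rna()):
            assert geom.twist_per_bp == pytest.approx(360.0 / geom.bp_per_turn)


class TestScaleLaw:
    def test_unit_edge_at_scale_one_gives_one_nm_cylinder(self):
        # isolated unit edge: no junction clearance applies
        pos = {0: np.zeros(3), 1: np.array([1.0, 0, 0])}
        g = WireframeGraph.from_edges(pos, [(0, 1)])
        route = cycle_cover(g)
        model = build_cylinder_model(
            route, g, DesignParameters(method="cc-dna", scale=1.0), HelixGeometry.dna()
        )
        assert len(model.cylinders) == 1
        assert model.cylinders[0].nominal_length == pytest.approx(1.0)

    def test_scale_proportionality(self):
        pos = {0: np.zeros(3), 1: np.array([1.0, 0, 0])}
        g = WireframeGraph.from_edges(pos, [(0, 1)])
        route = cycle_cover(g)
        for scale in (5.0, 20.0):
            model = build_cylinder_model(
                route, g,
                DesignParameters(method="cc-dna", scale=scale), HelixGeometry.dna(),
            )
            assert model.cylinders[0].nominal_length == pytest.approx(scale)

    def test_model_radii(self):
        model, _, _ = tetra_model("st-dna")
        assert all(c.radius == 1.0 for c in model.cylinders)
        model, _, _ = tetra_model("st-rna")
        assert all(c.radius == pytest.approx(1.15) for c in model.cylinders)

    def test_tiny_scale_rejected_listing_edges(self):
        with pytest.raises(ParameterError, match="edge"):
            tetra_model("st-rna", scale=1.0)  # too short for kissing loops


class TestRoundToTurns:
    @pytest.mark.parametrize("bp,expected", [(21, 21), (25, 21), (27, 31), (1, 10)])
    def test_examples(self, bp, expected):
        assert round_to_turns(bp, HelixGeometry.dna()) == expected

    def test_never_below_one_turn(self):
        geom = HelixGeometry.dna()
        for bp in range(1, 40):
            assert round_to_turns(bp, geom) >= 10  # one 10.5-turn, rounded down


class TestTransforms:
    def test_world_connection_points_from_matrix(self):
        model, _, _ = tetra_model("st-dna")
        for c in model.cylinders:
            for name in ("first5", "first3", "second5", "second3"):
                local = c.conn_local(name, model.geom)
                world = c.transform[:3, :3] @ local + c.transform[:3, 3]
                assert np.allclose(world, c.conn_world(name, model.geom), atol=1e-6)

    def test_connection_points_on_surface_at_ends(self):
        model, _, _ = tetra_model("st-dna")
        geom = model.geom
        rb = geom.backbone_radius_factor * geom.radius
        for c in model.cylinders:
            for name in ("first5", "second3"):  # y = 0 end
                p = c.conn_local(name, geom)
                assert p[1] == pytest.approx(0.0)
                assert math.hypot(p[0], p[2]) == pytest.approx(rb)

    def test_link_symmetry(self):
        model, _, _ = tetra_model("st-dna")
        m = model.neighbor_map()
        for key, val in m.items():
            assert m[val] == key

    def test_rigid_motion_equivariance(self):
        mesh1 = make_mesh("tetrahedron")
        mesh2 = make_mesh("tetrahedron")
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        shift = np.array([3.0, -2.0, 5.0])
        mesh2.vertices = mesh2.vertices @ R.T + shift
        out = []
        for mesh in (mesh1, mesh2):
            graph, route = route_mesh(mesh, "st-dna")
            out.append(
                build_cylinder_model(
                    route, graph, DesignParameters(method="st-dna", scale=10.0),
                    HelixGeometry.dna(),
                )
            )
        m1, m2 = out
        assert [c.bp_count for c in m1.cylinders] == [c.bp_count for c in m2.cylinders]
        for c1, c2 in zip(m1.cylinders, m2.cylinders):
            p1 = c1.conn_world("first5", m1.geom)
            p2 = c2.conn_world("first5", m2.geom)
            assert np.allclose(R @ p1 + shift * 10.0, p2, atol=1e-6)


def _toy_pair(gap: float, linked: bool, along=np.array([0.0, 1.0, 0.0])):
    """Two 10-bp DNA cylinders along +Y, separated end-to-start by ``gap``."""
    geom = HelixGeometry.dna()
    length = 9 * geom.rise_per_bp
    t1 = np.eye(4)
    t2 = np.eye(4)
    t2[:3, 3] = along * (length + gap)
    cyls = [
        Cylinder(0, 0, 0, 1, t1, length, length, 10, geom.radius),
        Cylinder(1, 1, 1, 2, t2, length, length, 10, geom.radius),
    ]
    links = []
    if linked:
        junction = tuple(along * (length + gap / 2))
        links = [CylinderLink(0, "first3", 1, "first5", junction, "route")]
    return CylinderModel(cyls, links, 10.0, geom, "st-dna")


class TestRelax:
    def test_zero_gap_is_a_fixed_point(self):
        model = _toy_pair(gap=0.0, linked=True)
        before = spring_objective(model)
        after = spring_objective(relax(model, iterations=50))
        assert after <= before + 1e-12

    def test_linked_pair_pulled_together(self):
        model = _toy_pair(gap=5.0, linked=True)
        relaxed = relax(model, iterations=400)
        assert spring_objective(relaxed) < spring_objective(model)

    def test_overlapping_unlinked_pair_separates(self):
        geom = HelixGeometry.dna()
        length = 9 * geom.rise_per_bp
        t1, t2 = np.eye(4), np.eye(4)
        t2[:3, 3] = np.array([0.5, 0.0, 0.0])  # axes 0.5 nm apart: overlap
        cyls = [
            Cylinder(0, 0, 0, 1, t1, length, length, 10, geom.radius),
            Cylinder(1, 1, 2, 3, t2, length, length, 10, geom.radius),
        ]
        model = CylinderModel(cyls, [], 10.0, geom, "st-dna")
        relaxed = relax(model, iterations=2000)
        a0, a1 = relaxed.cylinders[0].axis_segment()
        b0, b1 = relaxed.cylinders[1].axis_segment()
        from wireweaver.cylinders import _segment_distance

        assert _segment_distance(a0, a1, b0, b1) >= 2.0 - 0.1

    def test_objective_never_increases_on_random_models(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            model = _toy_pair(gap=float(rng.uniform(0.5, 6.0)), linked=True)
            # random rigid perturbation of the second cylinder
            R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
            model.cylinders[1].transform[:3, :3] = R
            before = spring_objective(model)
            after = spring_objective(relax(model, iterations=150))
            assert after <= before + 1e-9
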