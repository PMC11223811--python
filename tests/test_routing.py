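"""Spanning-tree routings, reconditioning and the cycle cover."""

import numpy as np
import pytest

from wireweaver import (
    WireframeGraph,
    cycle_cover,
    make_mesh,
    prim_max_branching_tree,
    recondition,
    st_rna_route,
    st_route,
    xt_route,
    xuong_tree,
)
from wireweaver.errors import RoutingError
from wireweaver.graph import (
    Route,
    check_double_coverage,
    check_walks_closed,
    route_from_text,
    route_to_text,
)
from wireweaver.routing import check_junction_connectivity


class TestPrim:
    def test_k4_star_from_seed(self, tetra_graph):
        tree = prim_max_branching_tree(tetra_graph, seed_vertex=0)
        assert len(tree.edge_ids) == 3
        # every tree edge touches the seed: a star
        for eid in tree.edge_ids:
            e = tetra_graph.edge(eid)
            assert 0 in (e.u, e.v)

    def test_path_graph_unique_tree(self, path_graph):
        tree = prim_max_branching_tree(path_graph, seed_vertex=0)
        assert tree.edge_ids == frozenset(e.id for e in path_graph.edges)

    def test_wheel_seeded_at_hub_gives_spokes(self, wheel_graph):
        tree = prim_max_branching_tree(wheel_graph, seed_vertex=0)
        for eid in tree.edge_ids:
            e = wheel_graph.edge(eid)
            assert 0 in (e.u, e.v)  # spokes only

    def test_disconnected_rejected(self):
        pos = {0: np.zeros(3), 1: np.array([1.0, 0, 0]),
               2: np.array([5.0, 0, 0]), 3: np.array([6.0, 0, 0])}
        g = WireframeGraph.from_edges(pos, [(0, 1), (2, 3)])
        with pytest.raises(RoutingError):
            prim_max_branching_tree(g, 0)


class TestStRoute:
    def test_k4_twelve_traversals_single_walk(self, tetra_graph):
        tree = prim_max_branching_tree(tetra_graph, 0)
        route = st_route(tetra_graph, tree)
        assert len(route.walks) == 1
        assert route.n_traversals == 12  # 2 x 6 edges
        check_walks_closed(route)
        check_double_coverage(route, tetra_graph)

    def test_single_edge_out_and_back(self):
        pos = {0: np.zeros(3), 1: np.array([1.0, 0, 0])}
        g = WireframeGraph.from_edges(pos, [(0, 1)])
        tree = prim_max_branching_tree(g, 0)
        route = st_route(g, tree)
        assert route.n_traversals == 2
        check_walks_closed(route)

    def test_cube_24_traversals(self):
        g = WireframeGraph.from_mesh(make_mesh("cube"))
        route = st_route(g, prim_max_branching_tree(g, 0))
        assert len(route.walks) == 1
        assert route.n_traversals == 24
        check_double_coverage(route, g)

    def test_nontree_edges_annotated_for_crossovers(self, tetra_graph):
        tree = prim_max_branching_tree(tetra_graph, 0)
        route = st_route(tetra_graph, tree)
        crossover_edges = {t.edge_id for t in route.walks[0] if t.kind == "crossover"}
        assert crossover_edges == set(tree.cotree_ids)


class TestRecondition:
    def test_octahedron_already_even(self, octa_graph):
        assert recondition(octa_graph).n_edges == octa_graph.n_edges

    def test_tetrahedron_doubles_a_perfect_matching(self, tetra_graph):
        # all 3 perfect matchings of the 4 odd vertices cost the same on the
        # regular tetrahedron; any of them doubles exactly 2 disjoint edges
        recond = recondition(tetra_graph)
        added = [e for e in recond.edges if e.id >= tetra_graph.n_edges]
        assert len(added) == 2
        touched = {v for e in added for v in (e.u, e.v)}
        assert len(touched) == 4
        assert all(recond.degree(v) % 2 == 0 for v in recond.positions)

    def test_path_doubles_both_edges(self):
        pos = {0: np.zeros(3), 1: np.array([1.0, 0, 0]), 2: np.array([2.0, 0, 0])}
        g = WireframeGraph.from_edges(pos, [(0, 1), (1, 2)])
        recond = recondition(g)
        assert recond.n_edges == 4
        assert all(recond.degree(v) % 2 == 0 for v in recond.positions)

    def test_doubled_edges_adjacent_in_rotation(self, tetra_graph):
        recond = recondition(tetra_graph)
        for e in recond.edges:
            if e.id < tetra_graph.n_edges:
                continue
            twin = next(
                x.id for x in recond.edges if x.key == e.key and x.id != e.id
            )
            for v in (e.u, e.v):
                r = recond.rotation[v]
                i, j = r.index(twin), r.index(e.id)
                assert abs(i - j) == 1 or abs(i - j) == len(r) - 1


class TestCycleCover:
    def test_tetrahedron_face_boundaries(self, tetra_mesh, tetra_graph):
        route = cycle_cover(tetra_graph, faces=tetra_mesh.faces)
        assert len(route.walks) == 4
        assert route.n_traversals == 12
        check_walks_closed(route)
        check_double_coverage(route, tetra_graph)
        check_junction_connectivity(route, tetra_graph)

    def test_single_edge(self):
        pos = {0: np.zeros(3), 1: np.array([1.0, 0, 0])}
        g = WireframeGraph.from_edges(pos, [(0, 1)])
        route = cycle_cover(g)
        assert route.n_traversals == 2
        check_walks_closed(route)
        check_double_coverage(route, g)

    def test_abstract_k4_covered_once_per_direction(self, tetra_graph):
        route = cycle_cover(tetra_graph)  # ignore faces
        check_walks_closed(route)
        check_double_coverage(route, tetra_graph)
        check_junction_connectivity(route, tetra_graph)


class TestRnaRoutes:
    def test_st_rna_k4_three_kissing_loops(self, tetra_graph):
        tree = prim_max_branching_tree(tetra_graph, 0)
        route = st_rna_route(tetra_graph, tree)
        assert len(route.annotations["kissing_loops"]) == 3
        assert len(route.walks) == 1
        check_walks_closed(route)
        check_double_coverage(route, tetra_graph)

    def test_tree_graph_no_kissing_loops(self, path_graph):
        tree = prim_max_branching_tree(path_graph, 0)
        route = st_rna_route(path_graph, tree)
        assert route.annotations["kissing_loops"] == []

    def test_icosahedron_cycle_rank_kissing_loops(self):
        g = WireframeGraph.from_mesh(make_mesh("icosahedron"))
        route = st_rna_route(g, prim_max_branching_tree(g, 0))
        assert len(route.annotations["kissing_loops"]) == 30 - 11  # E - (V-1)
        check_double_coverage(route, g)

    def test_nick_at_longest_ordinary_edge(self):
        # stretch one tetrahedron vertex so the longest edge is unique
        mesh = make_mesh("tetrahedron")
        mesh.vertices[0] *= 1.8
        g = WireframeGraph.from_mesh(mesh)
        tree = prim_max_branching_tree(g, 0)
        route = st_rna_route(g, tree)
        nick = route.annotations["nick_edge"]
        kl = set(route.annotations["kissing_loops"])
        assert nick is not None and nick not in kl
        longest_ok = max(
            (e.id for e in g.edges if e.id not in kl), key=g.length
        )
        assert nick == longest_ok

    def test_xt_route_k4_single_kissing_loop(self, tetra_graph):
        tree = xuong_tree(tetra_graph, mode="exact")
        route = xt_route(tetra_graph, tree)
        assert len(route.annotations["kissing_loops"]) == 1
        check_walks_closed(route)
        check_double_coverage(route, tetra_graph)

    def test_xt_route_c4_single_kissing_loop(self, cycle_graph):
        tree = xuong_tree(cycle_graph, mode="exact")
        route = xt_route(cycle_graph, tree)
        assert len(route.annotations["kissing_loops"]) == 1

    def test_xt_route_two_triangles_no_kissing_loops(self, two_triangles_graph):
        tree = xuong_tree(two_triangles_graph, mode="exact")
        route = xt_route(two_triangles_graph, tree)
        assert route.annotations["kissing_loops"] == []
        check_double_coverage(route, two_triangles_graph)


class TestRouteText:
    def test_round_trip(self, tetra_graph):
        route = st_route(tetra_graph, prim_max_branching_tree(tetra_graph, 0))
        pairs = route_from_text(route_to_text(route))
        assert pairs == [(t.frm, t.to) for t in route.walks[0]]

    def test_comments_ignored(self):
        assert route_from_text("# hello\n0 1\n\n1 0  # back\n") == [(0, 1), (1, 0)]
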