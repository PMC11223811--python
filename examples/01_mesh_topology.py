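"""Read a polygon mesh and diagnose its surface topology.

The A-trail method needs a closed orientable 2-manifold; the other methods
accept any connected wireframe.  Genus comes from the Euler characteristic
V - E + F = 2 - 2g and decides whether an A-trail routing is guaranteed
unknotted (genus 0) or merely possible (genus > 0).
"""

from wireweaver import analyze_topology, make_obj, parse_obj

for shape in ("tetrahedron", "icosahedron", "torus"):
    mesh = parse_obj(make_obj(shape))  # any OBJ file works the same way
    rep = analyze_topology(mesh)
    print(
        f"{shape:12s} V={rep.n_vertices:3d} E={rep.n_edges:3d} F={rep.n_faces:3d} "
        f"closed={rep.is_closed_manifold} genus={rep.genus} "
        f"odd-degree vertices={rep.odd_degree_vertex_count}"
    )

print()
print("A genus-0 mesh guarantees an unknotted A-trail scaffold;")
print("odd-degree vertices are the ones reconditioning must fix.")
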