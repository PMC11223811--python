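"""Find an A-trail scaffold routing on the octahedron.

The wireframe is first reconditioned (parallel edges added so every junction
has even degree -- the octahedron is already even), then a branch-and-bound
search picks one of the two sharp-turn transition systems at each junction
so that the whole wireframe is covered by a single circuit.
"""

from wireweaver import WireframeGraph, atrail_search, make_mesh, recondition
from wireweaver.routing import check_sharp_turns

graph = recondition(WireframeGraph.from_mesh(make_mesh("octahedron")))
result = atrail_search(graph)

route = result.route
print(f"A-trail found: {result.found} (explored {result.nodes} search nodes)")
print(f"circuit length: {route.n_traversals} edge traversals "
      f"({graph.n_edges} reconditioned edges, each exactly once)")
print(f"sharp-turn violations: {len(check_sharp_turns(graph, route))}")
print(f"per-junction turn configuration: {route.annotations['turn_config']}")
print()
print("walk:", " -> ".join(str(t.frm) for t in route.walks[0][:13]), "...")
print("Every consecutive pair of edges is adjacent in the junction's rotation")
print("order, which is what keeps a genus-0 scaffold unknotted.")
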