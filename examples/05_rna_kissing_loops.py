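"""XT-RNA: single-stranded RNA origami with a minimal number of kissing loops.

A Xuong tree minimises the number of odd-sized co-tree components; one
180-degree kissing loop is needed per odd component, so fully triangulated
(upper-embeddable) meshes need at most one.  Compare with ST-RNA, which
turns every non-tree edge into a kissing loop.
"""

from wireweaver import (
    WireframeGraph, export_nupack, make_mesh, prim_max_branching_tree,
    st_rna_route, xt_route, xuong_tree,
)
from wireweaver.pipeline import RunConfig, design_from_mesh

graph = WireframeGraph.from_mesh(make_mesh("icosahedron"))
st = st_rna_route(graph, prim_max_branching_tree(graph, 0))
xt = xt_route(graph, xuong_tree(graph, mode="auto"))
print(f"icosahedron (30 edges): ST-RNA needs {len(st.annotations['kissing_loops'])} "
      f"kissing loops, XT-RNA needs {len(xt.annotations['kissing_loops'])}")

report, artifacts = design_from_mesh(
    make_mesh("icosahedron"), RunConfig(method="xt-rna", seed=1)
)
model = artifacts["nucleotide_model"]
strand = model.strands()[0]
print(f"single RNA strand: {len(strand.ids)} nt, circular={strand.circular} "
      "(one open nick at the longest ordinary edge)")

npk = export_nupack(model)
print("\nNUPACK-style design file (first lines):")
for line in npk.splitlines()[:3]:
    print(" ", line[:70] + ("..." if len(line) > 70 else ""))
print("Kissing-loop bases are fixed letters; everything else is N for the")
print("external sequence designer to fill in.")
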