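# wireweaver

Design of DNA and RNA **wireframe nanostructures** from polygon meshes.

A wireframe nanostructure realizes only the edges and vertices of a 3D
polyhedral model, one double helix (or two-helix bundle) per edge.  Given a
mesh in Wavefront OBJ format, `wireweaver` computes a strand routing,
positions a rigid-cylinder model of the double helices, expands it into an
oriented nucleotide-level model, designs primary sequences, and exports the
result to oxDNA (simulation), UNF (interchange) and CSV (synthesis).  It is
a scriptable library for structural DNA/RNA nanotechnology with a thin CLI on
top.

## Routing methods

| method  | strands | idea |
|---------|---------|------|
| `at-dna` | scaffold + staples | A-trail: Eulerian circuit of the reconditioned wireframe in which every junction turn is a sharp left/right (rotation-adjacent edges); unknotted on genus-0 meshes |
| `st-dna` | scaffold + staples | scaffold routed twice around a maximally-branching (Prim) spanning tree; every edge a two-helix bundle, helix lengths rounded to whole turns |
| `cc-dna` | cyclic strands, scaffold-free | directed cycles covering every edge once per direction (face boundaries on a manifold); staggered nicks cut them into oligos |
| `st-rna` | one RNA strand | single strand twice around a spanning tree; each non-tree edge becomes a 180° kissing-loop pair of hairpins |
| `xt-rna` | one RNA strand | same around a *Xuong tree*, which minimises odd-sized co-tree components; ≤ 1 kissing loop on fully triangulated meshes |

Coverage laws are enforced by validators: the double-traversal methods cover
every edge exactly twice in antiparallel directions; the A-trail covers every
reconditioned edge exactly once with zero sharp-turn violations.

The cylinder model fixes the duplex diameter at 2.0 nm (B-DNA) or 2.3 nm
(A-RNA).  A user *scale* parameter converts mesh units to nanometers: at a
scale of 1 nm, an edge of length 1 becomes a cylinder of nominal length 1 nm.
Base counts follow from the helical rise (0.332 nm/bp DNA, 0.281 nm/bp RNA).
Sequences come from a scaffold (FASTA or seeded random) with Watson–Crick
complement staples, or — for the scaffold-free cycle cover — from a Focused
Metropolis Search that minimises the length `L` of the longest repeated
substring over all strands subject to GC-content bounds and forbidden
subsequences.

## Worked example

```sh
python examples/03_spanning_tree_design.py
```

```
nucleotides: 1082, strands: 13
coverage: each edge twice, antiparallel
complementarity check: True
staple length histogram: {44: 2, 45: 1, 46: 7, 47: 2}

first staple (44 nt, 5'->3'): TTCGTATCAGGCGAAGTAGATTTTCTGCATAATATGAAAATCTG
```

A tetrahedron at scale 10 nm consumes a 1082-nt design: one circular scaffold
routed twice over all 6 edges (12 cylinders of 21 bp, rounded to two full
turns each) and 12 staples of 44–47 nt.  Every staple binds the scaffold in
contiguous domains of at least `min_overlap` = 8 nt, the user-set stability
threshold for nicking; the complementarity validator confirms every base pair
is Watson–Crick.

Each `examples/*.py` script shows one capability end to end (topology
analysis, A-trail search, scaffolded design, FMS sequence optimisation,
kissing-loop minimisation, exports).  The same pipeline runs from the shell:

```sh
wireweaver fixtures tetrahedron --out tetra.obj
wireweaver design tetra.obj --method st-dna --seed 1 --out out/
wireweaver validate out/design.top out/design.dat
```

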