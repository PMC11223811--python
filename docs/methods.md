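# Methods

This note documents the models, algorithms and numerical choices behind
`wireweaver`, and what its tests do and do not establish.

## Mesh and rotation system

The input is a polygon surface mesh (OBJ).  Faces are used exactly as given:
no triangulation, no vertex welding (an optional `merge_epsilon` welds on
request; welding can silently change topology, so it is off by default).
Topology analysis classifies the mesh as closed-manifold (every edge in
exactly two faces), orientable (the two faces traverse the edge in opposite
directions) and computes the genus from the Euler characteristic.

The **rotation system** — the cyclic order of edges around each vertex — is
read off the face incidence for closed orientable manifolds, which makes it
an invariant of the embedding.  For non-manifold or faceless wireframes
(allowed by all methods except the A-trail), the fallback is geometric:
incident edge directions are projected onto the plane normal to an estimated
vertex normal (mean incident-face normal, else the best-fit plane of the edge
directions) and sorted by angle.  This fallback is a design choice; different
but equally valid cyclic orders would yield different, equally valid routings.

## Routing methods

**ST-DNA.**  Prim-style growth that always attaches the vertex adjacent to
the most tree vertices (ties: lowest index) produces a maximally branching
spanning tree.  The scaffold route is the boundary walk of this tree in
rotation order; each non-tree edge is visited as a full out-and-back
excursion at its first rotation slot and annotated for a scaffold crossover.
This places the crossover at the far vertex of the edge rather than at its
midpoint; the coverage law (every edge exactly twice, antiparallel, one
closed walk) is exact, but the fine stapling pattern of the original
two-helix-bundle scheme is approximated.  Helix lengths are rounded to an
integer number of turns (round-half-down, never below one turn), only in
this method.

**AT-DNA.**  Reconditioning makes all degrees even by doubling the edges of
a minimum-length T-join: odd-degree vertices are matched by a minimum-weight
perfect matching (exact blossom matching at any size) over shortest-path
distances, and edges used by an odd number of matched paths are doubled.
Doubled edges sit adjacent to their originals in the rotation order.  The
A-trail search then assigns to each junction one of its two *sharp-turn
transition systems* — the two perfect matchings of rotation-adjacent edge
pairs — by branch and bound in decreasing-degree vertex order.  A union-find
structure over edge-ends (with rollback) prunes any partial assignment that
seals a circuit not containing all edges.  The search is deterministic; on
graphs with at most ~20 junctions an exhaustive oracle over all 2^V
configurations cross-checks it.  Toroidal meshes are routed with a warning:
the sharp-turn condition guarantees unknottedness only on genus-0 meshes, and
no knot-invariant computation is attempted.

**CC-DNA.**  With faces, the cycle cover is the set of face-boundary cycles,
which double-cover the edges of a consistently wound manifold antiparallel
by construction.  Without faces, the cover traces the faces of the
rotation-system embedding (leave on the rotation successor of the arriving
edge), which chains all arms of every junction into a single transition
cycle — the arms stay connected, which face-boundary covers also satisfy.

**ST-RNA / XT-RNA.**  The single strand follows the spanning-tree boundary
walk; non-tree edges are visited as two hairpin half-edges, one per endpoint
slot, meeting at the edge midpoint as a 180° kissing loop.  The Xuong tree
minimises the number of odd-edge-count co-tree components: exact mode
enumerates spanning trees (budget 10^5, refused above; matrix-tree count
decides feasibility) with early exit at the parity lower bound (Betti number
mod 2); heuristic mode improves a Prim tree by tree-edge swaps and is never
worse than its start.  One kissing loop is flagged per odd component (lowest
edge id); even-component edges are routed as full out-and-back duplex
excursions.  The strand's open 3′-to-5′ nick goes to the longest
*ordinary* (non-kissing-loop) edge, since a hairpin pair cannot host it.

## Cylinder model

Each routed duplex segment becomes a rigid cylinder: 4×4 transform (local Y
= helix axis), radius 1.0 nm (DNA) or 1.15 nm (RNA), and four connection
points — the two 5′ and two 3′ strand ends, placed on the backbone radius
(0.9 × radius) at the azimuth given by the accumulated twist.  Helix
constants default to B-DNA (rise 0.332 nm/bp, 10.5 bp/turn, backbone groove
offset 120°) and A-RNA (0.281 nm/bp, 11.0 bp/turn, 139°); all are fields of
`HelixGeometry`.  Methods that route both strands of a duplex (CC, RNA) get
one cylinder per edge; scaffolded methods get one per traversal, with repeat
visits of a vertex pair offset sideways by one radius (two-helix bundles and
doubled edges).

Cylinder ends are pulled back from the vertex by a clearance
`d = r / tan(α/2)`, where α is the smallest angle to a neighbouring edge at
that vertex (parallel twin edges excluded — they are offset laterally, not
axially), clamped to [0, 0.45 × edge length].  The base-pair count is
`floor(usable / rise)`, at least 1; kissing-loop cylinders additionally need
`2 (loop + 1)` bp, and a scale too small to meet a minimum raises an error
listing the offending edges.  The local X axis is seeded from the first
other rotation neighbour at the start vertex, which makes the whole
construction equivariant under rigid motions of the mesh (verified end to
end in the tests).

**Relaxation** is a damped rigid-body spring integrator (defaults: 500
steps, dt 0.01, stiffness 1, damping 0.5): springs pull linked connection
points together; sphere-swept-segment collisions push non-linked cylinders
apart (pairs sharing a mesh vertex are exempt — their spacing is already
governed by the clearance).  The best visited state is returned, ranked by
(collision infeasibility beyond a 0.1 nm tolerance, spring objective), so
the returned spring objective never exceeds the input's and feasibility is
never sacrificed for it.  Divergent (non-finite) integration raises an error
suggesting a smaller step.

## Nucleotide model

A template double helix is generated along local Y (strand 1 gains Y from
5′ to 3′; strand 2 antiparallel) and mapped through each cylinder's
transform.  Orientation vectors follow the oxDNA convention: `a1` backbone →
base, `a3` along the 3′→5′ axis, so paired bases satisfy `a1·a1 < 0` in the
groove sense and `a3·a3 = −1`.

Linked strand ends are joined by `k = max(0, round(gap/0.6 nm) − 1)` unpaired
linker bases (cap 5, or a fixed user count), positioned by spherical linear
interpolation of the direction about the junction vertex with linearly
interpolated radius; orientation vectors are slerped between the end bases.
Antipodal or degenerate geometry falls back to linear interpolation.

**Kissing loops.**  A flagged cylinder is split at mid-helix into two
hairpins, each keeping its stem pairing; the 7 bases adjacent to the split on
each hairpin (configurable `kl_loop_len`) are re-paired *across* the
hairpins, their former partners becoming unpaired flanks.  This is a coarse
stand-in for the full loop–loop motif geometry: pairing bookkeeping, strand
closure and sequence assignment are exact, atomic loop geometry is not
modelled.

**Nicking.**  Candidates are staple-side helix ends (scaffolded methods) or
one mid-edge cut per duplex on alternating strands chosen to open every
cycle (cycle cover).  All candidates are inserted, then repaired greedily:
while any *binding domain* — a maximal run of a strand paired to consecutive
antiparallel bases of one partner strand — of a linear strand is shorter
than `min_overlap` (default 8 nt), the nick bounding the shortest illegal
domain is removed (lowest id first; deterministic).  Scaffolds are never
nicked; cycles too short to nick are left circular with a warning.  RNA
designs receive exactly one nick, mid-helix on the longest ordinary edge.

## Sequence design

Scaffolded designs thread the scaffold 5′→3′ along its route and set every
paired staple base to the Watson–Crick complement; staple linkers default to
T (U for RNA).  The cycle cover uses a **Focused Metropolis Search**: mutate
a uniformly random free position — with probability 0.9 a position inside a
current occurrence of a longest repeated substring — propagate the
complement, reject outright any move violating the per-strand GC bounds or
forbidden subsequences, accept non-increases of the repeat-length objective
and increases with probability exp(−Δ/T), T = 0.5.  The best assignment seen
is returned, making the best-so-far objective monotone.  The repeat length
itself is computed by binary search over the answer with a per-length
substring set (occurrences confined to single strands, overlaps allowed);
an independent quadratic common-extension table serves as the oracle in
tests.  Move-set and temperature are package defaults: the original search
schedule is not published in a reproducible form.

Kissing-loop sequences come from a packaged table of mutually
reverse-complementary 7-mers — a synthetic, user-replaceable fixture, not an
experimentally validated list.  RNA designs can be exported as a minimal
NUPACK-style design file (dot-paren structure; kissing loops as fixed-letter
domains since they are pseudoknots; N elsewhere) and external sequences
imported back with strict length checks.

## Exports

oxDNA legacy `.top`/`.dat` with nucleotides indexed strand-by-strand, 5′→3′
(documented in the writer; classic files list 3′→5′), coordinates in oxDNA
simulation units (0.8518 nm), zero velocities; the write→read round trip is
the identity on bases, connectivity and nm coordinates to 1e-6.  The cubic
box defaults to 1.5 × the bounding-box diagonal.  UNF output targets a
documented subset of the schema, version pinned to 1.0.0.  CSV rows are
`name, length, sequence, role`, with circular strands marked.

## Test fixtures and problem sizes

All test inputs are generated programmatically: the five platonic/prism
solids at unit circumradius and a configurable quad torus (radii 2 / 0.7).
Default test conditions are scale 10 nm per mesh unit and `min_overlap` 8 nt,
giving edges of roughly 20–50 bp — the scale regime of small wireframe
designs.  Exhaustive oracles run at desk scale: all 2^V sharp-turn
configurations (V ≤ 12), all spanning trees (≤ 384), all Eulerian circuits of
a 6-edge bowtie, all 4^4 sequences of a 4-bp duplex, repeat lengths up to
200 nt.  Passing these establishes the combinatorial laws (coverage, sharp
turns, kissing-loop counts, monotone objectives, round-trip identities) and
the stated geometric constants; it does not validate folding
thermodynamics, knotting of the nucleotide-level model, or wet-lab yields.

## Known limitations

- Scaffold crossovers on ST-DNA non-tree edges sit at the far vertex, not
  the edge midpoint; the specific stapling pattern of two-helix bundles is
  approximated by mirror-linked complementary strands.
- Kissing-loop geometry is a pairing-level model; no atomic motif.
- No knot detection beyond the genus-0 guarantee of sharp-turn routing.
- The relaxation is a lightweight integrator, not a physics-engine-grade
  solver; it guarantees monotone objectives, not global minima.
- Multi-helix edge reinforcement and PDB export are out of scope.
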