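# Methods

This note records the models, numerical choices and known limitations of
`hepatree`, at the level of detail a maintainer or reviewer needs to judge
what the package computes and what its tests do and do not show.

## Digital topology conventions

Foreground (vessel) voxels are read with 26-adjacency, background with
6-adjacency — the complementary pair under which a curve skeleton is well
defined. The Euler characteristic χ = objects − tunnels + cavities of a
binary volume equals the combinatorial Euler characteristic V − E + F − C
of the union of the closed unit cubes of the foreground voxels: corner-
and edge-touching cubes are connected (which is exactly 26-adjacency) and
the open complement decomposes into 6-connected regions. `hepatree.euler`
computes χ this way by direct cell counting — vectorized OR-pooling over
the cell lattice — and derives tunnels as objects + cavities − χ with
objects/cavities from component labeling. Everything out of grid is
background.

## Thinning

A voxel is deleted only if it is **border** (≥ 1 background 6-neighbor),
**line** (> 1 foreground 26-neighbor — endpoints are never deleted),
**Euler-invariant** (deleting it leaves χ of its 26-neighborhood
unchanged) and **simple** (its foreground neighbors form a single
26-component, so deletion leaves local connectivity intact). Sequential
deletion of such voxels provably preserves global component count and χ.

The Euler condition is evaluated with a 128-entry per-octant table: the
change of χ caused by deleting the center decomposes over the eight
2×2×2 octants containing it, each contribution a function of the octant's
seven non-center voxels. The table entries (stored ×8, so they are
integers) were obtained by solving that decomposition exactly against the
cell-counting χ — the linear system over 60 000 random neighborhoods has
full rank 128 and integer solution with zero residual — and the test
suite re-verifies table and predicate against the brute-force χ on
fresh random patches. The simplicity test is a bitmask flood fill over
the 26-neighbor adjacency graph; both predicates are memoized on the
26-bit neighborhood configuration.

**Deletion schedule.** Deletions run in passes of six directional
subiterations (up/down/north/south/east/west). Within a subiteration,
candidates are the voxels whose face-neighbor *in* the sweep direction is
background **and** whose opposite face-neighbor is foreground; they are
visited in lexicographic (z, y, x) order and re-checked against the
current image at deletion time, so results are bit-reproducible. The
support condition (material behind the voxel) is essential: without it, a
staggered one-voxel-thick ribbon — which arises whenever a tube's axis
falls between voxel columns — can be consumed end-to-end within a single
subiteration, each deletion locally topology-preserving while the
geometry collapses (a radius-2.2 tube centered on half-integer
coordinates loses 17 of its 19 centerline voxels; a widely used
Lee-style reference implementation returns an empty volume on the same
input). Neither border nor support status of a pending candidate can be
invalidated by other deletions of the same sweep, so the directional
phase needs no extra bookkeeping. Once it converges, one unrestricted
sequential cleanup pass removes the few redundant corner voxels the
support condition protects (at that point the object is curve-like and
cannot retract); the phases alternate to a global fixpoint at which no
voxel satisfies all four conditions. Thinning is idempotent, and
topology preservation is asserted exactly — not approximately — on every
phantom in the test suite.

## Graph extraction

End-voxels have one skeleton 26-neighbor; branch-voxel candidates have at
least three. Candidates cluster into 26-connected groups at junctions;
within each cluster the voxel with the highest connectivity cost
4·(#skeleton neighbors) + 3·(#face-connected candidates) +
2·(#edge-connected) + 1·(#vertex-connected) becomes the branch vertex
(ties to the lexicographically smallest voxel), the rest are absorbed.
Chains of degree-2 voxels between vertices become edges.

Edges carry: curve **length** (sum of physical steps along the path),
chord **distance** (≤ length), **volume** (voxel volume × number of
vessel voxels whose nearest retained skeleton voxel lies on the edge,
nearest computed in physical units; vertex voxels count for their lowest
incident edge), and **mean radius** √(Volume/(π·Length)). The raw ratio
Volume/(π·Length) has the dimension of a squared length, so the
square-root form is used and the raw value kept as a debug field.
Vertex **radius** is the Euclidean distance transform of the vessel mask
at the vertex.

**Spur pruning.** Thinning raises short leaf chains where tube surfaces
bulge at junctions. A leaf chain attached to a junction is an artifact,
not anatomy, when its curve length does not exceed 2·Radius(junction)
plus one voxel diagonal — it never leaves the junction's lumen. Such
chains are pruned before measurement (`prune_spurs=True`, the default)
and junctions left with two incident chains are dissolved into a single
through-going edge. Pruned voxels are excluded from volume attraction and
listed in `graph["pruned_spur_voxels"]`; absorbed junction voxels in
`graph["junction_cluster_voxels"]`. With pruning, phantom graph recovery
is exact (end-voxel and branch counts) with mean radii within half a
voxel of the true tube radii.

## Tree generation

The root is the end-vertex maximizing Radius(v) + MeanRadius(incident
edge); ties go to the lowest coordinate. Breadth-first search (vertices
and parallel edges in sorted order, hence deterministic) orients edges
downstream; non-tree edges are flagged cyclic. Redundant branches are
self-loops and leaf edges whose path voxels (except the tip) all have the
junction as nearest vertex *and* whose tip lies within
2·Radius(junction) + one voxel diagonal — the caliber gate is needed
because the nearest-vertex test alone is satisfied by any leaf edge whose
discrete path has no interior voxels.

Cyclic branches are resolved per ramification, in BFS order from the
root: with inflow mean radius r_in, non-cyclic outflow radii r_j and m
cyclic candidates, all 2^m candidate subsets are enumerated (m ≤ 16;
beyond that a greedy largest-first match substitutes, with a warning) and
the subset minimizing |r_in² − Σ r_j² − Σ r_subset²| is kept — inflow
equals outflow when flow scales with the vessel cross-section. The
absolute value matters: signed minimization would always delete
everything. Ties prefer smaller, lexicographically earlier subsets, so
the result is deterministic and matches exhaustive enumeration by
construction *and* by test against an independent bitmask enumerator.
Because kept subsets can interact across junctions, any surviving cycle
is finally broken at its smallest-mean-radius edge; the result is
re-oriented from the root and satisfies #edges = #vertices − 1 with
in-degree ≤ 1 everywhere. Branch angles are the angles between parent and
child chord vectors at the shared vertex, in [0°, 180°].

## Hierarchy and clustering

Branch mean radii are modeled as a two-component univariate Gaussian
mixture (EM, fixed seed, 5 initializations). With μ the mean of the
small-radius component and Min/Max the observed extremes, the distal
(Second Subtree) radius range is [Min, 2μ − Min], so θ = 2μ − Min,
clamped into [Min, Max]. The fit falls back to θ = 0.5·Max (again
clamped) when fewer than 4 radii are available, when the component means
are closer than 10⁻³, or when a component weight is below 0.05. Edges
with mean radius ≤ θ form maximal connected subtrees, rooted at their
minimum-depth vertex; subtrees with ≤ 5 vertices (Micro Subtrees) are
pruned as trivial structure. The surviving subtree roots' physical
coordinates are clustered with k-means++ (fixed seed, 10 restarts, best
inertia) into K = 8 groups; all vertices of a subtree inherit its group.
Cluster labels are renumbered by order of first appearance so a fixed
seed yields identical labels across runs. If fewer than K subtrees
survive, K is lowered with a warning rather than fabricating segments.

## Voxel classification and report

A liver voxel's segment is the branch group at minimum physical Euclidean
distance, distance to a group being the minimum over all its voxels —
skeleton path voxels and vertices by default (`vertices_only` gives the
sparser variant). Ties break to the lowest group label. The
implementation runs one exact Euclidean feature transform per group and
then recomputes each distance with the plain squared-offset formula
Σ((Δindex)·spacing)², so the arg-min sees exactly the same floating-point
values as a brute-force all-pairs computation — the test suite asserts
bitwise label equality, not approximate agreement. Distances honor
anisotropic spacing.

The report tables follow: N_seg (voxels), V_seg (mL), R_seg (% of the
labeled liver, denominator Σ N_seg so the column closes to 100 ± 0.01
under 2-decimal rounding), R_tumor (% of the segment), plus the lobe
grouping (caudal = SegI; left lateral = II+III; left medial = IV; right
anterior = VIII+V; right posterior = VII+VI; left lobe = II–IV; right
lobe = V–VIII). Cluster labels carry no anatomical identity; mapping
clusters to SegI..SegVIII is a user-supplied relabeling (identity by
default). SegIV is treated as a single segment, consistent with K = 8.
Written artifacts (NIfTI labels, CSV tables, tree + tumor-membership
JSON, manifest) are byte-identical across reruns with identical inputs.

## Phantoms

`rasterize_tree` renders each tree edge as a capsule (cylinder with
hemispherical caps) so junctions are watertight — no spurious cavities at
branch points; a voxel is foreground iff its center is within the edge
radius of the segment. Indices are 0-based (z, y, x), physical position =
index × spacing. Rasterization is monotone in radius, and validation
rejects radii under one voxel, disconnected trees, and out-of-grid nodes.

`random_tree_spec` grows a trunk plus two levels of binary branching
(default 64³ grid, 1 mm spacing, trunk radius 2.2 mm decaying by 0.65 per
level, branch angles 28–45°) with collision checks keeping non-adjacent
segments at least four trunk radii apart; junctions are placed
symmetrically (one polar angle, evenly spread azimuths) so thinning
produces a single compact branch point per ground-truth node. Branches
that cannot be placed are dropped, so the returned spec is always the
ground truth of what was built.

`couinaud_phantom_spec` emulates the portal anatomy the annotation
targets: a 3 mm trunk crossing a 112×128×112 liver ellipsoid with eight
three-level limb systems (7 edges each) attached at golden-angle
azimuths. Distal radii are kept nearly uniform (1.05–1.15 mm) so the
radius mixture cleanly separates trunk from limbs and θ covers every limb
edge; each limb subtree has 7–8 vertices and survives micro-pruning,
giving exactly eight branch groups.

`corrupt_mask` deterministically deletes pairwise non-adjacent strictly
interior voxels (isolated cavities, χ += 1 each) and draws straight
one-voxel bridges between surface voxels across background (each closes a
cycle, χ −= 1), preserving the single 26-component; bridging a convex
shape is impossible and raises.

What the phantoms do **not** emulate: CT intensity statistics, noise
textures, partial-volume effects, anatomical curvature of real portal
branches, or contact between vessel and liver boundary. Passing tests
therefore demonstrate correctness of the discrete pipeline under known
topology and geometry, not segmentation robustness on clinical images.

## Problem sizes

The test suite and the acceptance script run on desk-scale inputs chosen
as the smallest sizes at which every property is meaningful: 48³–64³
grids for topology/graph batches (50 and 10 phantoms respectively), the
112×128×112 eight-limb phantom for the end-to-end run, 100 randomized
ramifications (m ≤ 12) for flow-matching equivalence, and n = 1000
samples for radius-threshold recovery.

## Known limitations

- Portal/hepatic separation is approximated by largest-component
  selection; a user-supplied seed point can override it. Hepatic-vein
  analysis is out of scope beyond the edge label field.
- Mean-radius estimates of short edges adjacent to thick junctions are
  biased upward (junction-bulge volume is attributed to them). On a
  minority of random phantom geometries this pushes one distal edge above
  θ, splitting a limb subtree into pieces small enough to be
  micro-pruned, and the run yields 7 clusters instead of 8; θ can be
  overridden per run (`--theta`) exactly as a user would tune it on real
  data with the 3D view.
- The thinning fixpoint can retain a bounded number of junction-cluster
  voxels (degree ≥ 3) beyond the single representative; these are
  absorbed into edge paths and never affect topology, but branch-vertex
  positions are accurate only to about one voxel.
- k-means++ clusters carry arbitrary numeric labels; anatomical naming
  requires the relabeling table.
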