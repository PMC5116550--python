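# hepatree

Vessel-tree-based functional liver annotation for 3D volumes.

Surgeons and radiologists reason about the liver in terms of the Couinaud
classification: eight functionally independent segments, each supplied by
its own portal-vein branch. Given a segmented liver mask and a vessel
volume (binary, or a contrast-enhanced image), `hepatree` reconstructs the
portal tree and partitions the liver into those eight blood-supply
territories, producing a quantitative annotation report — per-segment
voxel counts and volumes, segment-to-liver ratios, lobe groupings, and the
segment membership of any tumor.

## Method

The pipeline follows the anatomy: a liver voxel belongs to the segment
whose portal branch feeds it, so the problem reduces to reconstructing the
branching structure of the portal vein and classifying voxels by their
nearest branch.

1. **Vessel enhancement** (optional, for intensity input). Tubular
   structures are enhanced with the Hessian-eigenvalue vesselness
   measure: with eigenvalues ordered |λ₁| ≤ |λ₂| ≤ |λ₃|, a bright tube has
   λ₁ ≈ 0 and λ₂, λ₃ ≪ 0, and the response is

   V = (1 − e^(−R_a²/2α²)) · e^(−R_b²/2β²) · (1 − e^(−R_c²/2c²)),

   zero whenever λ₂ ≥ 0 or λ₃ ≥ 0, with R_a = λ₂/λ₃, R_b = λ₁/√(λ₂λ₃),
   R_c = ‖λ‖₂, and defaults α = 0.3, β = 0.7, c = I_max/2. A 26-connected
   region grown from the strongest response, closed morphologically, and
   reduced to its largest component yields the portal mask.
2. **Skeletonization.** A 3D thinning pass iteratively deletes voxels that
   are simultaneously *border* (a 6-neighbor is background), *line* (more
   than one 26-neighbor, so endpoints survive), *Euler-invariant* (deleting
   them preserves χ = objects − tunnels + cavities of the neighborhood,
   checked with a per-octant lookup table) and *simple* (deletion preserves
   local connectivity). The result is a single-voxel-wide, medially placed
   curve skeleton with exactly the topology of the input.
3. **Graph construction.** End-voxels (one skeleton neighbor) and
   branch-voxels (three or more; one representative per junction cluster,
   chosen by a connectivity cost) become vertices; the voxel chains
   between them become edges measured with curve length, chord distance,
   vessel volume and mean radius √(Volume/(π·Length)).
4. **Tree generation.** The root is the end-vertex maximizing
   Radius(v) + MeanRadius(edge) — the main portal trunk. Breadth-first
   orientation directs every edge downstream; redundant self-loops and
   junction spurs are dropped, and cyclic branches (artifacts of imperfect
   segmentation) are resolved by flow matching: blood inflow equals
   outflow at a ramification, flow scaling with the squared radius, so the
   subset of cyclic outflows minimizing |r_in² − Σ r_out²| is kept.
5. **Hierarchical division.** Branch radii form two populations — few
   thick trunk branches, many thin distal ones. A two-component Gaussian
   mixture gives the small-component mean μ, and θ = 2μ − Min splits First
   (trunk) from Second (distal) Subtrees. Micro Subtrees (≤ 5 vertices)
   are pruned; the surviving subtree roots are clustered by k-means++ into
   K = 8 blood-supply branch groups.
6. **Annotation.** Every liver voxel takes the label of the branch group
   at minimum Euclidean distance (ties to the lowest label), yielding the
   segment map and the report tables.

A synthetic phantom module generates tubular branching trees of known
topology and radii (capsule rasterization) inside an ellipsoidal liver,
with optional tumors, cavities and cycle-inducing bridges, so every stage
is testable without patient data.

## Worked example

Build an eight-limb portal phantom and annotate it:

```python
from hepatree.phantom import couinaud_phantom_spec, make_liver_phantom
from hepatree.pipeline import run_pipeline

spec = couinaud_phantom_spec(0)                      # known ground truth
liver, vessels, tumors = make_liver_phantom(
    spec, tumor_centers=[(30.0, 45.0, 70.0)], tumor_radii=[7.0])
res = run_pipeline(liver, vessels, spec.spacing, tumors=tumors, seed=0)
print(res["attributes"].to_string(index=False))
print(res["lobes"].to_string(index=False))
```

prints

```
 label  n_seg  v_seg_ml  r_seg_pct  r_tumor_pct
     1  90166     90.17      11.00         0.00
     2  86702     86.70      10.58         0.00
     3  87758     87.76      10.71         1.62
     4 110269    110.27      13.46         0.00
     5 102507    102.51      12.51         0.00
     6 105036    105.04      12.82         0.00
     7 130402    130.40      15.91         0.00
     8 106536    106.54      13.00         0.00

                lobe                  segments  n_voxels  ratio_pct
         caudal_lobe                      SegI     90166      11.00
   left_lateral_lobe              SegII+SegIII    174460      21.29
    left_medial_lobe                     SegIV    110269      13.46
 right_anterior_lobe              SegVIII+SegV    209043      25.51
right_posterior_lobe              SegVII+SegVI    235438      28.73
           left_lobe        SegII+SegIII+SegIV    284729      34.75
          right_lobe SegV+SegVI+SegVII+SegVIII    444481      54.25
```

Each row of the first table is one recovered blood-supply territory:
its voxel count, volume in mL (1 voxel = 1 mm³ here), share of the liver,
and the fraction of the segment occupied by tumor — the 7 mm tumor ball
lands entirely in one territory (1.62 % of segment 3). The ratios sum to
100 % because the segments partition the liver mask exactly. The second
table groups segments into the standard lobes; numeric cluster labels are
mapped to anatomical names SegI..SegVIII by a user-supplied relabeling
(identity here), since cluster order carries no anatomical meaning.

The same pipeline is available from the shell:

```
hepatree phantom --seed 0 --out-prefix /tmp/ph
hepatree pipeline --liver /tmp/ph_liver.nii --vessels /tmp/ph_vessels.nii \
    --out-dir /tmp/report --seed 0
```

writing `segments.nii`, `segment_attributes.csv`, `lobe_report.csv`,
`tree.json` and a run manifest. `hepatree enhance` and
`hepatree skeletonize` expose the earlier stages individually.

## Layout

- `hepatree.phantom` — synthetic tree/liver/tumor phantoms, corruption
- `hepatree.vessel_enhance` — vesselness filter, region growing
- `hepatree.skeletonize` — topology-preserving 3D thinning
- `hepatree.euler` — independent Euler-characteristic / O,H,C counting
- `hepatree.topo_graph` — measured vascular graph
- `hepatree.vessel_tree` — rooting, orientation, cycle resolution
- `hepatree.hierarchy` — radius threshold, subtree split, clustering
- `hepatree.annotate` — voxel classification, report tables, output files
- `hepatree.pipeline`, `hepatree.cli` — orchestration and CLI
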