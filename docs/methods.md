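# Methods

## Problem and model

Atrial fibrillation ablation leaves fibrotic scar in the thin (~2 mm) left
atrial (LA) wall, visible as hyper-enhancement in late gadolinium
enhancement (LGE) MRI. Because clinical interest is in the location and
extent of scar on the atrial surface rather than its transmural geometry,
this package quantifies scar on the endocardial surface: the LA cavity
segmentation is meshed, every mesh vertex becomes a node of a graph whose
edges are the mesh edges, and scar-vs-normal classification is posed as the
binary energy minimization

    E(l) = Σ_i  W_t(i, l_i)  +  λ Σ_{(i,j)∈N}  W_n(i, j) · [l_i ≠ l_j],

a Potts model with learned potentials. The unary (t-link) weight of a node
is the predicted probability that the node is scar, produced by a
convolutional network (T-NET) from the node's multi-scale image patches.
The pairwise (n-link) weight of an edge is a predicted label similarity in
[0, 1], produced by a siamese network (N-NET) from the two nodes' patches
and their geodesic distance. All weights are non-negative, so the energy is
submodular and the global optimum is computed exactly by a two-terminal
max-flow/min-cut (networkx, Boykov–Kolmogorov); correctness is pinned by an
exhaustive-enumeration oracle on small random graphs rather than by trust
in any particular solver.

Completing the energy required two choices the formulation leaves open:

* **t-link encoding** — assigning scar costs `1 − L̂`, assigning normal
  costs `L̂`, linear in the probability (not `−log`), matching the scale on
  which the network is trained (squared error against binary labels).
* **n-link semantics** — the predicted similarity `M̂` is charged only when
  the two labels differ (Potts form): similar neighbors are expensive to
  separate, which is exactly the smoothing the boundary term should supply.

At `λ = 0` the energy decouples and the labeling reduces to thresholding
`L̂` at 0.5; the implementation takes that shortcut (with ties broken
conservatively to normal wall) and the equivalence with the generic solver
is asserted in tests.

## Patches and networks

Each node carries a stack of `N_s` elongated patches (default 13 × 13 × 17
samples) whose long axis is the outward surface normal; scale `s` samples
at `base_spacing · 2^s` mm, so low scales see wall texture and high scales
the surrounding anatomy (blood pool, aorta, right-atrial wall). The
in-plane axes are chosen as the world axis least parallel to the normal,
projected into the tangent plane, and its cross product — keeping patch
orientation as close to the world frame of the image as the normal
constraint allows, so in-plane appearance does not rotate arbitrarily
between neighboring nodes. Samples are trilinear; points outside the
volume read 0. The default single-scale patch flattens to 13·13·17 = 2873
values.

Patch-NET is a stack of 3×3×3 convolutions (stride 1, zero-padding 1) with
ReLU and 2× max-pooling (stride = pool size), ending in a sigmoid feature
vector, one pathway per scale. T-NET concatenates pathway features and
regresses a sigmoid scalar. N-NET applies the shared pathways to both
nodes' stacks, fuses features `F_i, F_j ∈ [0,1]^d` elementwise as

    G_ij = F_i F_j + (1 − F_i)(1 − F_j),

appends the min–max-normalized geodesic distance, and regresses the label
similarity; the fusion makes the prediction exactly symmetric under
swapping the nodes. Channel widths and feature dimension are configuration
(reference build 16/32/64 channels, d = 64); the networks are implemented
directly in numpy (im2col convolutions, manual backpropagation) and
verified against finite differences in the test-suite.

Training targets: `L_i` for nodes (squared loss), and for edges the label
similarity `M_ij = L_i L_j + (1 − L_i)(1 − L_j)`. The optimizer is plain
SGD, momentum 0.9, batch size 50, weight decay 1e-4, learning rate 0.01
with a stepped ×0.8 decay every 1000 updates; 15 epochs for T-NET and 10
for N-NET in the reference configuration. Patch intensities are
standardized by the training-set mean/SD (stored with the checkpoint) —
without it, raw MRI-scale intensities saturate the sigmoid features and
training collapses to the base rate.

Class imbalance is handled by sampling, never in the loss: the node set is
all scar nodes, all scar-boundary nodes (background nodes adjacent to
scar), and an equal-size uniform background sample. Edge samples are the
mesh edges internal to that node set; because dissimilar (M = 0) edges
exist only along the scar boundary, similar edges are subsampled to at
most twice the dissimilar count.

**Random shift.** During training only, each node's patch center is
displaced along its normal by γ ~ U(−R, +R) mm (negative = into the blood
pool), redrawn once per node per epoch, while the label stays fixed. This
teaches the networks to tolerate the patch being centered off the true
wall — the situation an imperfect automatic LA segmentation creates at
test time. R defaults to 8 mm, half the default patch's long-axis extent;
shifts beyond half the patch length can push the wall out of the patch
entirely and destabilize training, so R should scale with the patch if the
patch is changed. At test time R = 0.

## Surfaces, labels, metrics

Meshes come from marching cubes on the binary cavity volume, zero-padded so
surfaces close at the grid boundary. The indicator is Gaussian-smoothed
(σ = 1 voxel) first: meshing a raw binary volume yields staircase facets
whose vertex normals err by tens of degrees, while the smoothed isosurface
of a sphere recovers radius and area to well under a voxel. If the mean
edge length is not below the smallest voxel spacing, one loop-subdivision
pass densifies the mesh beyond image resolution. Vertex normals are
area-weighted face normals with the global sign fixed by the mesh's signed
volume, so orientation is outward regardless of face winding. Geodesic
distances are shortest paths over the edge graph with Euclidean lengths
(Dijkstra on a sparse adjacency), checked against brute-force all-pairs
search on small meshes.

Ground-truth node labels are projected from the voxel scar mask by a
corridor search: node `i` is scar when any voxel within
`v_i + t·n_i, t ∈ [−1 mm, +4 mm]` (half-voxel steps, nearest lookup) is
scar. The outward depth covers the reported wall thickness plus
segmentation error; projection is monotone in the corridor depth.

Evaluation is on surface nodes: Dice of the scar label, accuracy,
sensitivity, specificity (undefined values reported as NaN, not zero), and
the generalized Dice

    GDice = 2 Σ_k |S_k^auto ∩ S_k^manual| / Σ_k (|S_k^auto| + |S_k^manual|)

over both labels. The fully automatic pipeline is scored against ground
truth projected on the automatically segmented surface; baselines
initialized from the manual segmentation are scored on the manual surface.
A correlation report (Pearson, Spearman, OLS R²) relates per-case LA
segmentation Dice to scar Dice.

## Baselines

All operate on a wall mask `dilate(LA, 3 mm) \ LA`:

1. **2SD** — scar = wall voxels strictly above mean + 2·SD of wall
   intensity (population SD). Implicitly assumes scar is a sparse upper
   tail; with large scar burden the threshold can exceed every voxel.
2. **Otsu** — 256-bin between-class-variance threshold of wall intensities.
3. **MGMM** — a hand-written EM fit of a two-class mixture (default 3
   normal + 2 scar components, quantile-initialized with scar components on
   the enhanced tail); scar posterior = summed scar-component
   responsibilities. Variances are floored at 1e-6 of the data variance;
   log-likelihood is recorded per iteration and must not decrease. The
   K = 1 + 1 case is cross-checked against an independent mixture
   implementation in the tests.
4. **MGMM + GC** — graph cuts on the 6-connected wall-voxel grid with
   posterior t-links and n-links `exp(−ΔI²/2σ²)`, σ defaulting to the wall
   intensity SD; solved by the same exact min-cut.

## Synthetic phantoms

No imaging data ships with the package; every experiment runs on generated
LGE-like phantoms. A phantom is a spherical cavity with a smooth low-order
spherical-harmonic radial deformation (bands ≤ 4, default ±8%), a wall of
constant thickness (default 2 mm — the clinically reported LA mean), and
scar as angular caps around random wall directions, grown to a target
fraction of the wall (default 25%, realized by a quantile rule so batches
land on target). Intensities are piecewise constant (blood 100, wall 60,
scar 160, background 10) with three realism terms, each independently
switchable:

* **heterogeneous enhancement** — each scar patch draws its own mean
  (SD 25, floored at 30% of the nominal scar-wall contrast above the
  wall). Uniformly bright scar makes a global threshold Bayes-optimal and
  the method comparison vacuous; heterogeneity is what actually
  distinguishes local learning from global thresholds in LGE.
* **confounders** — an aorta-like tube and an RA-wall-like shell segment,
  enhanced at the scar mean, by default 0.5 mm from the epicardium, where
  they contaminate any dilation-derived wall mask.
* **bias field, blur, noise** — a smooth additive bias (default off; the
  smoke configurations use 15% of the wall mean, emulating surface-coil
  shading), Gaussian PSF blur (smoke: 2 mm FWHM, which creates the
  partial-volume mixing that makes thin walls hard), and Gaussian or
  Rician noise.

The "automatic" LA segmentation is simulated by displacing the true
cavity's signed distance by a Gaussian-filtered random field scaled to a
maximum amplitude `seg_error_mm` (default 2 mm; the signed distance gets a
half-voxel correction so sub-voxel displacements act at all). The output
is kept a single filled component, and the LA Dice between the true and
perturbed cavity decreases monotonically with the error amplitude.

What the phantoms do **not** emulate: real LA anatomy (pulmonary veins,
appendage, mitral valve opening), inversion-recovery physics, respiratory
motion, anisotropic clinical voxels, or anatomically varying wall
thickness. Passing the phantom suite therefore demonstrates the mechanics
and the relative behavior of the methods under controlled difficulty, not
clinical-grade accuracy.

## Problem sizes

Unit tests use 36–48³ grids and sub-200-node meshes. The integrative
experiments (the reproduction script and the heavier tests) use the
presets in `learngc.presets`: 48³ phantoms at 1.25 mm, ~2–7 k surface
nodes, 7 × 7 × 9 two-scale patches with R = 4 mm for the end-to-end
comparison (3 train / 3 test phantoms, 15/6 epochs), and 7 × 7 × 13
single-scale patches with a single training phantom for the random-shift
study — the data-scarce regime where shift augmentation has something to
add, with the patch long axis (~16 mm) chosen so an 8 mm shift stays
within half the patch length. The full-scale configuration
(`reference_experiment`: 13 × 13 × 17 patches, three scales, R = 8 mm,
16/32/64 channels) is provided for larger machines.

## Known limitations

* N-NET learns slowly on phantom edges (adjacent patches overlap almost
  entirely), so at smoke scale its similarity is close to uniform and the
  boundary term acts mainly as generic smoothing.
* The numpy networks are CPU-bound and single-threaded; the reference
  configuration is impractical to train at desk scale.
* Min-cut via networkx is exact but allocates a Python graph; meshes
  beyond ~10⁵ nodes would need a C max-flow backend.
* The corridor projection parameterizes an operation whose clinical
  counterpart (how a physician's voxel labels map to the surface) has no
  single canonical definition; depths are configurable.
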