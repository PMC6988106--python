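# learngc

Fully automatic quantification of left-atrial (LA) scar from late
gadolinium enhancement (LGE) MRI, for researchers studying atrial
fibrillation ablation outcomes. Instead of segmenting scar in the volume —
hard, because the atrial wall is ~2 mm thin and surrounded by other
enhanced structures — the LA endocardium is projected onto a surface mesh
and scar is classified per mesh node by exactly minimizing a graph-cuts
energy whose potentials are *learned*:

    E(l) = Σ_i W_t(i, l_i) + λ Σ_{(i,j)∈N} W_n(i,j) · [l_i ≠ l_j]

* **t-links** `W_t`: a multi-scale patch CNN (T-NET) predicts each node's
  scar probability `L̂` from elongated, normal-oriented intensity patches
  (default 13 × 13 × 17 samples, three scales); assigning scar costs
  `1 − L̂`, normal wall costs `L̂`.
* **n-links** `W_n`: a siamese network (N-NET) predicts the label
  similarity `M̂ ∈ [0,1]` of two neighboring nodes from their patch stacks
  and geodesic distance, charged only when their labels differ (Potts).
* Training uses balanced node sampling and a **random shift**: patch
  centers are displaced along the surface normal by γ ~ U(−R, +R)
  (default R = 8 mm), making the networks robust to the few-mm errors of
  an automatic LA segmentation.

The energy is submodular, so the labeling is the exact global optimum via
max-flow/min-cut. Classical baselines (mean + 2SD thresholding, Otsu,
multi-component Gaussian mixture EM, and GMM + voxel graph-cuts), surface
evaluation metrics (Dice, generalized Dice, accuracy,
sensitivity/specificity, correlation analysis), and a synthetic LGE-MRI
phantom generator complete the package, so the entire pipeline runs and is
tested without any clinical data. See `docs/methods.md` for the model,
parameter and phantom details.

## Worked example

```python
from learngc.presets import smoke_experiment
from learngc.pipeline import run_pipeline

cfg = smoke_experiment(seed=0)       # 48³ phantoms, 3 train / 3 test
cfg.baselines = ("2sd", "otsu")
print(run_pipeline(cfg).summary.to_string())
```

prints (about 90 s on one CPU):

```
    method  dice_scar_mean  dice_scar_sd  gdice_mean  accuracy_mean  n_cases
0      2sd        0.613412      0.019126    0.852552       0.852552        3
1  learngc        0.928924      0.030613    0.962021       0.962021        3
2     otsu        0.916963      0.047556    0.951561       0.951561        3
```

Each row is one method's surface-node performance averaged over the test
phantoms: `dice_scar_mean` is the overlap of predicted and ground-truth
scar nodes (1.0 = perfect), `gdice_mean` weighs both the scar and
normal-wall labels, and `accuracy_mean` is the fraction of correctly
labeled nodes. On these phantoms — heterogeneous scar enhancement, a
shading field, blur, noise, and enhanced confounders touching the wall —
the learned pipeline (`learngc`), although it starts from an imperfect
*automatic* LA segmentation, beats both thresholding baselines that use
the perfect manual segmentation; fixed 2SD thresholding misses most of
the strongly enhanced scar burden.

A command-line interface mirrors the library (`learngc phantom / train /
predict / baseline / eval / study`); volumes are NIfTI, meshes PLY or VTK
polydata with per-node labels, tables CSV.

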