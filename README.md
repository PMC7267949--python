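# priorseg

Spatial-prior-augmented 3D fully convolutional segmentation of structures in
volumetric images that are linearly registered to a common space — the
setting of neuroanatomical segmentation (hippocampi, subcortical structures)
in T1-weighted MRI.

## The problem and the method

A patch-based 3D network sees only a small cube of intensities, so two
mirrored structures with identical appearance (left vs right hippocampus)
are indistinguishable from inside a patch: prior-free baselines scatter
left/right confusions across hemispheres. `priorseg` implements a 3D fully
convolutional network combined with two registration-derived spatial priors
that close this gap at negligible cost:

* **Coordinate channels** — three extra input channels whose values at voxel
  (x, y, z) are simply x, y and z (rescaled to [−1, 1] by default), giving
  every voxel of a patch explicit location awareness.
* **Working volumes** — per structure c, the dilated union-minus-intersection
  of the training subjects' masks, `B^c = D ⊕ (U^c − I^c)`, marks where
  subjects disagree; training samples and test tiles are restricted to
  `B = ∪_c B^c`, while the certain interior `P^c = I^c − (I^c ∩ B^c)` is
  labeled c directly, without network evaluation.

The network itself: `depth` (8) unpadded 3×3×3 convolutions (ELU, `width` =
32 filters) shrink a 25³ patch to 9³; a dense connection concatenates the
centrally cropped feature maps of every layer; batch norm, two 1×1×1 layers
(128/64, dropout 0.1) and a softmax classifier produce per-voxel class
probabilities. Training minimizes `J + α‖W‖²` (categorical cross-entropy +
l2 on filters, α = 1e−4) by RMSProp with Nesterov momentum on class-balanced
patches sampled inside B, with on-the-fly random elastic deformations
(U(−1,1) field, Gaussian-smoothed with σ_e = 4 mm, normalized to unit mean
displacement, scaled by α_i = 2 mm) and early stopping on a fixed
uniformly-sampled validation set. Inference slides the network at stride 4,
averages overlapping probability tiles, merges with the positive volumes and
keeps the largest connected component per class. Accuracy is reported as
Dice (%) and modified Hausdorff distance (mm).

The network, its backpropagation and the optimizer are implemented in numpy
(no deep-learning framework dependency); gradients are verified against
finite differences in the test suite. A synthetic phantom generator produces
cohorts of mirrored-structure head phantoms so every stage is testable
without any dataset. See `docs/methods.md` for the full model description
and design choices.

## Worked example

Train the spatial-prior network on a small phantom cohort and evaluate on
held-out subjects (a few minutes on one CPU core):

```python
from priorseg import PhantomConfig, generate_cohort, SpatialPriorNet
from priorseg.training import TrainConfig
from priorseg.inference import InferenceConfig

cohort = generate_cohort(PhantomConfig(grid_side=48, seed=7), 12)
train, test = cohort[:9], cohort[9:]

model = SpatialPriorNet(
    train,
    width=8,
    train_config=TrainConfig(voxels_per_iteration=120, batch_size=32,
                             max_iterations=30, patience=30,
                             validation_patches_per_subject=32, seed=0),
    inference_config=InferenceConfig(stride=4, batch_size=64),
)
results = model.fit()
print(results.summary())
print(results.evaluate(test).summary())
```

prints

```
Spatial-prior 3D FCN segmentation
=================================
architecture        depth 8 x width 8, 4 input channel(s), 3 classes
parameters          29,923
spatial priors      coordinates, working volume
augmentation        off
iterations run      30
best val loss       0.0350 at iteration 28
final train loss    0.0801

structure  dice_mean  dice_sd  mhd_mean  mhd_sd
        1      94.88     0.82     0.066   0.015
        2      94.78     0.75     0.077   0.011
overall mean Dice = 94.83%  mean MHD = 0.071 mm
```

Structures 1 and 2 are the left and right members of the mirrored pair; a
mean Dice near 95% with sub-0.1 mm MHD says the network resolves the
hemispheres (which share identical intensity statistics) and recovers the
boundaries to about a tenth of a voxel of mean surface error on this easy
synthetic anatomy. `SpatialPriorNet.from_variant(subjects, "CNN-B")`,
`"CNN-SC"`, `"CNN-WV"`, `"CNN-SP"`, `"CNN-SP-D"` (optionally `"+DA"`)
construct the ablation arms: baseline, coordinates only, working volume
only, both priors, the depth-16 variant, and elastic-deformation
augmentation.

## Command line

Every stage is also a subcommand of `priorseg`, configured by one YAML file
(see `priorseg.config`):

```sh
priorseg make-phantoms --config c.yaml --n 20 --out cohort/
priorseg build-priors  --labels cohort/ --out priors/
priorseg train         --config c.yaml --images cohort/ --out run/
priorseg segment       --model run/best.npz --image s.nii.gz --priors run/priors --out seg.nii.gz
priorseg evaluate      --pred preds/ --ref cohort/ --out report.csv
priorseg crossval | ablation | reliability ...
```

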