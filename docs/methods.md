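# Methods

## The segmentation problem

`priorseg` segments anatomically regular, lateralized structures (the
motivating case is left/right hippocampi and other subcortical structures in
T1-weighted MRI) in 3D scalar volumes that have already been linearly
registered to a common space with ~1 mm isotropic voxels. In that setting a
patch-based classifier faces a specific failure mode: mirrored structures
have identical local appearance, so nothing inside a small patch says which
hemisphere it came from. The method addresses this with two cheap,
registration-derived spatial priors around a 3D fully convolutional network.

## Network

The network maps a multichannel cubic patch to a dense probabilistic label
estimate for its central cube:

* `depth` (default 8) unpadded 3×3×3 convolutions with `width` (default 32)
  filters and ELU activations. Each valid convolution trims one voxel per
  face, so the output side is `input − 2·depth`; with depth 8 a 25³ patch
  yields a 9³ output. Deep variants add two voxels of input per extra layer
  (depth 16 → 41³ input).
* a dense connection: the outputs of all conv layers, centrally cropped to
  the final 9³, are concatenated channel-wise (depth×width channels), giving
  the classifier simultaneous access to high-resolution early features and
  abstract deep features;
* batch normalization of the concatenated maps (ε = 1e−5, running-statistics
  momentum 0.9, inference uses running statistics);
* two 1×1×1 convolutions (128 and 64 filters, ELU, dropout p = 0.1 after
  each, training mode only) and a 1×1×1 classifier with a per-voxel softmax
  over the C classes.

Filters are Glorot-uniform initialized (seeded); biases start at zero. The
depth-8/width-32 network with N = 4 input channels and C = 3 classes has
exactly 239,107 parameters by the layer-by-layer count.

The training loss is `L = J + α‖W‖²` with J the categorical cross-entropy
averaged over batch and output voxels (probabilities clipped to
[1e−7, 1−1e−7] before the log) and α = 1e−4 penalizing convolution filters
only — biases and batch-norm parameters are exempt.

Because no deep-learning framework is a dependency, the network is a compact
numpy implementation (`priorseg.nn`). Convolutions are evaluated as 27
accumulating GEMMs, one per filter offset; the backward pass was verified
against central finite differences to ~1e−7 relative error (float64), and a
test keeps that check in the suite. All tensors are float32 in normal use.

## Spatial priors

*Coordinate channels.* Three extra input channels hold every voxel's
(x, y, z) position in the common space, so each voxel of a patch carries its
own location. By default positions are linearly rescaled per axis to [−1, 1]
over the grid; raw voxel indices are available by configuration. The
rescaling is an invertible affine map, so no information is lost, and it
keeps the channel magnitudes commensurate with the z-scored appearance
channel. Coordinate channels are *not* per-patch normalized — their absolute
values are the point.

*Working and positive volumes.* For each class c the training subjects'
masks M_i give the union U^c and intersection I^c. The working volume
`B^c = D ⊕ (U^c − I^c)` (one binary dilation with the full 3×3×3 element D)
marks where subjects disagree — the only region where the class boundary is
uncertain. The positive volume `P^c = I^c − (I^c ∩ B^c)` is certain interior
and is labeled c at test time without running the network. The global
working volume `B = ∪_c B^c` is where all training samples are drawn and all
test tiles are evaluated; everything outside `B ∪ P` is background by
construction. Priors are computed from all non-test subjects (training and
validation alike), since validation patches are also drawn inside B and no
test information is involved.

## Elastic deformation augmentation

Each training sample is warped on the fly by its own random field: i.i.d.
U(−1,1) per voxel and direction, Gaussian-smoothed per axis with SD σ_e
(default 4 mm; separable kernel truncated at 4σ), globally rescaled so the
mean Euclidean displacement per voxel is exactly 1, then scaled by α_i
(default 2 mm). "Mean per-voxel displacement" is read as the mean vector
magnitude, and σ_e/α_i are mm converted to voxels via the voxel size. The
same field warps the appearance channel, the three coordinate channels and
the one-hot label target (trilinear interpolation, edge clamping); warped
label channels are renormalized to sum to one per voxel — interpolation
already preserves the sum except where edge clamping intervenes — and the
resulting soft boundaries act as mild label smoothing. α_i = 0 is exactly
the identity. Fields are sampled at patch size. Rotations and flips are
deliberately absent: for linearly registered images they would create
implausible samples.

## Training

Per iteration, ~`voxels_per_iteration` centers are sampled: an equal share
per training subject and, within a subject, an equal number per class
(background included) from the class's voxels inside B, with replacement
when a stratum is small (quota = floor(v/(n·C)); a class absent from every
subject's region is an error, a subject merely missing a stratum is
skipped). Appearance patches are individually normalized to zero mean/unit
SD; samples are augmented, shuffled and consumed in minibatches of B
(default 128) by RMSProp (decay 0.9, ε = 1e−6) composed with Nesterov
momentum 0.9, at a static learning rate 2.5e−4. A fixed validation set —
drawn uniformly (no class balancing, so its class mix approximates B's) from
the held-out 20% validation subjects before training — is evaluated after
every iteration; training stops when the lowest validation cross-entropy
has not improved for `patience` (default 30) iterations, and the returned
weights are those of the argmin-validation iteration.

"Iteration" means one outer cycle (sample → minibatch steps → one validation
evaluation). RMSProp's decay/ε, the batch-norm constants and the validation
set size are package choices where the method description is silent.

## Inference

Output tiles (9³) are planned on a regular stride-4 grid from the working
volume's bounding box minimum, with the final tile per axis placed so the
box is reached (tile centers clamped into the volume); every voxel of B is
covered for any stride ≤ 9. Tile probabilities are overlap-averaged
(probabilities, not logits), argmaxed inside B (ties → lowest class index),
overridden by the positive volumes, and everything else is background. The
optional postprocessing keeps the largest 26-connected component per class
(6-connectivity configurable; the connectivity choice is not pinned down by
the method description, 26 is conservative against splitting thin diagonal
structures). Patches at volume borders are zero-filled, which after
per-patch normalization equals the patch mean; the border policy is a
package choice.

## Evaluation

Dice is reported in percent; two empty masks score 100 (with a warning), one
empty mask scores 0. The modified Hausdorff distance is
`max(h(A,R), h(R,A))` with h the mean over *all* labeled voxels (not only
boundary voxels — the literal reading of the definition) of the Euclidean
distance to the nearest voxel of the other mask, in mm via an exact distance
transform; it is undefined (an error, or a flagged NaN in reports) for empty
masks. Label median filtering (for noisy manual references) takes the modal
label of each edge-truncated 3×3×3 neighborhood, ties retaining the original
label; it is a fixed point on flat boundaries but keeps shaving convex
corners on repeated application, so it is applied once.

## Phantom cohorts

The synthetic cohort generator provides the study conditions without any
data download. Each subject is a head ellipsoid (intensity 40) on background
0 containing mirrored superellipsoid structure pairs (intensity 60, exponent
2.5, default radius 6 mm) placed symmetrically about the grid mid-plane;
intensities follow a 0–100 scale with additive Gaussian noise (SD 5),
echoing a ~20-unit structure/tissue contrast after linear intensity
normalization. Left and right structures are exact mirror images with
identical intensity statistics — hemisphere is distinguishable only by
location, reproducing the condition under which a prior-free patch network
confuses sides. Per-subject anatomical variability is a smooth random
deformation from the same elastic field sampler used for augmentation
(σ = 6 mm, mean displacement 3 mm — a plausible residual after linear
registration); labels are the warped noise-free masks, so they are exact.
A subject whose structures would leave the head is regenerated with a fresh
sub-seed (at most 10 attempts). Cohorts are bit-identically reproducible
from (config, subject index), and scan–rescan pairs are two noise
realizations of one anatomy.

What the phantoms do **not** emulate: MRI physics (bias fields, partial
volume beyond trilinear blur), multi-contrast acquisition, registration
failures, or anatomically realistic structure shapes. Passing tests on
phantoms therefore demonstrate the machinery and the direction of the
prior's benefit, not clinical-grade accuracy.

## Scaled-down reference experiment

`priorseg.workflow.scaled_down_ablation` (also run by
`scripts/acceptance.py`) trains CNN-B (no priors) and CNN-SP (both priors)
with shared seeds on one split of a 14-subject, 48³ phantom cohort (10
non-test subjects, of which 2 are validation; 4 test subjects) and compares
Dice/MHD with and without postprocessing plus the number of lateral
confusion components (a connected component of a predicted structure that
touches the reference territory of its mirror partner but not its own). To
keep the experiment minutes-scale on one CPU core the package uses width 8,
~120 balanced voxels per iteration, minibatches of 32, at most 30 iterations
with patience 8, and 32 validation patches per subject — the phantom task is
far easier than clinical segmentation and converges within a handful of
iterations, so the full-scale settings (width 32, ~2000 voxels, batch 128,
patience 30) would be idle capacity here. They remain the defaults for real
use.

## Known limitations

* CPU-bound numpy training is orders of magnitude slower than the GPU
  setting the method was designed for; the full-scale defaults are
  impractical without acceleration.
* The prior-free baseline's training region ("whole grid") and the
  components' connectivity are package choices where the method description
  is silent.
* Working volumes assume reasonable linear registration; a failed
  registration would invalidate both priors (by design).
* MHD uses all mask voxels, so its absolute values are small for large
  overlapping masks; comparisons should stay within one convention.
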