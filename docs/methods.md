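# Methods

## The model

`mvsir` segments a lung nodule in 3D by classifying every voxel of a
*nodule cube* — the isotropically resampled sub-volume containing the
nodule plus a 10-voxel pad on all six faces — as nodule or background.
Each voxel is described by six 30×30 patches: an intensity window (**VH**,
voxel heterogeneity) and a binary ROI window (**SH**, shape heterogeneity)
in each of the axial, coronal and sagittal planes through the voxel.  SH is
rasterized from reader-drawn contours, so prediction is semi-automatic: an
outline of the nodule must exist, and the network refines it into a
voxel-accurate 3D mask.

Each patch pair feeds one **SIR submodel**:

| stage | operation | output |
|---|---|---|
| C1 | 3×3 conv, 32 kernels, ReLU | 30×30×32 |
| P2 | 2×2 max pool, stride 2 | 15×15×32 |
| RB1 | identity residual block (1×1 valid → 3×3 same → 1×1 valid, +skip, ReLU) | 15×15×32 |
| EC1+EP2 | secondary input: the same patch through one conv + pool | 15×15×32 |
| concat | channel concatenation | 15×15×64 |
| P3 | 2×2 max pool, stride 2, ceil | 8×8×64 |
| C4 | 3×3 conv, 128 kernels, ReLU | 8×8×128 |
| RB2 | identity residual block | 8×8×128 |
| P5 | 2×2 max pool, stride 1, shape-preserving | 8×8×128 |
| F7, F8 | dense 256, dense 256 | 256 |

The six 256-vectors are concatenated (1536), passed through a 256-wide
fusion layer, and a single sigmoid neuron emits the nodule probability
δ(z) = 1/(1+e^−z).  Training minimises mean binary cross-entropy with
Adam.  Two ablation variants remove the named mechanisms: **MV-I-CNN**
drops the secondary-input path, **MV-CNN** additionally replaces each
residual block with a single 3×3 convolution of matched depth; parameter
counts nest (MV-CNN < MV-I-CNN < MV-SIR).

The layers themselves (stride-1 convolution via im2col, max pooling, dense,
ReLU, Adam, backpropagation) are implemented in NumPy (`mvsir.nn`), in
float32, with a float64 mode used by the finite-difference gradient tests.
Two numerical conventions worth noting: pooling gradients at exactly tied
maxima are split uniformly among the tied entries (a valid subgradient;
ties occur with ReLU zeros), and P3 uses ceil semantics (15 → 8) while P5
is stride-1 same-padded — the only ordering consistent with the stage
sizes above.

## Geometry conventions

Axis order is (z, y, x), 0-based, voxel centres at integer coordinates.
The inside test everywhere is ray casting in +x with a half-open edge rule
([y_low, y_high) per edge), so a ray through a vertex is counted once;
points on the polygon boundary count as inside (the reader outline is read
inclusively).  Contour rasterization, voxel labeling, and consensus
building all share this single geometry definition, which is why a
classifier stub that reads the ROI reproduces the ground truth exactly
(Dice 1) when the pipeline is run with stride 1.

Multi-reader fusion is a per-voxel majority vote: a voxel is consensus
positive when at least half the readers' rasterized contours cover it
(ties toward inclusion).  The published description ("the average results
of the four radiologists") does not define the averaging operator; majority
is symmetric, well defined for any reader count, and reduces to any single
reader under unanimity.

Resampling to 1 mm isotropic voxels uses trilinear interpolation with the
extent-preserving size rule `round(n·s_in/s_out)` per axis.

## The phantom

The synthetic generator produces the study conditions for every test: a
star-convex "bumpy ellipsoid" nodule of raised intensity in a uniform
background with i.i.d. Gaussian noise, plus per-reader slice contours whose
vertices sit exactly on the analytic boundary, radially jittered per vertex
to emulate inter-reader variability.  Defaults model a small solid nodule
in lung parenchyma: semi-axes (1.8, 6.0, 5.5) mm (three annotated axial
slices), bumpiness 0.12, contrast 40 − (−800) = 840 HU, noise σ = 20 HU,
four readers with 0.3 mm jitter, 64 contour vertices, on a 39×63×63 grid of
1 mm voxels.  The ground-truth mask is the rasterization of the noiseless
contours (identical to the analytic predicate up to a sub-voxel boundary
sliver; the package treats the rasterization as truth so that geometry,
labels and evaluation are mutually consistent).

What the phantom does **not** model: lung anatomy (vessels, pleura,
airways), attachment, spiculation, partial-volume blur, scanner noise
texture, or reader disagreement beyond radial jitter.  Passing tests
demonstrate that the pipeline and model recover a known shape under
controlled contrast and noise — not clinical performance.

## Sampling

Training centres are drawn per annotated slice: `per_slice_n` centres with
a balanced positive fraction (positives from the nodule on that slice,
without replacement while the pool suffices).  Negatives come from the
expansion (non-nodule) part of the cube; by default half are drawn from the
centre's own slice and half from the whole cube, so both the in-plane
surroundings and the pad region (including off-nodule slices) are
represented in training — the whole padded cube is the prediction domain at
test time.  Everything is deterministic given the plan seed.

## Scale presets

Every numeric constant is a named configuration field.  Two presets:

* **paper**: 4000 centres/slice, batch 2000, 100 epochs, learning rate
  1e-4, weight decay 0.01, 10 % validation split, no VH normalisation,
  stride 1.  These are the published settings; at this scale training needs
  GPU-class hardware.
* **desk** (default): 200 centres/slice, batch 64, 10 epochs, learning rate
  1e-3, VH min-max normalised to [0, 1] per cube, stride 1.  Sized for a
  single CPU (minutes, not hours).  The larger learning rate compensates
  for having ~100 optimizer steps instead of hundreds of thousands; the
  normalisation keeps He-initialised activations in range given HU-scale
  inputs (the published work does not state a normalisation; the option
  exists precisely because small-sample training is sensitive to it).

"Weight decay 0.01" is ambiguous in the source framework; it is
implemented as an L2 penalty coefficient added to the gradient, with a
learning-rate-decay alternative behind `training.decay_mode = "lr"`.

## Inference and thresholding

Prediction scores every cube voxel (a stride, scalar or per-axis, may
evaluate a subgrid with nearest-neighbour fill as a further desk-scale
shortcut; scored voxels are recorded).  The confidence volume is
binarized at the ROC *optimal threshold* — the sweep point closest to the
upper-left corner, argmin √(FPR² + (1−TPR)²), ties to the lower
threshold — computed against the reference mask, exactly the published
threshold-selection procedure.  SH patches at inference come from the
provided consensus ROI (semi-automatic protocol); a two-pass
SH-from-prediction mode is deliberately out of scope.

## Evaluation

Dice, PPV and SEN are voxel-count ratios (conventions: both masks empty →
Dice 1; an empty segmentation reports PPV 0 with a flag rather than
failing a batch).  HSD and ASD operate on boundary point sets — mask
voxels with at least one of six face-neighbours outside, the volume border
counting as outside — with coordinates scaled by the voxel spacing, so
both are in millimetres (sub-voxel ASD values are only meaningful in
physical units).  ASD is the half-sum of the two directed mean nearest
distances; HSD the symmetric maximum.  Nearest distances use a k-d tree;
tests verify both against all-pairs brute force.

## Problem sizes used by the test suite and acceptance script

The end-to-end learned check runs the desk preset on the easy condition of
the default phantom — geometry, contrast and sampling unchanged, noise
σ = 5 HU, jitter-free readers — giving 3 annotated slices → 600 training
centres and a ~23×31×33 cube ≈ 24k voxels scored at stride 1.  Residual
error at this scale is a soft ~1-voxel band at the nodule surface (see
Known limitations), which for a three-slice nodule is the dominant Dice
term.  The ablation sweep runs all three variants at a
further reduced scale (100 centres/slice, 6 epochs, stride (1,2,2)): it
demonstrates the harness and emits the five-metric comparison table; at
this scale the ordering among variants is noise, which is why no ordering
is asserted anywhere.  The paper-scale patch accounting check (4000
centres/slice, 6 streams per centre) runs sampling and extraction only, no
training.

## Known limitations

* Desk-scale training sees ~2.5 % of the cube's voxels; the learned
  decision boundary is soft within ~1 voxel of the nodule surface, which
  is where almost all residual error lives (the upper-left ROC rule keeps
  sensitivity at 1 at some cost in precision there).
* Bit-exact reproducibility is guaranteed for sampling, patches and
  phantom artifacts; trained weights are reproducible on the same
  BLAS/thread configuration (floating-point reduction order is not
  controlled across libraries).
* The MV-CNN / MV-I-CNN variants are ablations of the two named
  mechanisms, not reconstructions of any external baseline.
* Whole-scan detection, DICOM ingestion, augmentation and post-processing
  (CRF, morphology) are out of scope.
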