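# Methods

## Model

The segmenter refines per-slice evidence with inter-slice context.  Its
input for one target slice is a window of N (image, attention-map)
pairs, N odd, centred on the target (default N = 5; 3 and 7 are
supported).  The attention map is a soft foreground probability in
[0, 1] produced by a separately trained 2D backbone; image and map are
stacked as a 2-channel input.  Window positions beyond the volume ends
are filled by replicating the edge slice (default) or by reflection,
and flagged as padding.  Replication is the default because reflection
fabricates reversed anatomy at the volume ends.

Per frame, two residual blocks (3×3 Conv → BN → ReLU → 3×3 Conv → BN,
ReLU-capped skip; 1×1 projection when the channel count changes)
extract 64-channel features.  A convolutional LSTM with 128 filters per
gate processes the frame sequence forward, a second one backward; the
backward outputs are re-reversed so both directions describe the same
position, then fused.  Concatenation is the default fusion — the final
64-filter convolution absorbs the doubled channels — and elementwise
sum is retained, which also makes the direction-swap symmetry testable:
with sum fusion, reversing the sequence and swapping the two parameter
sets provably reverses the outputs.  A 3×3 convolution to 64 channels,
ReLU, and a 1×1 convolution produce the single-channel logit map;
a sigmoid gives probabilities and `p >= 0.5` the mask (ties go to
foreground, fixed for reproducibility).  By default only the centre
position is decoded (`output_scope="target_slice"`); whole-volume
inference slides the window so every slice is the target exactly once.

ConvLSTM gates use the peephole (cell-to-gate Hadamard) formulation;
peepholes are on by default and toggleable, since published ConvLSTM
configurations differ on this point.  Peephole weights are per-channel.
The forget-gate bias initializes to 1 to keep early cell memory open;
other biases start at zero, kernels are He-normal.  Cell state H is
bounded in (−1, 1) by construction (σ and tanh bounds).

## Losses and optimization

Focal loss, mean-reduced over pixels, with p clamped to
[1e−7, 1 − 1e−7] before the logarithm for numerical stability.
Defaults α = 0.25, γ = 2 (the standard focal-loss setting); training
scripts that overfit small phantoms use α = 0.75 to upweight the
minority foreground.  At γ = 0, α = 0.5 the loss reduces to half the
binary cross-entropy — a closed form the tests exploit.  Optimization
is plain SGD (momentum 0.9 available), learning rate 0.005 for the
head and 0.0001 for the backbone by default.  All training loops are
deterministic given their seed.

## Attention backbone

Two providers honor one contract — a 2D map in [0, 1], clamped, the
same H×W as the slice:

* **SingleInstanceDetector**: a detection-style network with the three
  canonical branches (classification score, box regression, dense
  mask) over a shared convolutional trunk, trained with a multi-task
  sum (BCE on the score, squared error on the normalized tight GT box,
  focal loss on the mask).  At inference the soft mask of the single
  highest-scoring detection is pasted into full-image coordinates,
  zeros elsewhere; a score below the threshold yields an all-zero map
  — not an error.  One detection at most is emitted because the
  segmentation target is a single thrombus instance per volume.
  `DetectorConfig` records the reference detection configuration
  (50-layer residual backbone name, three anchor scales, three aspect
  ratios, RoI output size, 1024-wide head) and is validated and
  serialized; anchor enumeration and region-proposal machinery are
  deliberately out of scope at desk scale.
* **LightweightBackbone**: a same-resolution convolutional
  encoder–decoder (8/16/8 channels, 1×1 output) yielding a dense
  foreground probability; trains on a CPU in seconds and is the
  default provider in tests and examples.

The pipeline is two-stage: the backbone is trained first, its maps are
cached on disk keyed by (study, slice), and the head trains on the
cached maps.  Soft (probability) maps are passed downstream rather
than binarized ones; calibrated scores carry more information for the
refinement stage, and a binarize-at-0.5 view is trivially available.

## Synthetic phantom

Each study renders an elliptical body of soft tissue (mean 110 on the
8-bit scale, smooth low-frequency texture ±10), a bright circular
contrast-filled lumen (240), and an annular thrombus (150) around it
whose outer boundary is perturbed by fixed per-study radial harmonics
(orders 2–5, total relative amplitude 0.15).  `tissue_overlap` ∈ [0, 1]
scales the std of per-pixel Gaussian jitter on thrombus intensities as
a fraction of the thrombus–tissue gap: 0 gives perfectly separable
classes; larger values push the distributions together, and the
band-threshold oracle's Dice decreases monotonically — the generator's
difficulty knob.  Optional stent streaks (thin full-brightness line
segments through the sac, 2 by default) and additive Gaussian noise
(σ = 5) complete the slice.  GT masks mark exactly the generated
annulus pixels before noise and artifacts.  The sac centre drifts per
slice by at most `center_drift` px (uniform step in a disc of 0.9×
that bound, clamped to keep the sac inside the image), giving the
inter-slice coherence the sequence model exploits; the boundary shape
is frozen per study so consecutive GT centroid displacement stays
within the bound after rasterization.

Defaults (64 px frame): lumen radius 5–8 px, thrombus thickness
4–8 px, drift 2 px, overlap 0.3, stents on, noise σ = 5, spacing
0.8 mm.  `PhantomParams.for_size` scales the geometry proportionally
(tests use 16–32 px, demos 256).  Cohorts derive per-study seeds
counter-style via `SeedSequence([cohort_seed, index])`, so a cohort is
reproducible from (params, seed) regardless of generation order.

What the phantom does *not* emulate: CT reconstruction physics, beam
hardening, HU calibration, anatomical variability beyond the sac, or
multiple thrombus instances.  Passing tests therefore demonstrate that
the machinery learns and exploits volumetric coherence under the
stated difficulty factors — not clinical-grade performance.

## Metrics and protocol

For prediction A and ground truth B: TO = |A∩B|/|B|, Dice =
2|A∩B|/(|A|+|B|), Jaccard = |A∩B|/|A∪B|, FN = |B∖A|/|B|, FP =
|A∖B|/|A|.  TO + FN = 1 identically, and Dice = 2J/(1+J).  The FP
denominator is the prediction by convention here; |B| is available
behind a flag, since published aggregates do not pin it down.  Empty
prediction: TO = Dice = Jaccard = 0, FN = 1, FP = 0 (the FP
denominator would be zero).  Empty GT is an error — the protocol
excludes slices without a thrombus ROI before evaluation, mirroring
the data-preparation rule.  Aggregation is the unweighted mean over
slices → studies → folds → overall, so large volumes do not dominate
patient-level summaries.  Cross-validation splits by patient study:
seeded shuffle, contiguous partition into k test sets of size
⌊n/k⌋/⌈n/k⌉; with 60 studies and k = 4 each fold trains on 45 and
tests on 15, and every study is tested exactly once.

## Augmentation

Elastic deformation (uniform random field smoothed by a Gaussian,
σ = 4 px, magnitude 8 px at 64×64 — scale-proportional and visually
mild) and rotation within ±10°.  One transform per call is applied to
image and mask together (linear vs nearest-neighbour interpolation, so
masks stay binary).  Sequence-level augmentation applies a single
transform to all N pairs and the GT, preserving the coherence the
model learns; attention maps are warped alongside their slices, the
cheap and consistent choice in a two-stage pipeline.  Augmentation is
applied on the fly during head training, reseeded from the training
stream, rather than by pre-expanding the dataset.

## Numerical and engineering choices

The neural layers run on a small reverse-mode autograd core written
for this package (float64 NumPy; stride-1 same-padding im2col
convolution; gradients verified against central finite differences to
~1e−10 in the test suite).  8-bit rescaling of input volumes is a
linear map of the full range — per-volume min/max by default, a fixed
range optionally — with round-half-to-even; a constant volume maps to
zeros rather than erroring so degenerate synthetic inputs cannot abort
a pipeline.  Coordinates are 0-based (row, col); bounding boxes are
inclusive at both ends; box fitting uses 8-connected components, one
box per instance by default.  BatchNorm uses standard train/eval mode
switching with running statistics.  Checkpoints are single .npz
archives holding all parameter tensors, the architecture config and a
format version.

## Problem sizes

Tests and the acceptance script run the method at deliberately small
scales chosen for a single CPU: 16×16 phantoms for workflow checks,
32×32 for overfit demonstrations (2 studies × 6 slices, 500 head
steps), 1000 random 16×16 mask pairs for metric identities, 100
parameter draws for the gate-equation oracle.  The architecture is the
same at any resolution; only filter counts and step budgets are scaled
down in the small-scale configurations.

## Known limitations

No joint end-to-end training of backbone and head; single foreground
class; no surface-distance metrics (Hausdorff/ASSD) or significance
testing; no DICOM series assembly or HU calibration; the detector
provider is a desk-scale stand-in honoring the output contract, not a
full region-proposal detector.
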