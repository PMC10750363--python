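# Methods

`gaitpipe` implements a two-stage video method for separating adult spinal
deformity (ASD) from other spinal gait disorders (dropped head syndrome,
lumbar canal stenosis, hip osteoarthritis — pooled as "non-ASD") in
side-view walking video. This note documents the model, the procedure, the
synthetic data the package is validated on, and the design choices made
where the design was genuinely open.

## The two-stage pipeline

**Stage 1 — detection.** Clinical gait video contains a cluttered static
background and, in some recordings, a second person (the accompanying
doctor) who enters the frame after the patient. The detection stage
reduces each frame to a square region centered on the patient:

1. *Body area*: a per-frame person detector produces bounding boxes and,
   optionally, COCO-17 keypoints. The stage is backend-agnostic — the
   bundled backend is an exact oracle over synthetic scenes; any learned
   detector satisfying the same `Detection` contract can be plugged in.
2. *Body center*: the midpoint of the two hip keypoints when both are
   confidently visible (confidence ≥ 0.3, a conventional visibility
   cutoff), otherwise the box center. When both are available and they
   disagree by more than a tolerance (default 10 px Euclidean) the
   disagreement is flagged but the hip midpoint is kept: the keypoints
   exist precisely to refine the box estimate, so the flag is an audit
   signal, not an override.
3. *Key-frame tracking*: the patient is the person present in frame 0
   (first-entrant prior); if frame 0 unexpectedly holds several people,
   the largest box wins (ties toward the leftmost). Between adjacent
   frames the track continues with the detection whose center is nearest
   to the previous one — the "same person moves the shortest distance"
   rule. This is provably identity-safe whenever the inter-person
   distance exceeds twice the per-frame displacement. Empty frames carry
   the previous detection over for at most `max_gap = 5` frames (brief
   detector dropouts should not abort a clip); beyond that the track is
   declared lost.
4. *Square crop*: the source square's side equals the bounding-box height
   (preserving the person's aspect ratio), centered on the tracked body
   center; parts outside the frame are filled by edge-pixel replication
   (zero-fill selectable — replication avoids injecting artificial black
   borders into the CNN input); the square is resized isotropically to
   512×512 by default.

**Stage 2 — classification.** Cropped video is cut into 1-second,
30-frame shots; T = 8 frames are sampled per shot at indices
floor(k·F/T), k = 0..T−1 (for F = 30: 0, 3, 7, 11, 15, 18, 22, 26 — the
stride-based uniform sampling standard in clip-based action recognition).
The classifier is a 50-layer bottleneck-block residual 3D CNN:

| stage   | output (224 input)| configuration                         |
|---------|-------------------|---------------------------------------|
| conv1   | T × 112 × 112     | 3×7×7, 64, stride 1×2×2               |
| pool1   | T × 56 × 56       | max 1×3×3, stride 1×2×2               |
| conv2_x | T × 56 × 56       | [1×1×1, 64 → 3×3×3, 64 → 1×1×1, 256] × 3  |
| conv3_x | T × 28 × 28       | [.., 128, .., 512] × 4                |
| conv4_x | T × 14 × 14       | [.., 256, .., 1024] × 6               |
| conv5_x | T × 7 × 7         | [.., 512, .., 2048] × 3               |
| pool5   | 1 × 1 × 1         | global spatiotemporal average pool    |

All temporal strides are 1, so T is preserved through every stage and the
parameter count is independent of T. The pooled 2048-vector feeds a
2-way fully connected layer with **independent elementwise sigmoids**
(scores are per-class probabilities, prediction is the argmax, and the
ASD-output sigmoid is the ROC score). Spatial downsampling uses stride
1×2×2 on the 3×3×3 convolution of the first block of conv3/4/5 with a
1×1×1 projection shortcut; batch normalization follows every convolution
and the ReLU follows the residual addition — the standard residual
conventions, adopted where the architecture table is silent.

A `width_multiplier` scales every channel count without changing the
shape ladder; the test suite exercises the full-width topology once
(forward only) and trains quarter-width, 1-block-per-stage variants.
The head can be swapped (`adapt_head`) to fine-tune a checkpoint trained
with a different class count (e.g. a 400-way action-recognition head →
2-way), leaving every non-head weight bitwise untouched.

The network, its backward pass and the Adam optimizer are implemented
directly on numpy: convolutions lower to a single BLAS matrix multiply
through an im2col view, and the backward pass scatters the column
gradient with one strided add per kernel offset. Gradients are verified
against central finite differences in the test suite.

## Training protocol

Adam, learning rate 1e-5 (default), batch size 8. Two independent
monitors run per epoch:

* **Early stopping** — training ends when the best validation loss is
  `patience = 5` epochs old. (Stated as "loss did not increase" in some
  descriptions; read as *did not improve*, since a non-increasing loss is
  the desired outcome and the literal reading would stop training
  immediately.)
* **LR plateau halving** — the learning rate halves when the best
  validation accuracy is `patience = 3` epochs old; the stagnation
  counter restarts after each halving and each new best, so consecutive
  plateaus compound (quartering, etc.). The two counters run
  independently.

The loss is mean binary cross-entropy of the two sigmoid outputs against
one-hot labels (matching the head; no loss was otherwise prescribed).
Adam's moment parameters stay at their conventional defaults. A hard cap
of `max_epochs = 100` backstops the early stop. The checkpoint kept is
the best-validation-loss state.

## Evaluation

**Folds.** Patient-level five-fold stratified group cross-validation: no
patient contributes clips to both train and validation, and class
proportions stay balanced across folds. The split is a greedy
label-balanced deal: per label, seed-shuffled patients go round-robin to
the fold currently holding the fewest patients of that label (ties toward
the smallest fold, then the lowest index). For 54 + 27 patients and k = 5
this yields validation folds of sizes {17, 16, 16, 16, 16} with per-fold
class balance within one patient of the global 2:1 ratio, for every seed.

**Metrics.** Accuracy, precision/recall/F1, and AUROC, averaged
arithmetically across folds. The confusion matrix uses a positional cell
convention — rows are truth (row 1 = ASD), columns are prediction
(column 1 = ASD); TP/FP name row 1 and FN/TN row 2 — note "FP" here
counts ASD cases predicted non-ASD. AUROC is the rank (Mann–Whitney)
statistic with ties counted ½, identical to the trapezoidal ROC area.
For a hard rater with a single operating point this reduces to the
closed form (TPR + TNR)/2, and the equivalence with the rank statistic
on 0/1 scores is exact (tested).

**Rater reproduction.** Clinicians' observations are published as
row-normalized confusion ratios plus class sizes. All three metrics are
scale-invariant in the class sizes, so the full report is reconstructed
from the ratios alone (`report_from_ratios`). Because printed ratios are
rounded versions of integer count ratios, each implied count (rate ×
class size) is snapped to the nearest integer when unambiguous (within
0.05), which recovers the original arithmetic exactly; otherwise the
fractional value is kept, leaving every ratio-based metric unchanged.
The rater F1 values reproduce only with **non-ASD as the positive
class**, so that is the convention on the rater-reproduction path; the
model-evaluation path defaults to ASD-positive (the diagnostic target).

## Synthetic scenes and cohorts

No clinical video ships with the package; a generator produces the same
*structure* so every stage is testable:

* a single articulated stick figure (elliptical head, thick limb
  segments) crossing a fixed side-view camera over a static cluttered
  background, advancing `stride_px` per frame with sinusoidal limb
  oscillation and vertical bob;
* exact per-frame ground truth: bounding box and COCO-17 keypoints
  (hips kinematically meaningful, the rest schematic). The truth box
  uses the figure's extents over a whole gait cycle, so it is rigid and
  its center advances exactly with the stride;
* an optional second figure entering at a configurable frame, trailing
  the patient by exactly `distractor_gap_px` — the "doctor follows
  patient" prior is true by construction and can be violated on purpose
  for negative tests;
* a figure that would leave the frame truncates the scene with a flag,
  never wraps around.

Class identity is carried by the motion signature. Defaults: ASD mean
trunk pitch 28° with 22° head drop; non-ASD mean 4°/2°; per-patient
jitter σ = 2° (plus small stride/sway jitter). The choice makes the
sagittal stooped posture — the visually dominant sign of uncompensated
spinal deformity — the class signal. A `separation` dial scales the
distance between class means: 1 = defaults, 0 = identical means (no
signal), used as a negative control. Default scene size is 640×360
(full-HD geometry scaled down for CPU practicality; the native size is a
config away).

What the generator does **not** emulate: photorealistic appearance,
detector noise (the oracle is exact), camera jitter, occlusions,
clothing/illumination variation, and the true clinical effect sizes —
the kinematic class differences are chosen for testability, not
calibrated to patients. Passing tests therefore demonstrate that the
pipeline's machinery is correct and can recover a class-dependent gait
signal end to end; they say nothing about clinical accuracy.

## Desk-scale experiment

`run_experiment` ties everything together: cohort → oracle detection →
tracking/cropping → slicing/sampling → per-fold training → metrics. One
global seed fans out via `numpy.random.SeedSequence` spawning to cohort
generation, fold split, weight init and batch order; runs are bitwise
reproducible single-threaded. The default desk-scale configuration is
12 patients × 4 one-second clips, 320×180 scenes, 64×64 crops fed at
64×64 to a quarter-width, 1-block-per-stage network trained 10 epochs at
learning rate 1e-3 (a tiny network trained from scratch needs a larger
step than the full network's 1e-5). Under this configuration the
well-separated cohort is recovered at mean held-out AUROC ≈ 1.0 and the
zero-separation control sits at chance.

## Grad-CAM++ visualization

Attention maps use the second-order Grad-CAM++ weighting at a chosen
stage (default conv5_x, the standard choice; any stage is selectable):
α = g²/(2g² + ΣA·g³) per position, channel weights Σ α·relu(g), map =
relu(Σ_k w_k A_k), computed from the gradient of the target-class logit.
Because temporal strides are 1 the stage activation keeps one slice per
input frame; each slice is upsampled bilinearly to frame resolution and
the clip is min–max normalized jointly. The per-frame maps fuse into a
single image by pixelwise maximum (mean selectable) — the maximum
preserves per-frame attention peaks and is order-invariant. Overlays
colormap the fused map (red = strong evidence) and alpha-blend it onto a
frame.

## Numerical and degenerate-input choices

* Boxes are 0-based, half-open; crop geometry rounds to the nearest
  pixel once, when fixing the source square.
* Nearest-center ties during tracking go to the lowest detection index;
  initial-selection area ties to the lowest x1.
* AUROC on a single-class fold is reported as NaN and excluded from the
  fold mean; empty inputs raise rather than default.
* Min–max normalization of an all-constant attention map returns zeros.
* Batch norm uses ε = 1e-5, momentum 0.1; evaluation mode uses running
  statistics, so an untrained network is still deterministic.
* All tensors are float32; the im2col buffers dominate memory (the
  largest, for conv1 at 224 input, is ~180 MB per clip).

## Known limitations

* The bundled detector is the synthetic oracle; plugging in a learned
  detector is an interface away but no weights are shipped or produced.
* Training the full-width network to the published clinical operating
  point requires the private 81-patient dataset and accelerator-scale
  compute; the package trains reduced-width variants on synthetic
  cohorts instead, and the published clip-level results are not
  reproduced here.
* MP4 I/O is not bundled (no ffmpeg binding is assumed); videos are
  exchanged as PNG frame directories with JSON sidecars.
* The numpy engine is single-device and unoptimized for large batches;
  it is built for correctness, determinism and CPU-scale tests.
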