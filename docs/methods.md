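# Methods

`perfseg3d` detects hypoperfused (hypoattenuating) lung parenchyma in CT
pulmonary angiography (CTPA) volumes with a patch-based, valid-padding 3-D
U-net, and evaluates it against the naive global Hounsfield-unit (HU)
threshold that a density-based analysis would use.  Because no patient data
ship with the package, every stage is exercised on synthetic CTPA phantoms
whose construction is described below; the phantom generator is first-class,
tested code.

## Data model and preprocessing

Volumes are 3-D scalar fields in HU with per-axis voxel spacing in mm
(NIfTI-1 on disk; nibabel applies the on-disk slope/intercept).  Masks are
boolean fields on the same grid.  Volume of a mask in mL is
`count * prod(spacing) / 1000`.

Preprocessing resamples to an isotropic grid (trilinear for images,
nearest-neighbour for masks, output shape `round(shape * spacing / target)`
with ties away from zero) and normalizes intensities with the fixed linear
map `y = (x + 750) / 150`, which sends −900 HU to −1 and −600 HU to +1.  The
map is not clipped: values outside the window map linearly outside [−1, 1],
preserving vessel and soft-tissue contrast, and the map is exactly
invertible.  (The network's *input pipeline* may additionally clip the
normalized values — see Training — but the stored normalization never does.)

## The synthetic CTPA phantom

Each case is built on a 64³ grid at 2 × 2 × 2 mm (≈ 2.1 L field of view):

* air background (−1000 HU) around a soft-tissue body ellipsoid (+40 HU);
* two ellipsoidal lung fields of aerated parenchyma (−780 HU), jointly
  ≥ 200 mL; bright (+150 HU) tubular vessels radiating from a hilum point;
* in positive cases, lesions drawn as unions of 2–3 overlapping random
  ellipsoids (metaball-style irregular blobs), placed in the lung interior
  and sized so lesions occupy ≈ 21 % of the lung voxels.  The lesion
  interior is carved to −900 HU (120 HU below normal parenchyma) with a
  sigmoid-graded border of width 3 mm built from the signed Euclidean
  distance to the lesion surface, giving the well-demarcated plateau-plus-
  gradient profile of mosaic perfusion.  Connected components below 5 mL are
  removed from both the label and the image before grading;
* beam-hardening-like streaks: 4 oriented low-HU bands (Gaussian profile
  across a random plane, depth 80–150 HU, width 1.5–3 voxels, lateral reach
  8–16 voxels) anchored on the lung border.  They are added **after** the
  label is frozen, so they are unlabelled confounders — the dominant
  false-positive source for a pure HU threshold;
* Gaussian HU noise with SD 40, also added after label creation.

The 120 HU lesion contrast is deliberately below 4 noise SDs, so voxel-wise
thresholding is imperfect and the network-vs-baseline comparison is
non-degenerate, while local averaging and shape context carry genuine
additional information.  A fixed seed reproduces a case voxel for voxel;
cohorts derive per-case seeds from one master seed via `SeedSequence`.

What the phantom does **not** emulate: CT physics (no projection or
reconstruction, no genuine beam-hardening spectra), scanner and tube-voltage
variability, respiratory/cardiac motion, airway trees, real vascular
anatomy, pleural effusions or comorbid parenchymal disease, and the
inter-observer variability of manual labels.  Passing tests therefore
demonstrate that the pipeline is implemented correctly and that the network
can exploit spatial context on well-posed data — they are not evidence of
clinical performance.

## Patch extraction and exact tiled inference

Training samples pair a binary label patch of side 32 (16 in the scaled-down
experiment) with an input window extended by the network margin on every
side; windows that leave the volume are padded by edge replication.
Candidate placements are uniform over the volume and rejected only when the
label-patch region contains no lung voxel (patches *partially* inside the
lung are kept).  An optional oversampling knob forces a configurable
fraction of samples to contain lesion voxels; the experiment default is 0.5,
which counters the scarcity of lesion voxels in uniform samples.

Inference tiles the lung bounding box with non-overlapping label patches
whose starts are multiples of the patch size, so every tile shares one
pooling-grid alignment.  Because all convolutions are valid and upsampling
is exact (below), stitching per-tile outputs equals a dense whole-volume
pass on the replication-padded volume to within float tolerance; this
identity is the correctness oracle for all margin handling and is asserted
in the tests.  Voxels outside the lung are set to probability zero.

## Network architecture

The reference network has three 2×2×2 max-pooling steps, 3×3×3 valid
convolutions with ELU activations, filter counts 16/32/64 (bottleneck 64),
and a single 1×1×1 sigmoid output neuron.  Upsampling is factor-2 linear
interpolation followed by a 1-voxel validity crop (n → 2n − 2): every
retained sample is an exact interior interpolation, which is what makes
tiled inference exactly equal to dense inference.  Skip connections crop the
encoder feature map centrally to the decoder size.

Under this upsampling rule the per-side shrinkage of a 3-level network is

    S/2 = e0 + 2·e1 + 4·e2 + 8·b + 4·d2 + 2·d1 + d0 + 7

(e, b, d = number of convolutions per encoder/bottleneck/decoder stage).
The reference configuration — encoder (2, 2, 1), bottleneck 1, decoder
(1, 0, 1) — gives exactly 30 voxels per side, so a 92³ input yields a 32³
output.  The margin is a build-time contract: a symbolic shape trace
validates it at construction and rejects configurations whose achieved
shrinkage differs, naming the achieved value.  Admissible input sides for
the reference network satisfy N ≡ 4 (mod 8), N ≥ 68.

Normalization is per-channel batch normalization by default, with running
statistics at inference (a fixed affine map, hence translation-equivariant
and compatible with exact tiling).  Group normalization is selectable, but
its statistics depend on the entire input window, so tiled and dense
inference then differ by construction; this trade-off is why batch
normalization is the default.

The engine is pure NumPy (float32): convolutions are evaluated as one GEMM
per kernel tap, with hand-written backward passes for every layer (verified
against finite differences in the tests) and an Adam optimizer.

## Training

Dice loss `1 − (2Σpt + s)/(Σp + Σt + s)` with smoothing s = 1, computed over
the whole minibatch; Adam with learning rate 2·10⁻⁴ and batch size 16 are
the library defaults.  Early stopping monitors validation Dice (voxel
accuracy selectable) with a configurable patience and restores the
best-epoch weights.

Small-batch Dice training of a small network is noisy, so the trainer
includes four stabilizers, all configurable:

* **Frozen batch-norm statistics** after a warm-up epoch: training then
  optimizes exactly the inference-time network, removing the train/eval
  statistics mismatch that otherwise dominates at batch size 8–16.
* **Output-bias initialization** at the logit of the expected lesion
  prevalence, so optimization starts near the class prior instead of at
  p = 0.5 everywhere.
* **Input clipping** of the normalized intensities to ±2 at the network
  input (training and inference consistently).  Unclipped inputs span
  roughly −1.7 (air) to +6 (vessels), and the out-of-lung content otherwise
  dominates the conditioning of the first layers.
* **Cosine learning-rate decay** to 10 % of the initial rate.

Gradients with magnitude below 1e-25 are flushed to zero in the backward
pass: they are far below anything Adam can use, but their products underflow
into subnormal floats, which slow x86 arithmetic by orders of magnitude once
the network saturates.  Flushing changes no observable result (the test
suite pins exact training behaviour) and roughly halves training time late
in a run.

## Baseline

The naive HU-threshold comparator labels lung voxels with HU ≤ t (inclusive,
default −850 HU) positive, with no clustering or smoothing.  Its continuous
ROC score is the negated HU value on lung voxels; voxels outside the lung
carry no score and are excluded from every evaluation.

## Evaluation

Voxels are pooled across test cases for the ROC curve (trapezoidal AUC, ties
grouped); each method's operating threshold maximises pooled balanced
accuracy, with ties broken toward the lower (more sensitive) threshold.  MCC
is computed from the pooled confusion counts at that threshold; a zero
factor in its denominator yields MCC = 0 by convention.

Confidence intervals are percentile bootstrap over test **cases** (the
patient analogue; voxels within a lung are strongly correlated), 10⁵
resamples at the 95 % level by default.  Paired differences (network minus
baseline) are computed on the same resample, with the point estimate the
mean resampled difference and significance declared when the interval
excludes zero.  Resamples on which a statistic is undefined (e.g. a pooled
single-class draw) are redrawn, with a documented cap.  For AUC intervals
the per-case data are class histograms of the scores on a fixed 512-bin
grid, so each resample is a histogram sum; this binned AUC is accurate to
well below the bootstrap noise at the cohort sizes used.  MCC statistics use
exact per-case confusion counts, which are additive.

Region-level matching computes 26-connected components of the predicted and
manual masks; a manual component with at least one overlapping predicted
voxel is exactly one true positive (several predicted components overlapping
the same manual region still count once), predicted components with no
overlap are false positives, and unmatched manual components are false
negatives.  Case-level calls use the mean network probability over the lung
with an inclusive 0.55 cutoff; the per-case HU summary reports both readings
of the sub-threshold statistic (fraction of lung voxels at or below the
threshold, and their mean HU) without asserting either as canonical.

Probability maps are carried in float64 so that near-saturated sigmoid
outputs retain distinct ranks in the ROC analysis.

## The scaled-down experiment

The default experiment (`default_small_config()`) is sized for a single CPU
core: a 9 + 9 cohort of 64³ phantoms at 2 mm spacing, split 5/1/3 per class
(10 training / 2 validation / 6 test cases, the 48/12/40 design at cohort
scale); a one-level U-net (margin 6, filters 8/16, window 28³ for 16³ label
patches); 48 training patches per case, batch 8, learning rate 7·10⁻³ with
cosine decay, at most 10 epochs; evaluation with 2000 bootstrap resamples.
One run takes a few minutes on one core.  With these conditions the trained
network reliably exceeds the HU baseline's pooled AUC and the paired MCC
difference excludes zero — the phantom analogue of the clinical comparison.
The reference margin-30 architecture is exercised structurally (shape trace,
forward-pass shrinkage, untrained-output range) rather than trained, which
keeps the full test battery within a CPU budget of roughly twenty minutes.

## Numerical choices and edge cases

* Resampled output shape: round-half-away-from-zero; identity short-circuit
  when the spacing already matches.
* Upsampling: half-voxel linear interpolation, 1-voxel validity crop.
* Pooling requires even feature-map sides; the shape trace rejects
  inadmissible inputs with a named reason.
* Threshold comparisons are inclusive (`score ≥ t` positive; HU ≤ t
  positive; case call at mean ≥ cutoff).
* MCC degenerate denominator → 0; balanced accuracy treats 0/0 class rates
  as 0.
* Empty evaluation region, empty lung, single-class ROC truth: errors.
* Edge tiles are clipped to the volume; their input windows keep the full
  nominal size via replication padding, and the network output is cropped to
  the clipped extent when stitching.

## Limitations

The phantom's simplifications (listed above) mean measured effect sizes do
not transfer to patients.  The scaled-down network is far smaller than the
reference architecture, and its advantage over the HU threshold rests on the
confounders the phantom contains (noise, graded borders, unlabelled streak
artifacts, bright vessels inside lesions).  Group-normalized networks do not
satisfy the tiled-equals-dense identity.  Bootstrap intervals with 6 test
cases are wide; the experiment's verdict is the sign and significance of the
paired difference, not a precise effect size.
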