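# Methods

## Overview

`rbseg` implements a semi-supervised pipeline for segmenting
retinoblastoma-like lesions in color fundus photographs:

1. **Unsupervised pixel pseudo-labeling.** The target image is resized to
   320 × 480, converted to grayscale, and stacked with three healthy
   reference fundus images so that healthy retina is guaranteed to dominate
   the pixel population. A K = 6 Gaussian mixture is fitted to the pixel
   intensities of the composite by expectation–maximization with multiple
   seeded restarts; the most populous cluster is declared *healthy* and every
   other cluster is merged into a *suspected* mask. The mask restricted to
   the target block is cleaned with a median filter, a morphological closing,
   and small-connected-component removal.
2. **Disc removal.** The optic disc is the method's characteristic false
   positive. In the clinical workflow a human edits it out of each
   pseudo-label; with synthetic data the generator's known disc support
   (dilated by a small margin to cover the blurred rim) is subtracted
   instead.
3. **Curation.** Only pseudo-labels a reader would call properly segmented
   enter the training pool. On synthetic data the generator's ground truth
   stands in for that judgment: diseased cases must reach Dice ≥ 0.5 against
   the true tumor mask and healthy cases must carry < 3 % spurious
   foreground. In practice this keeps ≈ 80 % of cases, comparable to the
   fraction a human reader accepts.
4. **Refinement network.** A compact fully-convolutional network distills
   the slow clustering stage into a fast forward pass. It is trained on the
   (image, edited pseudo-label) pairs and evaluated on a held-out 10 % split
   against the generator's tumor masks.

## The mixture model

Pixel intensities are modeled as a K-component Gaussian mixture
{μ_k, Σ_k, π_k}. The E-step computes responsibilities
γ(z_nk) = π_k N(x_n | μ_k, Σ_k) / Σ_j π_j N(x_n | μ_j, Σ_j); the M-step
re-estimates π, μ, Σ from responsibility-weighted moments. The
implementation is dimension-generic, all density arithmetic is carried out
in log space with per-point max subtraction, and every covariance is floored
at an eigenvalue of 1e-6 (intensities live in [0, 1]) to avoid collapse on
flat regions. A component whose effective count vanishes is re-seeded from a
random data point rather than aborting the fit.

**Convergence.** Iteration stops when the *mean per-point* log-likelihood
improves by less than 1e-6 (or after 200 iterations). A criterion on the
total log-likelihood is useless at this problem size: with ~6 × 10⁵ pixels
the total is O(10⁵), so any absolute threshold either never fires or fires
immediately.

**Histogram-weighted EM.** Fundus photographs are 8-bit, so the composite is
quantized to 256 intensity levels and EM runs on the level histogram with
bin counts as sample weights. This is algebraically identical to per-pixel
EM on the quantized image and removes a factor of ~2,000 from the E-step
cost; it is why 25 restarts at full resolution cost well under a second.

**Initialization and determinism.** Restart i of `fit_gmm(seed=s)` is seeded
`s + i`: K means drawn uniformly from the data without replacement, global
variance, uniform mixing weights. The restart with the highest final
log-likelihood wins, making the whole fit a pure function of its arguments.
Hard assignments break ties toward the lowest component index.

## Pseudo-label post-processing

Order: median filter (5 × 5) → binary closing (5 × 5, outside treated as
foreground so constants survive) → removal of 8-connected components smaller
than `min_area` = 100 px. The sizes are chosen so that sub-vessel-width
clutter (≤ 2 px strokes, isolated speckle) dies while the smallest plausible
lesion (~14 px radius at 320 × 480, i.e. ≥ 600 px) survives; `min_area` is an
absolute pixel count rather than a resolution-scaled one because the
smallest true lesion stays above 150 px even at half resolution while
texture clutter does not shrink with resolution (stroke widths saturate at
one pixel).

## The refinement network

Three sequential subnetworks; each applies three convolutional layers *in
parallel* to its input (kernels 3/5/7, 4 channels per branch by default),
concatenates the feature maps (12 channels) and applies a ReLU; a final
1 × 1 convolution with a logistic activation yields one score per pixel.
Same-padding everywhere, so the network runs at any resolution;
~8,300 trainable parameters with the default widths. Four channels per
branch (rather than a wider net) keeps a 10-epoch batch-size-1 training run
on one CPU core in minutes while already saturating the synthetic task —
the width is configurable.

Implementation: convolutions, backpropagation and the optimizer are written
on numpy. Each block's three branches are stored as one dense k_max × k_max
kernel tensor under a fixed structural mask that zeroes every branch outside
its own support, so a block is a single masked convolution computed as one
BLAS matrix product against a persistent shifted-input cache. Gradients were
verified against central finite differences.

**Training.** RMSProp with learning rate 0.001, decay 0.9, and epsilon 1e-7
*inside* the square root (`lr · g / √(avg + ε)`), batch size 1 (one update
per image — averaging losses across dissimilar fundus images blurs the
per-image gradient signal), at most 10 epochs with early stopping on the
validation loss (patience 3, minimum improvement 1e-4), and the best
validation weights restored at the end. Inputs are centered ([0,1] intensities
shifted to [-0.5, 0.5]) before entering the network: fundus images share a
large mean-brightness component, and without centering the first-layer
features are dominated by that shared offset rather than by local contrast,
which measurably slows and destabilizes the short training schedule. The
output bias is initialized to
the logit of the training labels' foreground rate (prior initialization):
without it, the first several epochs of a short batch-1 schedule are spent
re-learning the class base rate — the validation loss sits at the prior's
entropy — and whether the run recovers in the remaining epochs depends on
the weight-initialization seed. The epsilon placement matters: with
ε added *outside* the root, per-pixel-mean losses produce gradients so small
that every update degenerates to a ±lr sign step, and the coherent movement
of thousands of parameters saturates the logistic output within one epoch.

**Two output modes.**

* `importance` (binary cross-entropy): graded scores in (0, 1) acting as a
  per-pixel importance map. This mode trains robustly and is the one the
  quantitative evaluation uses (thresholded at 0.5 for pixel metrics).
* `boundary` (mean absolute error): pushes scores toward exactly 0/1 for
  hard boundaries. With a logistic output and a rare positive class this
  objective has a strong all-background attractor: the majority-class
  down-push on the logits is proportional to (1 − 2·foreground fraction)
  and the gradient of a wrongly-suppressed positive carries the vanishing
  factor p(1 − p), so at desk scale (~2,000 updates) the mode reliably
  collapses to empty masks before the features can differentiate. The mode
  is implemented and contract-tested, but quantitative claims in this
  package are made for the importance mode only.

**Splits.** Seeded shuffle; 10 % evaluation, then 10 % of the remainder for
validation, rest training (≈ 81/9/10). A pool of 3,279 images yields the
328-image evaluation set.

## Synthetic fundus phantoms

The generator renders the imaging traits the method depends on, each with
its own intensity mode (grayscale luma in parentheses): warm orange-red
background with a gentle radial falloff and low-frequency mottle (~0.50),
dark vessel curves radiating from the disc (~0.23), a fine dark capillary
mesh (~0.38), bright drusen-like speckle (~0.62, ~2 % support), whitish
blurred-edge tumor blobs (lift 0.28 → ~0.75), and a bright optic disc
(~0.94). A mild vignette darkens the far corners; lowering
`vignette_radius` produces a hard black surround for robustness tests, but
the default emulates the frame-filling field of wide-field pediatric fundus
cameras.

The six distinct intensity modes are not decoration: a K = 6 mixture
allocates one component per mode, so the majority-cluster rule isolates the
background cleanly. The capillary mesh and speckle are deliberately thin
(≤ 2 px strokes and dots, spacing set in absolute pixels at every
resolution) — they are flagged as "suspected" by the clustering, exactly
like real retinal texture, and it is the median/morphology cleanup that must
remove them. A background without such occupying structures would be
silently split across spare mixture components, flagging large coherent
areas — the failure mode that motivates the healthy-reference concatenation
in the first place.

Tumor geometry: 1–3 blobs per diseased eye, each a union of 2–4 overlapping
ellipses with radius 14–42 px at 320 × 480 (roughly 0.5–2 optic-disc
diameters), Gaussian-blurred margins (σ = 1.5 px), placement
rejection-sampled to avoid the disc so the two ground-truth masks are
disjoint. Geometry parameters are expressed at the 320 × 480 reference scale
and rescale with the requested resolution, except stroke counts, which scale
with the linear factor to keep texture spacing in absolute pixels.

What the phantoms do **not** emulate: photorealistic texture, regression
patterns, calcification, vitreous seeds, acquisition artifacts, and the full
variability of camera color profiles. Passing tests therefore show that the
pipeline's machinery (clustering, majority rule, cleanup, distillation,
metrics) behaves as specified on data with the assumed contrast structure —
not that the clinical performance numbers transfer to real wide-field fundus photographs.

## Desk-scale experiment protocol

The reproduction run (`scripts/acceptance.py`, also the headline fixture of
the test suite) uses n = 300 phantoms with 20 % healthy, clustering at the
method's native 320 × 480 with 5 EM restarts (the restart count is the one
concession to desk-scale runtime; 25 restarts change the results only
marginally because the histogram EM landscape at K = 6 is easy), disc
removal with a 5 px margin (a human editor wipes the blurred rim along with
the disc core), curation, and refiner training/evaluation at
160 × 240 (images and masks area-resampled, masks re-thresholded at 0.5).
Clustering at native resolution and refining at reduced resolution keeps
each stage at the scale that dominates its quality/cost trade-off: label
fidelity is resolution-limited, while the refiner is compute-limited.

Evaluation: predictions binarized at 0.5, filtered with the same
minimum-lesion-size prior as the unsupervised stage (8-connected components
under 100 px are discarded — the smallest plausible lesion exceeds 150 px at
every supported resolution, while a handful of stray super-threshold pixels
on a healthy eye would otherwise flip that image's Dice from 1 to 0 under
the empty-truth convention), and scored against the generator's tumor masks
on the evaluation split with the Sørensen–Dice coefficient
2TP/(2TP+FP+FN), sensitivity TP/(TP+FN), specificity TN/(TN+FP) and
accuracy. Degenerate conventions: Dice of two empty masks is 1 (perfect
agreement on absence), and an undefined sensitivity/specificity (empty
reference class) reports 1.0 with a logged warning.

## Known limitations

* The majority-cluster rule presumes the healthy background forms the
  single largest intensity cluster; images whose background is strongly
  non-stationary (illumination gradients comparable to lesion contrast)
  break that premise, and such failures must be caught by the curation step.
* Boundary (MAE) mode is quantitatively unreliable at desk scale (see
  above).
* The refiner consumes grayscale input by default; color input is supported
  but untested against the synthetic palette's color degeneracies.
* Pixel-level metrics treat every pixel equally: a single large lesion
  dominates per-image Dice, and lesion-level detection rates are out of
  scope.
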