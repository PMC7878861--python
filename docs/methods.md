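# Methods

## Problem setting

Reflectance confocal microscopy (RCM) produces large grayscale mosaics
(up to ~12k × 12k pixels) of skin at the dermal–epidermal junction.
Architecturally preserved tissue shows one of five benign patterns
(ring, meshwork, nest, background, artifact); loss of that regular
architecture — the *aspecific* pattern — is associated with inflammation,
pre-malignancy or malignancy, and is the positive class throughout this
package.  Expert pixel-level annotation of such mosaics is expensive and
partial: only a fraction of pixels carries a label, transitions between
patterns are ill-defined, and areas the readers chose not to call are
explicitly *unlabeled* rather than negative.

`camstitch` implements a weakly supervised route to segmenting the
aspecific pattern: a binary patch classifier is trained from single
patch-level labels only, and per-patch class activation maps (CAMs) are
stitched into a mosaic-level aspecific probability map.  Pixel labels are
used only to pick patch centers during dataset construction and to
evaluate the final maps — never as a training signal.

## Weak-label dataset construction

Annotated mosaics (one patient each) are split patient-wise into
train/validation/test at 70/10/20.  Patient counts per split follow
largest-remainder rounding (ties toward the earlier split), so 157
patients yield 110/16/31 and 12 yield 9/1/2.  Within those capacities a
greedy pass (largest patients first) assigns each patient to the split
whose running per-class pixel composition stays closest (L1) to the
global composition, approximately preserving each class's label ratio in
every split.

Mosaics are then downsampled — block-mean for intensities (anti-aliased),
block-center nearest-neighbour for labels (categories never mix) — by a
factor of 4 at full scale.  Patches are extracted by sampling a uniform
random pixel of a requested fine label and cutting the square window
centered on it; the patch inherits the *weak* binary label of its center
pixel (aspecific vs any benign sub-label).  Centers closer than half a
window to a border are excluded from the candidate set, which keeps the
center-pixel rule exact without padding artifacts.  Sampling is with
replacement by default (a flag disables it).  Quotas are balanced — a
fixed count per benign subclass, with the aspecific quota matching the
total benign count — and each mosaic contributes in proportion to its
share of that label's samplable pixels (largest-remainder rounding keeps
per-label totals exact).  Unlabeled pixels are never sampled and never
scored.

Training-time augmentation: random crop (to 256 px at full scale),
horizontal/vertical flips, brightness/contrast jitter, additive noise and
mild blur, all clipped back to [0, 1].  The pipeline realises
augmentation as one seeded draw per extracted patch rather than a fresh
draw every epoch; at the scales this package trains at the synthetic task
does not need per-iteration augmentation, and a single draw keeps
training fully deterministic given the seed.

## Backbone and training

CAM generation requires one specific topology: convolutional feature
extractor → global average pooling (GAP) → fully connected head.  Any
backbone honouring the contract

    p(aspecific | x) = sigmoid( ⟨w, GAP(A(x))⟩ + b )

can be plugged in.  The shipped reference backbone (`TinyCNN`) is three
3×3-conv + ReLU + 2×2 average-pool blocks (channels 8/16/16 by default)
implemented in plain numpy with hand-derived backpropagation, so the
whole pipeline trains on a single CPU in minutes.  Because average
pooling preserves spatial means, the GAP of the final conv activations
equals the GAP of the pooled tensor, and the contract above holds exactly
for the pre-pool feature stack used by the CAMs (asserted numerically in
the tests).

The head is a single sigmoid logit.  A two-unit softmax head is
mathematically equivalent for two classes (fold w = w_pos − w_neg); it is
documented here rather than duplicated in code.  CAMs for the benign
class use −w.

Optimisation: SGD with momentum 0.9, weight decay 5e-4, batch 128,
binary cross-entropy on the logit, dropout (default 0.75) between GAP and
head, and a staircase learning rate lr₀ · 0.9^(epoch/10) from lr₀ = 1e-3
over 500 epochs at full scale.  The best-by-validation-loss checkpoint is
returned.  The desk-scale preset shortens this to 20 epochs at lr 0.02
with dropout 0.25 and batch 64 — the reference CNN on the synthetic task
saturates within a handful of epochs, and the heavy regularisation that a
7M-parameter network needs would only slow the 6k-parameter one down.

## CAM generation

**Traditional CAM** bypasses the GAP layer: the raw map is the weighted
sum R(x,y) = Σₖ wₖ Aᵏ(x,y) over the final conv feature stack.  R is
min–max normalized to [0, 1] (a constant map normalizes to all-zeros; an
8-bit 0–255 display form is also available) and bilinearly upsampled to
the patch size.  Min–max is the only normalization consistent with a
fixed display range, and it makes the map invariant to positive affine
transforms of R.  Negative raw values are retained until normalization;
no ReLU is applied on this path.  The spatial mean of R equals the logit
minus the head bias — the closed form the tests pin down.

**ScoreCAM** replaces the head weights with forward-pass evidence.
Phase 1: take the K activation maps at a user-selected conv level
(default: the final one, matching the traditional method), normalize each
channel, and upsample to the input size.  Channel normalization defaults
to per-channel min–max — the masking step needs maps in [0, 1] to act as
masks — with a per-channel spatial softmax available as an option.
Phase 2: mask the input with each map (Mᵏ = Âᵏ ∘ I), forward all K masked
inputs, softmax the target-class outputs over channels into scores Sₖ
(Σ Sₖ = 1), and return ReLU(Σₖ Sₖ Âᵏ), min–max normalized.  If every
pixel of the weighted sum is non-positive the map is all-zero and flagged
(`all_nonpositive`) rather than silently rescaled.

## Sliding-window stitching

The mosaic is processed in overlapping windows (256 px at full scale;
steps 25/50/100).  Window positions run 0, step, 2·step, … plus a flush
position at `dim − window` so every pixel is covered without
zero-padding.  Each window contributes p · C — its aspecific probability
times its normalized CAM — which boosts maps from aspecific windows and
suppresses benign ones; benign windows are deliberately not zeroed.
Overlaps are resolved as a per-pixel weighted average with either uniform
weights (plain averaging) or a separable 2-D Gaussian kernel

    g(x, y) = N(x; 0, σ₁) · N(y; 0, σ₂)

centered on the window, which favours each window's center where the
classifier has full spatial context.  Widths beyond σ ≈ 10 blur the
result unrealistically and the sweep grid stops there.

Numerical choices:

* Offsets are measured from the continuous window center (window−1)/2,
  so the kernel is exactly mirror-symmetric; for even windows no pixel
  sits at offset zero and the maximum is shared by the four central
  pixels.
* The kernel is never renormalized to sum to one — only weight ratios
  survive the per-pixel division — but inside the stitcher it is
  max-normalized and floored at the smallest positive double: for narrow
  σ the corner weights of a large window underflow, and a border pixel
  covered only by window corners would otherwise divide zero by zero.
* Accumulation is streaming over two mosaic-sized rasters (score·weight
  and weight), so windows can be processed in any order or batch; the
  result is order-independent to 1e-6 and equals a per-pixel brute-force
  weighted average exactly (tested).
* Per-window contributions depend only on window content and CAM method,
  never on step or σ, so sweeps compute them once on the union grid and
  reuse them across all configurations.

The final score map is a convex combination of p · C values and therefore
lies in [0, 1]; it is interpreted as a probability-like aspecific score
(the p × C product is taken in [0, 1] units, not 0–255).

## Evaluation under partial annotation

All pixel metrics are restricted to labeled pixels; the five benign
sub-labels collapse into one negative class.  Flipping the scores of
unlabeled pixels changes nothing (tested).

* **ROC/AUC**: trapezoidal AUC over the masked pixels, which equals the
  rank statistic P(positive outscores negative, ties ½); an independent
  pairwise implementation serves as the test oracle.  A single-class
  region returns an explicit *undefined* marker — never a silent 0 or 1.
* **Dice sweep**: Dice = 2|P∩T|/(|P|+|T|) at every threshold on the exact
  0.02 grid (rule: score > t; both-empty counts as 1).  Ties at the
  maximum break toward the lowest threshold — the sensitivity-favouring
  choice when the cost of overlooking malignancy is asymmetric.
* **Bootstrap ROC**: replicates draw test mosaics with replacement
  (default: as many as there are test mosaics; 1000 replicates at full
  scale), pool their labeled pixels, and compute one ROC each; TPRs are
  linearly interpolated onto a 101-point FPR grid and the mean plus
  2.5/97.5-percentile bands reported.  The replicate metric is the
  pooled-pixel ROC; a per-mosaic-averaged variant is possible but not the
  default.  Single-class replicates are redrawn and counted.

## Synthetic study conditions

The clinical mosaics are proprietary, so a generator emulates their
statistical structure:

* **Textures.** Benign tissue: a quasi-periodic bright lattice — white
  noise filtered by an annular band-pass at spatial wavelength 32 px
  (mimicking ring/mesh regularity).  Aspecific tissue: disordered
  broadband speckle — rectified low-pass noise, correlation length
  ~10 px.  The families differ in spectrum and, by default, mean
  intensity (0.58 vs 0.40; the `easy()` preset widens this to 0.62 vs
  0.33), which fixes the difficulty of the downstream task.  A
  Kolmogorov–Smirnov statistic between the families' intensity
  histograms is exposed as the learnability floor.
* **Annotation.** Labeled regions are the top quantiles of per-class
  Gaussian random fields (blob scale `blob_sigma`, default 48 px) —
  smooth blobs with soft borders, not polygons.  Quantile construction
  makes per-class pixel fractions essentially exact.  Default fractions
  mirror a realistic clinical distribution: of the 38% of pixels labeled,
  ring 34%, artifact 17%, mesh 17%, background 14%, aspecific 12%,
  nest 5%.  The remaining 62% is unlabeled and filled with a random
  spatial mixture of both texture families, so evaluation masking is
  genuinely exercised.
* **Imaging noise.** Mean-one multiplicative speckle (variance 0.01)
  followed by Gaussian blur (σ = 1 px), clipped to [0, 1].
* Every mosaic gets a distinct patient id; generation is bit-identical
  given (spec, seed).

What the generator does **not** model: the true biology of the six
patterns, intra-class texture diversity, stitching seams between fields
of view, depth-dependent signal loss, or annotation noise.  Passing the
end-to-end floors on this data shows the pipeline's machinery is correct
and can recover a planted texture distinction; it says nothing about
clinical performance.

## Problem sizes

Full-scale defaults (2048² synthetic mosaics, 500-px patches, ~5000 per
benign subclass, 500 epochs, 256-px windows) reproduce the intended
study geometry.  The test suite and the acceptance script run the
desk-scale preset instead: 12 mosaics of 512² used at native scale
(window 64, steps 16/32/64, patch 72, crop 64; the ×4 downsampling is
skipped so the window keeps a representative ratio to the labeled
structures), 40 patches per benign subclass (400 train patches total),
20 epochs, 200 bootstrap replicates.  The default sweep grid is the
cross product of 3 step sizes × (plain averaging + σ ∈ {1, 2.5, 5, 6, 7,
8, 9, 10}) for each of the two CAM methods — 27 rows per method, 54
total.

## Known limitations

* The reference backbone is deliberately small; swapping in a modern
  pretrained feature extractor is an interface exercise (honour the
  conv → GAP → FC contract) but outside this package's scope.
* Six-class segmentation is not implemented; the head and the evaluation
  are strictly binary (aspecific vs rest).
* The numpy training loop is single-threaded per operation and not meant
  for datasets beyond ~10⁵ patches.
* With very small test splits the bootstrap bands are driven by a handful
  of mosaics and should be read qualitatively.
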