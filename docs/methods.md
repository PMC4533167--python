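# Methods

This note documents the models and numerical choices behind `fvstage`:
what each stage of the pipeline computes, the defaults and why, what the
synthetic data generator does and does not emulate, and the known
limitations.

## Problem setting

Placental maturity on B-mode ultrasound is graded 0–3 by the appearance
of calcification: grade 0 is homogeneous speckle, higher grades show
increasingly many bright echogenic foci and ring/arc-like structures
along the chorionic and basal plates. The package treats staging as
four-class texture classification of 2-D grayscale images with a
bag-of-features pipeline and evaluates it by stratified cross-validation.

## Pre-processing

Images are reduced to a single luminance channel (Rec.601 weights —
deterministic and universally expected), rescaled so the dtype's maximum
representable value maps to 1.0, denoised, and range-normalized to
[0, 1]. The denoising operator is configurable; the default is a 3×3
median filter, chosen because median filtering suppresses speckle
outliers while preserving the edges and bright foci that carry the
staging signal. Constant images normalize to all-zeros rather than NaN
so degenerate inputs cannot poison later stages.

## Sampling and descriptors

The pipeline's preferred sampling is a dense regular grid: patches of
side `patch_size` (default 16) anchored at the top-left corner with
stride `step` (default 8), keeping only fully-inside windows, so the
count per axis is `floor((dim − patch)/step) + 1`. Interest-point
detectors (Harris, Hessian, Harris-/Hessian-Laplace, multiscale
variants, DoG) are provided for comparison. Conventions shared by every
module: 0-based coordinates, `x` = column, `y` = row, pixel centers at
integers; `scale` is a Gaussian σ for detectors and the patch half-width
for dense sampling. Non-max suppression uses a 3×3 neighborhood with
ties broken in raster order; detector output is sorted by descending
response. The DoG detector uses a single-resolution σ ladder (ratio
2^(1/levels), σ₀ = 1.6, peak threshold 0.01 of the unit dynamic range,
edge ratio 10). Not downsampling between octaves costs speed on large
images but keeps localization exact at the desk scales used here.
Second derivatives for the Hessian/Laplacian responses are computed as
two first-derivative Gaussian passes: truncated even-order derivative
kernels do not sum exactly to zero and would otherwise leave a spurious
response on constant regions.

Descriptors are computed upright (no dominant-orientation assignment),
the convention for densely sampled features, and clamp-to-edge padding
is used at borders so descriptors are always finite:

- **SIFT** (128-dim): 4×4 spatial × 8 orientation trilinear histogram of
  Gaussian-weighted gradients over the patch, L2-normalized, clipped at
  0.2, renormalized. Orientation bin centers sit at k·2π/8 so an axis-
  aligned edge falls in the center of a bin.
- **DAISY** (200-dim): half-wave-rectified oriented gradient maps
  smoothed per ring (σ = radius/2, default radii 5/10/15 px), sampled at
  the center and 8 points per ring; per-histogram L2 then a global L2.
- **LIOP** (144-dim): for each pixel of the patch's inscribed circle,
  4 points are sampled (bilinear) anticlockwise on a radius-6 circle
  anchored at the pixel's outward radial direction; the permutation that
  sorts the samples indexes a histogram cell within the pixel's ordinal
  intensity bin (6 equal-population bins, raster-stable ties). The
  radial anchor makes the construction rotation invariant; the center
  pixel, whose radial direction is undefined, is excluded. Invariance to
  monotone intensity maps is exact whenever no two interpolated samples
  swap order — guaranteed for positive affine maps, and for smooth
  patches with ordering margins under any monotone map; a harsh
  nonlinearity on a noisy patch can flip near-ties.
- **Intensity** (256-dim): bilinearly resampled 16×16 patch, mean
  subtracted, L2-normalized.
- **Combine**: row-wise SIFT ⊕ intensity over identical keypoints.

## Vocabulary and encoding

Descriptors are PCA-whitened (default 64 dimensions; 32 in the reduced
benchmark) so the GMM's diagonal-covariance assumption is reasonable.
The vocabulary is a K-component diagonal GMM (default K = W = 400, the
accuracy/cost sweet spot for this task; 64 in the reduced benchmark) fit
by EM from a seeded k-means++ initialization, with the per-iteration
mean log-likelihood recorded (non-decreasing, stop at relative tolerance
1e-6 or 100 iterations) and variances floored at 1e-4 × the mean
per-dimension data variance so near-duplicate dense patches cannot
produce singular components. Responsibilities are computed in log space;
rows sum to 1 even for components thousands of σ away.

The Fisher vector is the Fisher-information-normalized gradient of the
per-descriptor log-likelihood with respect to means and standard
deviations (2Kd entries; the weight-gradient block is deliberately
excluded — the encoding concatenates the mean and variance statistics
only). Improved-FV normalization (signed power α = 0.5, then global L2)
is applied by default and exposed as a flag. VLAD (per-component
residual sums, K·d) and BoVW (hard-assignment histogram, L1) use the
same GMM vocabulary via maximum-posterior assignment — one vocabulary
serves all three encoders, and ties assign to the lowest component
index.

The multi-layer encoding partitions the image per pyramid layer
(boundaries at rounded equal fractions; regions tile each layer exactly),
assigns each descriptor to the region containing its keypoint center,
encodes regions independently (empty region → zero block), and
concatenates in layer then raster order with a final global L2. The
default layout `[(1,1), (2,2)]` keeps the vector length tractable while
adding coarse spatial information; per-region normalization before the
global one prevents descriptor-dense regions from dominating.

## Staging and evaluation

Four one-vs-rest linear SVMs with class-balanced penalties (the stage
distribution in clinical practice is heavily skewed toward early stages)
produce per-stage scores; the predicted stage is the argmax with ties to
the lowest stage. The libsvm solver is used with hinge loss and a tight
KKT tolerance: on separable data the solution is the hard-margin one,
which is invariant to duplicating the training set, and fitting is
deterministic. C defaults to 1.0 (the standard pairing with normalized
Fisher vectors); only the linear kernel is wired in, as FV dimensions of
10⁴–10⁵ make nonlinear kernels impractical and unnecessary.

Cross-validation is stratified and seeded; *everything that learns from
data* — whitener, GMM, SVM — is refit inside each training fold, because
fitting the vocabulary on all images would leak test information into
the models. Per-stage sensitivity and specificity come from the pooled
hard predictions, average precision and ROC/AUC from the pooled score
columns; AUC is the trapezoidal area under the ROC with thresholds at
unique scores, which equals the Mann–Whitney pair statistic with ties
counting one half. Macro averaging over the stages present in the truth
is reported (the standard choice for a single summary number on a
4-class problem); stages absent from the truth are excluded with a
warning. Retrieval ranks database images by cosine similarity with ties
to the lower index.

## Synthetic data

`generate_stage_image` renders smoothed multiplicative exponential
speckle — the standard statistical surrogate for ultrasound texture —
pinned to mean intensity 0.25 so that stage ordering is driven by
structure, not speckle fluctuations. Stage defaults add 0/6/14/28
Gaussian foci of brightness 0.0/0.35/0.5/0.65 and 0/0/2/4 arc segments,
with stage-3 arcs placed on a circle that reaches the lower image border
(as basal-plate calcification does). Foci and arc counts are
non-decreasing in stage, and mean image intensity averaged over ≥ 20
images per stage is strictly increasing — the property that makes
staging learnable downstream. Per-image seeds derive from the master
seed via a counter, so generation is bit-reproducible and
order-independent.

The generator emulates only the statistical structure the classifier
exploits (four classes separated by the density/brightness of bright
structures on speckle). It does not model beamforming, attenuation,
shadowing, probe-dependent point-spread functions, anatomy, or
inter-patient variability; a passing benchmark therefore demonstrates
that the pipeline's machinery works end to end on separable texture
classes, not clinical-grade staging accuracy.

## Benchmark sizes

The end-to-end benchmark uses 30 images per stage at 128×128, dense
SIFT (step 8, patch 16 → 225 descriptors/image), PCA to 32 dimensions,
K = 64, layout `[(1,1),(2,2)]` and 10-fold CV — sizes chosen so a full
three-encoder comparison completes in minutes on one core while leaving
each training fold ≈ 24 000 descriptors for the vocabulary fit.
Empirically the Fisher vector scores highest, with VLAD and BoVW close
behind, mirroring the encoder ranking reported in the literature for
this task.

## Known limitations

- SIFT/DAISY/LIOP are this package's own implementations with the
  conventions above; they are deliberately plain (no orientation
  assignment, no affine adaptation) and are not drop-in replacements
  for other libraries' variants.
- LIOP's accumulation uses unit weights; the threshold-based weighting
  of the original formulation is a known deviation knob.
- The spatial layout implements concatenation over nested grids only;
  no learned or overlapping partitions.
- EM's variance floor technically breaks the monotone-likelihood
  guarantee in pathological cases; in practice the recorded trace is
  non-decreasing to 1e-10 and this is asserted in tests.
- Stochastic benchmark results are reproducible bit-for-bit only for a
  fixed seed, BLAS, and library versions.
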