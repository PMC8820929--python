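# Methods

## Problem and pipeline

Chlorophyll-fluorescence (CF) frames of potted wheat contain three
intensity populations: background at exactly 0, the pot at low
intensities (≈ 11–17), and the canopy, which starts dim and brightens
over the capture timeline and is depressed under water stress (with
more of the pot exposed). The analysis target is the canopy only, so
segmentation must discard both background and pot before texture
traits are computed.

The pipeline is: standardize the frame → dynamic elimination threshold
→ histogram-initialized 2-means → 23-trait GLCM panel → IoU evaluation
and trait statistics.

## Preprocessing

Images are 8-bit PNG/TIFF. RGB input is collapsed with the Rec. 601
luminance weighting (0.299, 0.587, 0.114); in CF data the channels are
nearly identical, so the choice is low-impact, and it is recorded in
`RunConfig.rgb_weights`. Frames are resized bilinearly to the analysis
frame (native 1388 × 1038); masks use nearest-neighbour so labels stay
binary. Intensities remain 0–255 integers through the histogram and
threshold stages; division by 255 (monotone) happens only at the
K-means stage, matching the algorithm's stated ordering.

## Dynamic threshold

The elimination threshold is a cubic polynomial of the image's index
*x* in capture order, with fixed published coefficients
(p₁ = 2.273e−08, p₂ = −4.118e−05, p₃ = 0.01699, p₄ = 11.95). The
polynomial was fitted externally to ~1188 hand-tuned thresholds; the
fitting data are not available, so the coefficients are taken as
given and re-fitting is out of scope. Interpretation of *x* at
inference time is a design choice: we use the image's position in the
full capture sequence, under which the raw polynomial stays inside
≈ 11.9–13.5 over x ∈ [0, 1188]. The raw value is clamped into
[11, 17] — the empirically stated elimination range — as a guard
against out-of-range indices. Thresholding is strict (`pixel < T` is
removed), so a pixel exactly at the threshold survives.

The static baseline (GST) uses T = 17 by default, the top of the
elimination range; no authoritative value exists, so it is
configurable. Otsu (GAT) maximizes between-class variance over the
fixed 256-bin 0–255 histogram; it is implemented in-package because
library implementations bin over the observed data range, which
changes the returned level on images that do not span 0–255. Ties take
the lowest maximizing level.

## CfitK-means

After thresholding at T(x), the occupied histogram levels strictly
above the cutoff initialize the two centroids: their mean (which sits
inside the canopy intensity mass) and their minimum (the dimmest
retained level). Lloyd iteration runs on normalized intensities for at
most 20 rounds, stopping when assignments are stable; an empty cluster
keeps its previous centroid (logged). The higher-centroid cluster is
labelled canopy, and pixels removed by the threshold are forced to
background regardless of cluster. Everything is deterministic given
the input — there is no random initialization.

Using the *level set* rather than the pixel mass for initialization is
a deliberate reading of the histogram-means construction: it places
one centroid near the dim (pot) end and one inside the canopy mass,
which is what makes the subsequent 2-means a pot/canopy split rather
than a split of the canopy itself. The 4-means baseline initializes at
quartile midpoints of the image's intensity range and merges all but
the lowest cluster into foreground.

## Texture panel

The GLCM is 9 × 9 by default. The source description of the
quantization is internally inconsistent (a "9∗9" matrix vs.
"quantization level of 3"); matrix dimensions are the operative
quantity in every formula, so Ng = 9 is used and Ng is configurable.
Quantization is equal-width binning of 0–255 into levels 1…Ng; grey
levels are 1-based in all formulas, which matters for level-weighted
traits (autocorrelation, sum average). Cooccurrence uses a single
displacement (0, 1) with symmetric accumulation; only pairs with both
pixels inside the canopy mask are counted. Four-direction averaging is
deliberately not the default (no authority for it); any offset can be
configured.

Entropies are base-2 with machine epsilon (≈ 2.2e−16) added inside
each logarithm, so empty cells contribute nothing and the one-hot
matrix gives exactly zero entropy.

Formula conventions, where the printed forms are impossible or
ambiguous:

- **sosvh** (sum of squares): the printed form is (1 − μ)², a constant
  across cells; the default computes the standard (i − μ)² variance.
  The literal printed form is available via
  `GLCMConfig(sosvh_standard=False)`.
- **dvarh** needs the mean of the difference distribution; the printed
  marginal-mean pair repeats μₓ₊ᵧ twice, so the second is implemented
  as μₓ₋ᵧ = Σ k·p₍ₓ₋ᵧ₎(k).
- **inf2h** is printed without a square root and that form is the
  default; the square-rooted variant, which is bounded in [0, 1], is
  available via `GLCMConfig(inf2h_sqrt=True)`.
- **senth** (sum entropy) is printed without a leading minus sign,
  which would make it negative for every distribution while its
  sibling difference entropy carries the minus; it is implemented as a
  proper entropy (with the minus).
- **corrm/corrp** denominators use σₓ·σᵧ with the respective marginal
  means; for a constant texture (σₓσᵧ = 0) both are returned as NaN
  rather than raising.
- **homop** and **homom1** are printed identically and both are
  computed (equal by construction) to preserve the 23-column schema.
- **idmnc** follows its printed normalization (i − j)²/Ng.

## Evaluation protocol

IoU = |target ∩ prediction| / |target ∪ prediction|. Two empty masks
agree perfectly on absence, so that case is defined as 1.0 with a
warning. The sampling protocol draws rounds of 25/50/75/100 images:
mutually exclusive (one seeded shuffle, consecutive slices) when the
pool holds their sum, otherwise independent seeded draws without
replacement within each round. Because the original aggregation is
ambiguous, the report carries both the per-round mean IoU and the mean
pooled over all evaluated images, plus the count of images above the
0.5 acceptability cutoff per round.

## Trait statistics

Correlation categorization uses the literal printed ranges
A (−1…0.09), B (0…0.49), C (0.5…0.89), D (0.9…1.0); they overlap, and
a trait may appear in several categories. The membership rule — a
trait is listed in a range iff at least one of its off-diagonal
correlations falls in it — is an interpretation and is recorded as a
flag on the output. Constant columns are flagged and excluded rather
than propagating NaN.

KMO is computed from the anti-image partial correlations
uᵢⱼ = −(R⁻¹)ᵢⱼ/√((R⁻¹)ᵢᵢ(R⁻¹)ⱼⱼ):
KMO = Σr²ᵢⱼ / (Σr²ᵢⱼ + Σu²ᵢⱼ) over i ≠ j. Bartlett's sphericity is
χ² = −(n − 1 − (2p + 5)/6)·ln det R with p(p − 1)/2 degrees of
freedom. Full factor analysis is deliberately not performed — these
are the suitability checks only.

Trait clustering treats the 23 columns as points whose coordinates are
the z-scored instances (sample sd, ddof = 1), with squared Euclidean
distances. Six of the seven linkage rules delegate to
`scipy.cluster.hierarchy`: single/complete/average run directly on the
squared-distance matrix; centroid/median/Ward run on the raw points in
Euclidean geometry and their merge coefficients are squared back onto
the squared-Euclidean scale (the convention under which centroid
linkage is the squared distance between centroids). The SPSS-style
within-groups average rule (merge the pair minimizing the mean of all
pairwise distances inside the merged cluster) has no scipy equivalent
and is implemented directly — O(n³), trivial at 23 variables. The
agglomeration schedule labels clusters by their lowest-numbered member
and records first-appearance and next-use stages; memberships are cut
at k = 3 and cluster ids are canonicalized by first appearance so
methods can be compared column-wise. Single-linkage coefficients are
non-decreasing by construction; centroid/median/within coefficients
may invert (a known property of those rules).

## Synthetic data

The scene generator emulates the structure of the real dataset, not
its optics: exact-zero background; a pot band across the bottom of the
frame with uniform integer intensities 11–17, taller under drought
(stress exposes more pot); a canopy of randomly oriented elliptical
blobs with truncated-Gaussian intensities bounded below at 18. The
canopy mean follows 32 + 0.8·day (control) and 26 + 0.55·day
(drought) with sd 4 — dim early, bright late, depressed under stress —
and drought scenes get fewer, smaller blobs. Noise, when enabled,
perturbs pot and canopy pixels only (background stays exactly 0) and
is clipped to [0, 255]; ground truth always refers to the noiseless
geometry.

With `noise_sd = 0` pot and canopy supports are disjoint (≤ 17 vs
≥ 18), so the canopy is exactly recoverable — by the full CfitK-means
pipeline, whose K-means stage relegates pot pixels surviving the
threshold (including the 17-valued ones a static threshold at 17
keeps) to the background cluster. This is what makes the generator a
calibration fixture: the hybrid segmenter should approach IoU 1 while
the static-threshold baseline retains a pot sliver. What passing these
tests does **not** show: robustness to blur, specular highlights,
overlapping leaves at pot level, sensor noise structure, or any real
CF optics — blob geometry is pure fixture design.

The trait-table generator draws multivariate-Gaussian rows with a
planted 3-block correlation structure (default blocks of 15/6/2
traits, matching the variance/homogeneity/information grouping the
traits fall into); it exists to give the statistics layer a known
answer, not to mimic real trait distributions.

Default frame is 347 × 260 (a 4×-downscaled native frame) so the full
suite runs in seconds; the native 1388 × 1038 is one argument away.
The bundled evaluation suite uses 100 scenes (50 control + 50 drought
over the 60-day schedule).

## Numerical choices and degeneracies

- Threshold comparison is strict `<`; Otsu ties take the lowest level.
- K-means: empty clusters keep their previous centroid; a constant
  image yields a single cluster and a constant mask.
- A threshold that removes every pixel yields an all-background mask
  with a warning, not an error.
- GLCM degeneracies (empty mask, no valid pair) raise `ValueError` at
  the operation level and are skipped with a logged reason at the
  table level.
- Sums of each GLCM marginal distribution are validated in tests to
  1e−9; oracle equivalence of the optimized pipeline against naive
  double-loop implementations is asserted to 1e−10 per trait.

## Known limitations

- The cubic threshold coefficients are frozen; applying the model to a
  differently scheduled capture sequence requires re-fitting, which
  this package does not do.
- The trait panel is computed at a single GLCM offset by default;
  orientation-sensitive textures will show offset dependence.
- Within-groups linkage is exact but cubic in the number of variables;
  it is intended for trait-level (tens of variables) clustering, not
  for clustering instances.
- Synthetic scenes do not model real fluorescence physics; conclusions
  about segmentation quality transfer to real data only insofar as the
  pot/canopy intensity separation holds there.
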