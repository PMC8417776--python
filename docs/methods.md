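# Methods

`lesionquant` quantifies the lesion burden of a whole-slide histology image
as the area ratio A_lesion / A_tissue, and compares treatment arms on that
ratio. This note records the model, its assumptions, the defaults and why
they are what they are, and what the synthetic benchmark does and does not
establish.

## Pipeline model

1. **Tissue extraction.** The slide is reduced to Rec. 601 luminance
   (0.299 R + 0.587 G + 0.114 B). A slide has a bright, near-white
   background and darker tissue, so the tissue mask is the *dark* side of
   the Otsu threshold — the intensity cut maximizing the between-class
   variance σ_b²(t) = ω₀ω₁(μ₀ − μ₁)² of the 256-bin histogram. Ties break
   to the smallest maximizing t; an all-one-intensity histogram has
   σ_b² ≡ 0 and is flagged degenerate (no tissue). The raw mask is cleaned
   by binary opening (disk r = 2 px, kills speckle), closing (disk r = 4 px,
   bridges narrow bright gaps such as sinusoids), removal of components
   below 256 px, and hole filling. A_tissue is the true-pixel count.

2. **Patch classification.** The tissue region is tiled by a sliding
   window of side P with stride S; candidate origins per axis are
   {0, S, 2S, …} plus the flush position (dim − P) so the window reaches
   the image edge, and a patch is retained when at least τ = 0.5 of it is
   tissue. Each patch maps to 12 texture features — per channel: mean,
   SD, and horizontal/vertical gradient energy (mean |difference| of
   adjacent pixels) — standardized by training statistics and scored by an
   L2-regularized logistic model. The model minimizes *mean* log-loss
   + (λ/2)‖w‖² (intercept unpenalized) by full-batch L-BFGS to gradient
   tolerance 1e−8: deterministic given the data, and invariant under
   duplication of training rows because the data term is a per-sample
   mean. λ defaults to 1e−3. The classifier is a deliberate stand-in for
   a patch CNN — deterministic and trainable in milliseconds, and fully
   sufficient for the two separable synthetic textures; anything
   implementing `predict_prob` over patch stacks drops into the same
   contract.

3. **Likelihood map and lesion mask.** Patch probabilities are accumulated
   per pixel and divided by the number of covering patches. This
   coverage-averaging *is* the normalization to [0, 1]: it is structural
   (a mean of probabilities), unlike global min–max rescaling, which would
   make the subsequent threshold depend on the slide's own extremes
   (min–max is retained behind `normalize="minmax"` but is not the
   default). The lesion mask is (likelihood ≥ θ) ∧ tissue ∧ covered, with
   θ = 0.9 inclusive; A_lesion is its pixel count and the burden ratio is
   A_lesion / A_tissue. A slide with A_tissue = 0 yields a missing ratio,
   never 0/0. Lesion count is the number of 8-connected components of at
   least 64 px.

4. **Group statistics.** Incidence = 100·k/n rounded half-up to one
   decimal. Two-arm contrasts use the pooled-variance two-tailed t-test
   (computable from printed means ± SD and n alone; Welch available by
   flag), plus Pearson χ² (no continuity correction by default; Yates
   optional) and Fisher's exact test on the 2×2 affected table. Three or
   more arms get one-way ANOVA with Bonferroni-corrected pairwise pooled
   t-tests as the post hoc step — chosen for determinism and simplicity.
   Distribution functions come from scipy.stats (documented accuracy well
   below 1e−6). A slide counts as "affected" when at least one lesion
   component survives the minimum-area filter.

## Why P = 8, S = 4

Thresholding a coverage-averaged map at a high θ biases the recovered
boundary inward. Near a straight lesion boundary the map value at signed
depth d (positive inside) is approximately the fraction of covering
patches whose content is mostly lesion, a ramp of width ≈ P centred where
the classifier flips; the θ = 0.9 level set therefore sits ≈ (c − 0.1)·P
inside the true boundary, where c is the lesion fraction at which the
classifier's probability crosses ½. The area deficit is ≈ perimeter ×
that offset, so the patch must be small relative to a lesion diameter for
unbiased area recovery. On 512-px synthetic slides with blob radii of
60–170 px, P = 64 would put the offset at tens of pixels (ratio bias far
beyond any useful tolerance), P = 16 measures ≈ −0.02 mean ratio bias,
and P = 8 ≈ −0.01 with lesion-mask Dice ≥ 0.9 down to planted fraction
0.05. P = 8, S = 4 (50 % overlap) are therefore the defaults; both are
plain config knobs, and real gigapixel slides with centimetre-scale
lesions would tolerate much larger patches for the same reason.

## Synthetic slides

No suitable public whole-slide corpus with lesion annotations exists for
this setting, so the benchmark substrate is generated: a near-white
background (intensity 244), one smooth dark-pink tissue blob (an ellipse
with a low-frequency radial perturbation, ~60 % of the canvas), and
bluish lesion blobs grown inside it. Blobs grow by frontier dilation with
random acceptance (rough, connected, non-circular shapes), with the last
step taking exactly the shortfall, so the planted fraction matches the
target to within the stated tolerance (default 0.02) or an explicit
"unachievable fraction" error is raised — never a silent miss. Lesions
are separated from each other and from the tissue border by a small gap,
keeping lesion ⊆ tissue by construction. Texture: normal parenchyma is
pink (228, 168, 188) with low-frequency mottling; lesions are
blue-purple (158, 130, 196) with extra high-frequency speckle
(SD 22), so the two classes differ in hue *and* texture energy; dark
nuclei dots (1.2 per 1000 px² of tissue) and global Gaussian noise
(SD 7) are superimposed. Everything derives from one seeded generator
per call: identical (spec, seed) gives bit-identical output.

Cohorts draw per-animal target fractions i.i.d. from a scaled
Beta(mκ, (1−m)κ) law with concentration κ = 50 (SD ≈ 0.056 at mean 0.20,
≈ 0.037 at mean 0.075 — a realistic animal-to-animal spread that leaves a
two-arm design of n = 9 vs 7 well powered), or from a point mass for
degenerate designs.

**What the generator does not emulate:** staining variation, pyramid/
multi-resolution formats, stain deconvolution targets, lesion subtype
morphology, tissue folds and scanner artefacts, and any realistic CNN
training distribution. Passing the recovery suite shows the *pipeline
machinery* (segmentation, tiling, accumulation, thresholding, statistics)
is correct and unbiased at the stated scales; it says nothing about
classifier performance on real histology.

## Numerical and procedural choices

- Otsu is computed vectorized over all 256 cuts; the test suite holds it
  to an exhaustive plain-Python argmax oracle, exactly, including ties
  and the degenerate flag.
- Grid origins are row-major sorted and unique; with τ = 0 and S ≤ P the
  grid covers every pixel (flush rule), asserted as a property.
- `fit_classifier` starts from θ = 0, so refits are bit-reproducible; a
  single-class training set is an error, not a warning.
- Probabilities are validated to [0, 1] on entry to map accumulation;
  map values are exactly 0 where coverage is 0.
- Degenerate statistics are flagged rather than NaN-propagated: both-SD-
  zero t-tests (p = 1 when means agree), all-identical ANOVA (F
  undefined), zero-margin 2×2 tables (error).
- The χ²-vs-permutation validation uses the hypergeometric permutation
  null with the mid-P tie convention and large-count tables: the
  asymptotic χ² p approximates the *mid-P* of the discrete conditional
  law, and for small tables (total ≲ 50) the discrete law itself sits far
  from the asymptotic value, which no amount of Monte-Carlo precision
  changes.
- Experiment sizes in the validation suites — 20 slides per fraction at
  512 px for recovery, 20 cohort replicates for power, 200 draw
  replicates for the null rate — were chosen so Monte-Carlo error is
  comfortably below the asserted margins while the whole suite stays in
  the minutes range.

## Known limitations

- The reference classifier is linear in 12 fixed texture features; real
  lesion/parenchyma boundaries that differ only in higher-order structure
  would need the pluggable-CNN route.
- Boundary bias of the θ = 0.9 rule is reduced, not removed, by small
  patches; ratios carry a residual ≈ −0.01 at the synthetic scales.
- Patches straddling the tissue boundary keep their background pixels in
  the features (simplicity; τ controls how much boundary is classified).
- Processing is single-resolution; downscaling a gigapixel slide is the
  caller's responsibility.
- The reported real-study group ratios cannot be recomputed here because
  the original slides are not public; the printed-count statistics
  (incidences, pooled-t on lesion-count summaries) are recomputed exactly.
- On the 9/9-vs-4/7 incidence table itself the categorical tests give
  p ≈ 0.029 (χ², df = 1) and p = 0.0625 (Fisher exact, two-sided),
  whereas the pooled two-tailed t on the per-animal lesion-count
  summaries (12.0 ± 10.07, n = 9 vs 2.86 ± 5.43, n = 7) gives
  p = 0.0487: a quoted 0.0487 for that comparison corresponds to the
  t-test on counts, not to a test of the incidence proportions. Both
  routes are implemented; which one a given study ran must come from its
  authors.
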