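# Methods

This note records the model choices, parameter conventions and numerical
decisions behind `sanqigrade`, and what the synthetic-data experiments do and
do not demonstrate.

## Grade derivation

Assay values are clustered univariately (total saponin content only) with
agglomerative average linkage (UPGMA — the standard reading of SPSS's
"between-groups linkage") on squared Euclidean distances. Cutting one
dendrogram at every K guarantees nested partitions, so the distortion curve
J(K) is non-increasing and J(n) = 0.

**Elbow detection.** The elbow is scored by the *relative* second forward
difference Δ²J(K)/J(K) with Δ²J(K) = J(K−1) − 2J(K) + J(K+1), ranked
descending over K ∈ [2, Kmax−1]. The raw second difference is dominated by
the K = 1 → 2 drop whenever the one-cluster distortion is large — on
well-separated three-cluster data it ranks K = 2 first even though the
visually prominent bend sits at K = 3. Dividing by the remaining distortion
measures the bend relative to what is left to explain and recovers the
visual elbow; the raw statistic remains available (`normalize=False`). A
flat or exactly linear curve yields no candidates.

**Boundary construction.** Clusters sorted by mean content become grades
1..K (grade 1 = lowest). Each internal boundary is the midpoint between the
adjacent cluster extents, rounded to integer mg/g by default to match how
published grading tables are printed; outer bounds are the observed min/max.
Intervals are lower-closed/upper-open with the top interval closed, so a
shared endpoint belongs to the higher grade, and out-of-range values clamp
to the boundary grades (logged). The published 3/5/6-grade boundary tables
(54, 66, 85, 101, 129, 150, 162 mg/g) ship as constants because the raw
143-sample assay set is not deposited and the boundaries cannot be
re-derived.

## Feature extraction

* **Color.** Hue uses the arccos formulation with the standard
  H ← 360° − H correction when B > G (the bare formula only spans
  [0°, 180°]); achromatic pixels get H = 0 by convention. Saturation is the
  HSI form 1 − 3·min(R,G,B)/(R+G+B), 0 on black pixels. CIELAB a/b use sRGB
  gamma linearization, the standard 4-decimal sRGB→XYZ matrix, and the CIE
  piecewise f with threshold (6/29)³. The reference white is the matrix's
  own image of (1,1,1) — numerically the D65 white (95.047, 100.0, 108.883)
  up to rounding — so neutral grays map *exactly* to a = b = 0 instead of
  picking up ~10⁻³ offsets from mismatched tabulations.
* **Moment scaling.** Before computing moments the seven channels are
  mapped to [0, 1] (H/360, S as-is, a and b affinely from [−128, 127]) so
  all 14 features share a scale. σ uses the population (1/N) normalization,
  matching the root-of-mean-square-deviation definition.
* **Grayscale.** ITU-R BT.601 luma (0.299R + 0.587G + 0.114B), quantized to
  8 bits, feeds both texture extractors and the Otsu foreground threshold.
* **Uniform LBP.** 8 neighbors on the 3×3 square window, ordered clockwise
  from the top-left with p = 0 weighting 2⁰; ties (neighbor = center) score
  1, so a constant image maps entirely to code 255. The u2 table gives each
  of the 58 patterns with ≤ 2 circular transitions its own bin in ascending
  code order plus one catch-all (59 bins, verified by exhaustive enumeration
  of all 256 codes). Codes whose window touches background are dropped; the
  histogram is normalized to sum 1 over the remaining pixels.
* **Gabor bank.** 5 scales × 8 orientations; orientation θᵥ = vπ/8, scale u
  at center frequency 0.25/√2ᵘ cycles/pixel, envelope σ = 0.56·λ, aspect
  ratio 0.5, 31×31 kernels (all configurable). Kernels are DC-compensated
  (zero response to flat regions) and L1-normalized; convolution uses
  reflect padding via FFT. The per-filter statistic is the *mean* response
  magnitude over foreground pixels, making energies image-size invariant;
  energy therefore scales linearly with image contrast.
* Background pixels are excluded from moments, LBP counts and Gabor means
  throughout; masking can be disabled in configuration.

## Dataset preparation

The stratified split fixes the total training size at round(n·fraction) and
allocates per-class quotas by largest remainder, so 143 samples at 80 % give
exactly 114/29. SMOTE is implemented directly from its interpolation rule;
nearest neighbors are found in z-scored feature space (training-fold
statistics) while interpolation happens in the original space, so synthetic
rows are exact convex combinations of same-class originals. Every row
carries a provenance flag and test partitions/evaluation folds are asserted
synthetic-free. Balancing targets are explicit configuration (default: up to
the majority class size).

Feature-selection importances: random-forest impurity importance
(500 trees), |Pearson r| against the numeric grade label, k-NN mutual
information (k = 3, on z-scored features), recursive feature elimination
(tree ensemble, step 1, importance = reverse elimination order) and XGBoost
total gain. Importances are normalized to sum 1; the minimal descending
prefix reaching 60 % cumulative mass is kept (ties broken by original
index), which makes the selected set monotone in the threshold.

## Modeling and tuning

The registry ships five installed tree-ensemble learners: extremely
randomized trees, a random-forest baseline, XGBoost, LightGBM and
scikit-learn's histogram gradient-boosting classifier. An ordered-boosting
(CatBoost-style) learner is not included; the registry is a plain mapping
and accepts additional entries. Canonical hyperparameter names
(learning_rate, depth, iterations, l2_leaf_reg) are translated per
algorithm so one PSO search box drives any of them.

Metrics follow the binary confusion-matrix identities macro-averaged
one-vs-rest for multi-class data; AP accumulates precision over recall
increments along the descending-score ranking (ties broken by sample index)
and matches scikit-learn's step-wise average precision on untied scores.
Variability is the 1/(n−1) standard deviation across folds or runs.

Cross-validation is stratified and, by default, refits balancing and
feature selection inside each training fold. A compatibility flag instead
balances the whole set before partitioning — the protocol some grading
studies report — which leaks synthetic interpolations of test samples into
training and typically inflates scores; it is provided for comparison and
flagged as methodologically weaker.

PSO uses the canonical global-best update (w = 0.72, c1 = c2 = 1.49,
20 particles, 30 iterations by default — values absent from the grading
literature are standard textbook settings), clamping positions to the box
and zeroing the velocity on clamped dimensions; integer dimensions round
only at objective evaluation. One particle starts at the incumbent
hyperparameters, so tuning can never fall below the default configuration.
Fitness is accuracy on a seeded inner validation split (default 25 % of the
training partition), never the outer test set.

## Synthetic data

`gen_pns` draws from a truncated normal on [54, 162] mg/g whose
pre-truncation parameters (μ₀ ≈ 87.73, σ₀ ≈ 36.51) are solved numerically so
the *realized* distribution has mean 97.3 and sd 25.9 — the published survey
statistics. A two-parameter truncated normal cannot simultaneously reach the
published median of 102 mg/g: median > mean requires left skew, but with
these moments the left truncation binds harder and forces right skew, so the
realized median is ≈ 95 mg/g. This is a known, accepted deviation; the
survey's reported median and >80 % concentration in 80–140 mg/g suggest the
real population is left-skewed or multimodal, which the optional mixture
model can represent. Mixture components are truncated normals with supplied
(weight, center, spread).

`gen_slice_image` renders an ellipse on a dark field whose base hue slides
monotonically from yellow-green (65°) to orange-brown (25°) across the assay
range, with saturation, speckle frequency and speckle contrast rising
alongside, plus Gaussian pixel noise (sd 0.02). The appearance–chemistry
link is a *modeling fiction chosen for testability*: no published
quantification of how slice color and texture co-vary with saponin content
exists, and the planted monotone relationship is deliberately strong.
End-to-end tests therefore demonstrate that the pipeline recovers a planted
signal without leakage — not that real slices are gradable at any particular
accuracy. Real cross-sections additionally show radial structure, cambium
rings, specular highlights and illumination drift that the generator does
not emulate.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by design: the
end-to-end grid uses 96 synthetic 64×64 images with a reduced grid
(2 algorithms × 2 feature sets × the 3-grade scheme), elbow-recovery uses
n = 143 as in the original survey, and generator calibration uses 10,000
draws. All randomness flows through explicit seeds; the pipeline fans a
single master seed out to per-stage seeds through a CRC-based hash so
toggling one stage leaves the others' draws unchanged.

## Known limitations

* The generator's median deviation described above.
* Published headline accuracies for the original 143-sample image set are
  not reproducible here: the images were never deposited, so desk-scale
  validation rests on synthetic data.
* Grade-boundary rounding (integer mg/g) can shift a boundary across a
  sample that sits within 0.5 mg/g of a cluster gap midpoint; use
  `precision` > 0 when exact round-trips matter.
* The univariate clustering deliberately ignores the five individual
  saponin components; a multivariate profile would need its own linkage
  validation.
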