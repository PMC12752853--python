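# Methods

## Model and assumptions

The package treats a grayscale image as the superposition of oscillatory
components at decreasing spatial frequency plus a slow trend, and treats
intensity as a mass distribution whose local scaling behavior carries the
texture information. Two procedures implement this view:

1. **BEMD** — a data-driven decomposition with no fixed basis. Its only
   assumptions are that the surface has enough local extrema to define
   envelopes and that the sifting iteration contracts (a property that is
   empirical, not proven, for mode decompositions in general).
2. **Moment-method multifractal analysis** — assumes approximate scale
   invariance of the box masses over the analyzed size range, i.e. that
   the log-log regressions are close to linear. The per-q coefficient of
   determination is reported so that departures are visible rather than
   silent.

## Decomposition details

- **Extrema.** Default is regional extrema by morphological
  reconstruction, with each plateau represented by the plateau pixel
  nearest its centroid. Strict neighbor comparison is available for
  parity checks but discards plateaus entirely (on a checkerboard it also
  depends strongly on connectivity: under 8-connectivity diagonal ties
  eliminate all strict extrema).
- **Envelopes.** Scattered-data interpolation with a thin-plate-spline
  RBF plus a degree-1 polynomial tail (exact on constants and planes).
  Extrema within `boundary_pad` (default 8) pixels of the border are
  mirrored across it before fitting, which emulates evaluating on a
  mirror-padded image and tames edge divergence.
- **Envelope cost.** The dense RBF solve is O(m³) in the number of
  centers m. Above `max_rbf_centers` (default 1500) the centers are
  subsampled uniformly with a fixed seed; 1500 centers fit and evaluate a
  128×128 grid in well under a second on one CPU, and the interpolation
  exactness contract then applies to the retained centers. The cap is a
  complexity choice, configurable for small images where exact
  interpolation of every extremum is wanted.
- **Stopping.** `sd_max = 0.2` sits inside the conventionally recommended
  band (0.02–0.3) for the SD criterion; the per-mode iteration cap is 10
  and every cap hit is logged (`stop_reason: "cap"`), so no mode is ever
  accepted silently without meeting the criterion. Eligibility requires
  at least 3 maxima and 3 minima — the minimum for an RBF fit with a
  linear tail — which is stricter than the classical "at least one
  maximum and one minimum" and therefore governs.
- **Determinism.** Identical input and config give bit-identical stacks;
  the only internal randomness (center subsampling) is seeded by the
  center count.

## Spectrum estimation details

- **Measure.** A box's mass is the sum of gray levels inside it — the
  standard gray-mass box measure. A pixel-count measure would be
  degenerate on full grids (every box equal), so gray mass is the only
  reading that produces nontrivial spectra.
- **Signed modes.** BIMFs oscillate around zero. `shift_min` subtracts
  the global minimum (plus ε = 10⁻⁹ × range, so no box mass collapses to
  exactly zero) *only when the minimum is negative*; an already
  nonnegative image is used as-is, so a constant positive image keeps its
  uniform box probabilities. `rescale_unit` maps the range onto [ε, 1].
- **Grids.** Boxes are anchored at the top-left corner and trailing
  partial boxes are discarded. Defaults: sizes 2..64 step 2, q in the
  open interval (−4, 4) step 0.1. q = 0 and q = 1 go through their
  uniform/limit forms, never the generic power formula; large |q| is
  computed in log space (softmax), keeping Σμ = 1 to machine precision.
- **Partial-box bias.** Discarding trailing boxes biases log N(s) when s
  does not divide the side (on a 128² constant image the default step-2
  sizes give α(0) ≈ 2.12 rather than 2). Oracle and control checks
  therefore use power-of-2 sizes on dyadic images, where the scaling
  relation is an exact line; on dyadic cascades the estimator then
  reproduces the closed form to machine precision at any depth.
- **Conventions.** Δf = f(α_max) − f(α_min) (α_max is attained at the
  most negative q since α(q) is non-increasing). The scalar "α" reported
  per mode is α(q = 0), the spectrum's apex; f(α) is f(q = 0). A
  monotonicity violation of α(q) beyond 10⁻⁶ is logged.
- **Box-range selection.** Candidate (s_min, s_max) windows are scored by
  the R² of the q = 0 regression; ties break toward the widest window,
  then the smallest s_min.

## Synthetic data: what it emulates, what it does not

- **Multiplicative cascade** (`generate_binomial_cascade`): base-2,
  four-subcell cascade with per-cell shuffled weight placement — the
  estimator oracle, since α(q) and f(q) have closed forms depending only
  on the weight multiset. Shuffling makes realizations spatially
  heterogeneous without changing the spectrum.
- **Slow/fast demo signal**: a Gaussian bump plus cos/sin oscillation on
  [−π, π]² (the domain is a configurable choice), used to verify that
  sifting separates fast from slow components.
- **fBm surface**: spectral synthesis with power ∝ frequency^−(2H+2),
  standardized; a narrow-spectrum control only, so exactness of
  increments is not pursued.
- **Two-class dataset**: cascade realizations (weights (0.4,0.3,0.2,0.1)
  vs (0.7,0.1,0.1,0.1), depth 7 → 128×128), rescaled to mean 1 (an affine
  gain that leaves box probabilities unchanged), plus a polynomial
  background bump (amplitude 0.5) and Gaussian noise (σ = 0.02) — noise
  small relative to the cascade fluctuations so that the first mode
  carries class structure, as in textures whose fine scales are
  informative. Per-image seeds come from
  `numpy.random.SeedSequence(master).spawn(i)`, so any image can be
  regenerated alone.

What passing these tests shows: the estimators recover known spectra, the
decomposition satisfies its contracts, and the pipeline separates
populations that differ in multifractal structure. What it does not show:
performance on clinical images — the synthetic textures have no lesion
morphology, breast-density variation, acquisition noise correlation, or
annotation noise. Mode mixing (one BIMF carrying several scales) is a
known limitation of empirical mode decompositions and is not corrected
here.

## Classification protocol

The evaluation protocol is the package's own design: stratified 5-fold
outer cross-validation; inside each training fold, median imputation
(absent modes are explicit NaNs, never zeros), standardization, and an
inner 3-fold grid search over an 8×8 log-spaced (C, γ) grid within
C ∈ [0.5, 1156666], γ ∈ [0.0722, 16]. Metrics are computed on pooled
outer-fold predictions; ROC scores are SVM decision-function values.
Preprocessing statistics never see test folds. Ties at the threshold
rule's boundary are negative (the rule is strictly "lower than").

## Problem sizes

The shipped study runs 40 images per class at 128×128 with 5-fold CV
(about four minutes on one CPU); reconstruction checks use ten 128×128
cascades, and the spectrum oracle uses one 512×512 depth-9 cascade. These
sizes give the estimators several decades of scaling while keeping a full
run in minutes.

## Known limitations

- Envelope quality, and hence mode content, depends on the RBF kernel and
  the boundary treatment; very anisotropic textures may need a larger
  `boundary_pad`.
- The moment method estimates the Legendre transform of the coarse
  spectrum; it cannot resolve non-concave singularity spectra.
- The pointwise Hölder map is a diagnostic, not an estimator with
  guarantees: window-based regression smooths singularities below the
  smallest radius.
- With default step-2 box sizes, non-divisible image sides incur the
  partial-box bias described above; power-of-2 sizes on power-of-2 crops
  avoid it.
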