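# Methods

## Problem and model

`ctiqa` treats slice quality assessment as supervised regression: a
39-dimensional hand-crafted descriptor `x` of a preprocessed grayscale
slice is mapped to a continuous quality score `y ∈ [0, 4]` by an
RBF-kernel support-vector regressor, `ŷ = clip(f(x), 0, 4)`. The score
scale follows the radiologist convention for low-dose CT: 0 bad, 2
borderline, 4 anatomically evident. No reference image is used at any
point (no-reference / blind IQA). A second stage sharpens slices
predicted at or below 2 and re-scores them with the same model.

## Preprocessing

Images are resized to 224 × 224 with bilinear interpolation (both axes
forced, aspect ratio not preserved), min–max normalized per image to
[0, 1], then quantized to 8 bits as `round(255·x)`. Per-image rather
than dataset-global normalization is used: CT slices exported through a
fixed soft-tissue window already share an intensity scale, and per-image
scaling makes the descriptor insensitive to residual window offsets. A
constant image maps to all zeros (the min–max scale is degenerate
there). Preprocessing order is resize → normalize → quantize.

## Feature views and conventions

Which pixel view each group uses is a convention of this package:
intensity, frequency and diagnostic features are computed on the [0, 1]
float view; histogram, GLCM and LBP features on the 8-bit view (these
are inherently discrete-level statistics).

Choices worth calling out:

* **Edge statistics.** `edge_mean`/`edge_variance` are moments of the
  Sobel gradient magnitude, not of the binary Canny map (whose mean is
  redundant with `edge_count`). Canny runs at σ = 1.0 with hysteresis
  thresholds at the 70th/90th gradient-magnitude quantiles, so the
  detector is invariant to the image's absolute contrast.
* **Region shape.** The region is the largest connected component of
  the 3 × 3-closed Otsu foreground. Its perimeter is the Crofton-style
  estimate (`skimage.measure.perimeter`); a raw boundary-pixel count
  systematically overestimates circularity of smooth shapes (a
  digitized disc would score ≈ 1.25 instead of ≈ 0.92), violating the
  isoperimetric bound the descriptor relies on.
* **Diagnostic cues.** The five named cues are fixed to standard CT-IQA
  readings: sharpness = variance of the 4-neighbor Laplacian response;
  tissue density = mean foreground intensity; heterogeneity = mean
  local standard deviation in a 7 × 7 window; SNR = μ/σ over the
  foreground; CNR = (μ_fg − μ_bg)/σ_bg. All degenerate to 0 when the
  relevant mask or denominator vanishes.
* **Frequency statistics** exclude the DC coefficient — otherwise sum
  and mean are dominated by mean intensity and carry no quality signal.
  Spectral flatness is the geometric/arithmetic mean ratio of the power
  spectrum (+1e−12 floor). Note its white-noise value is e^(−γ) ≈ 0.56,
  not 1: the power of a white spectrum is exponentially distributed, and
  the GM/AM ratio of an exponential is e^(−γ). The feature is still
  monotone in "noisiness", which is what the regressor uses.
* **GLCM** uses 256 native gray levels, a single (0, +1) offset
  (distance 1, angle 0°), unsymmetrized, normalized to probabilities.
  Correlation of a degenerate (single-marginal) matrix is defined as 1.
* **LBP** is the classic non-rotation-invariant code: 8 neighbors on a
  radius-1 circle, sampled counter-clockwise from east with bilinear
  interpolation (offsets rounded to 8 decimals so axis-aligned
  neighbors land on pixel centers), bit set when neighbor ≥ center with
  1e−6 slack so equality — e.g. a constant image — yields code 255.
  A border of width 1 is excluded. The implementation is vectorized
  in-package and tested for exact equality against a scalar double-loop
  reference; the skimage variant differs at borders and exact ties.

## Training protocol

80/20 shuffle split (`round(0.8·n)` train rows, seed-driven). Features
are z-scored with training statistics inside the model pipeline.
Hyperparameters are tuned by exhaustive grid search over
C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.001, 0.01, 0.1},
ε ∈ {0.01, 0.1, 0.2}, minimizing 5-fold CV MSE; random search draws 25
configurations from the same space. Feature selection is permutation
importance on the held-out split (mean MSE increase over 10 seeded
permutations); the top 25 features are kept (ties broken by canonical
feature order) and the model retrained on them. 100-fold
cross-validation aggregates per-fold metric reports by unweighted mean;
folds too small to define a metric (size-1 folds have no rank
correlation) are excluded from that metric's aggregate.

## Metrics

MSE, MAE, RMSE and median absolute error follow the 1/N conventions;
R² = 1 − Σ(a−p)²/Σ(a−ā)²; explained variance uses population variance
(consistent with the 1/N MSE convention). PLCC is Pearson's r; SROCC is
Pearson's r on mean (fractional) ranks, which equals the classic
1 − 6ΣR²/(S(S²−1)) form exactly when no ties exist; KLCC is Kendall's
τ_b = (S_c − S_d)/√((S_c+S_d+T_p)(S_c+S_d+T_a)), with doubly tied pairs
counting toward neither tie term. Metrics that are undefined on an
input (correlation of a constant vector, R² of a constant target) raise
a typed `UndefinedMetricError`; the batch evaluator records them as
missing with a warning instead of propagating NaNs.

## Enhancement

Sharpening subtracts a fraction k of the 4-neighbor Laplacian response
(reflect-padded) and clips to [0, 1]; k defaults to 0.3 — strong enough
to visibly raise Laplacian-variance sharpness on blurred slices without
ringing on 8-bit CT windows — and an 8-neighbor kernel is available.
Clipping (rather than rescaling) preserves the intensity calibration of
untouched regions. The gate is inclusive: predicted score exactly 2.0
is enhanced. Gating is single-pass; re-scored images are not re-gated.

## Synthetic phantoms

Each clean phantom is a dark field with a bright body ellipse, 2–5
interior "organ" ellipses of varying intensity, and a bright upper arc
standing in for a bone rim, lightly smoothed (σ = 1.5). Degradation
follows a 4 × 4 grid: additive Gaussian noise with
σ ∈ {0, 0.02, 0.05, 0.10} for levels 0–3 and 4·level random straight
streaks of alternating ±0.15 amplitude, applied in the order streaks →
noise → optional Gaussian blur (blur last: a soft reconstruction
smooths anatomy, artifacts and noise alike), then clipped to [0, 1].
The ground-truth score is
`clip(4 − 0.8·noise − 0.5·artifact − 0.6·blur + u, 0, 4)` with
u ~ U(−0.15, 0.15) playing the role of rater noise; the coefficients
make the 16-cell grid with blur up to 1 span the full 0–4 band.
`make_dataset` tiles the 16 (noise, artifact) cells evenly over n
samples with blur σ drawn from {0, 0.5, 1.0}; everything is pure in the
seed.

What the phantoms do **not** emulate: projection-domain physics (streaks
here are image-domain lines, not FBP artifacts), anatomical variability,
scanner-specific noise texture, and a human rater's nonlinear response.
Passing tests therefore show the pipeline recovers a known monotone
quality signal from images with CT-like degradations — not clinical
performance on real LDCT data, whose headline numbers require the real
scored dataset.

## Study sizes and evaluation choices

The end-to-end recovery check uses a 400-phantom dataset (80/20 split),
where the tuned top-25 SVR reaches held-out SROCC ≈ 0.93–0.96 and MSE
well below the score variance. The enhancement-efficacy check uses 120
blur-dominated low-quality phantoms (noise level 0, artifact level 3,
blur σ cycling {1.0, 1.5, 2.0}): those gated at predicted ≤ 2 gain on
average ≈ +0.03 to +0.12 in re-scored quality across seeds, and
Laplacian-variance sharpness rises for every enhanced image.

A known limitation shapes that choice: unsharp-style enhancement
amplifies noise and streaks along with anatomy, so on noise-dominated
low-score phantoms the re-scored quality typically *drops* — the model
correctly recognizes amplified noise as lower quality. Score-gated
sharpening is a remedy for smoothing-type degradation, not for noise;
deploying it in practice would warrant a noise-aware gate.

## Numerical notes

* All extractors are deterministic and seed-free; identical inputs give
  bit-identical feature vectors.
* Histogram mode ties resolve to the smallest intensity; skewness and
  kurtosis (excess, population moments) are defined as 0 at σ = 0.
* Predictions are clamped to [0, 4] after regression; no prediction can
  leave the score scale.
* Model bundles embed a format-version string and refuse to load
  mismatched versions; a clear-text JSON sidecar lists the selected
  features and hyperparameters for audit.
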