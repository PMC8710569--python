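# Methods

This note documents the model, the numerical choices, and the limits of
the synthetic stimuli. Defaults quoted below are the package defaults;
everything is overridable through the public APIs and `RunConfig`.

## Coordinate conventions

Images are square, values in [0, 1]. The visual field spans 40° of
diameter (`FULL_FIELD_DEG = 40`), so one pixel covers `40 / size_px`
degrees. The field is the inscribed circular aperture of radius
`size_px / 2` pixels (20°) around the center `(size_px − 1) / 2`; x grows
rightward and y upward in degree coordinates. All area-based quantities
(mask fractions, the Blind Field Index) are computed over this aperture,
never over the full square.

## Synthetic scene categories

Each scene is Fourier-shaped Gaussian white noise: the amplitude spectrum
is the product of a radial `1/f^α` falloff (α = 1 by default, matching
natural-image statistics) and a band-weight profile defined on an
orientation × spatial-frequency grid. Orientation weights are
interpolated circularly over [0, π); spatial-frequency weights are
interpolated in log frequency between octave-spaced band centers. The DC
component is zeroed and the image min–max normalized to [0, 1].

The two default categories differ only in orientation profile: category A
weights cardinal orientations (0°, 90°) up by a factor `category_strength`
and category B weights obliques (45°, 135°). `category_strength = 1.5`
was chosen so that clean classification performance is high but finite
(d̂′ in the single digits rather than effectively infinite), leaving
dynamic range for degradation to act on. The generator reproduces
second-order (spectral) scene structure only — no phase structure, no
objects, no scene layout; see Limitations.

`equalize_set` matches every image's mean and standard deviation to the
set's grand mean and mean standard deviation before clipping, so that
first-order luminance/contrast cues cannot drive classification.

## GIST descriptor

Preprocessing: luminance conversion, resize to the bank's size, local
contrast normalization `d / (0.01 + local_sd)` with a Gaussian window
(σ = size/16, periodic boundary), then min–max scaling; a constant image
maps to uniform 0.5.

The bank holds 48 log-Gabor filters (8 orientations × 6 scales). Radial
profiles are log-Gaussians (σ-ratio 0.65) around octave-spaced center
frequencies descending from 0.25 cycles/pixel; angular profiles are
raised-cosine lobes of half-width 1.3·π/8, single-lobed in the half-plane
so each filter is analytic and its complex response magnitude is an
envelope. DC gain is exactly zero for every filter. Response magnitudes
are averaged over a 4×4 grid of blocks, giving 6 × 8 × 16 = 768 features
ordered scale-major, then orientation, then row-major blocks.

## Degradation

- **Pink noise**: amplitude envelope ∝ 1/f, DC zeroed, mean-subtracted,
  unit variance. `apply_snr` scales the field so
  `10·log10(var_signal / var_noise)` equals the requested level *exactly*
  before the final clip to [0, 1]; default levels are
  {−2, 5, 10, 25} dB.
- **Field-defect occlusion**: binary rasters from geometric generators
  (hemifield and quadrant masks split the aperture at the meridians) or
  from perimetry. Occluded pixels are replaced by a fill value, defaulting
  to the equalized set mean (mean-gray behind the mask).
- **Perimetry path**: simulated grids use the standard Humphrey 30-2
  lattice (76 points, 6° spacing) with floor 0 dB inside the defect and
  ceiling 30 dB outside, optional Gaussian jitter. Lattice points beyond
  the raster's 20° aperture are sampled at 0.95 × the aperture radius
  along the same direction. Rasterization interpolates the point set by
  triangulation-based linear interpolation with nearest-neighbor fill
  outside the convex hull, and marks pixels blind below a 10 dB
  sensitivity threshold.

## Model observer

A linear SVM (`LinearSVC`, `dual=False`, `tol=1e-6`, `max_iter=20000`,
squared-hinge loss) on standardized GIST features; standardization
statistics come from the training set only, and zero-variance features get
unit scale. The frozen model is four arrays (weights, intercept, feature
mean, feature scale) serialized to JSON. Ties on the decision boundary go
to class 0.

Model sensitivity d̂′ is estimated two ways:

- `gaussian_decision_values` (default): `(mean₁ − mean₀) / pooled SD` of
  the decision values (equal-variance Gaussian assumption; degenerate
  spreads return 0);
- `rate_based`: hit/false-alarm rates of the hard classifications pushed
  through the same d′ estimator used for human data.

`semi_random_split` assigns each participant a balanced, per-participant
disjoint stimulus subset per condition, refilling from the pool (excluding
a participant's own draws) when the pool is exhausted across participants.

## Signal-detection statistics

- d′ = z(H) − z(FA), criterion c = −(z(H) + z(FA))/2. The log-linear
  correction (add 0.5 to every cell) is applied **only** when a rate is
  exactly 0 or 1; regular tables are untouched.
- One-sample t-tests on per-condition sensitivity differences r̂ are
  accompanied by the BIC-approximation Bayes factor
  `BF01 = √n · (1 + t²/(n−1))^(−n/2)`; at t = 0 this is √n.
  |ln BF| > 4.6 is labelled strong evidence.
- Multiple comparisons use Benjamini–Hochberg FDR (q = 0.05 default);
  NaN p-values (participants with too few usable conditions) are excluded
  from the family.
- BFI = (blind aperture fraction) × (−1); a field is hemianopia-like when
  BFI < −0.375 (strict inequality, so −0.375 itself classifies as
  quadrant-like).

The pipeline's `model_rates` observer mode simulates humans directly from
the classifier's per-condition rates; those rates receive the same
extreme-rate shrinkage as the d′ estimator and none otherwise, so the
null path (observer ≡ model) is exactly self-consistent.

## Problem sizes and runtime

Development and tests run at desk scale: 128 px images, 50 training and
100 pool images per class, 48-filter banks. One GIST extraction costs
≈ 15 ms at 128 px and ≈ 0.1 s at 256 px on a single CPU; a small
multi-condition pipeline run completes in seconds to a few minutes.

## Limitations

- The synthetic categories carry only spectral (second-order) structure.
  Findings about phase-dependent or object-level scene content are out of
  reach; the generator is a testbed for the *pipeline*, not a stand-in for
  natural-scene category structure.
- Occlusion is all-or-none: perimetry sensitivity is binarized at the
  blind threshold, so relative (partial) defects are treated as absolute.
- The model observer has no fixational eye movements, no attentional
  weighting, and sees the occluder's sharp edge, which adds spurious
  spectral energy that a human with a field defect does not experience
  (mitigated, not removed, by mean-value filling).
- The equal-variance Gaussian assumption underlies both d̂′ estimators and
  the simulated observers; unequal-variance observers would bias the
  comparison.
- The BIC Bayes factor is an approximation with an implicit unit-information
  prior; it is used for evidence labelling, not posterior inference.
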