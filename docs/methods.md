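# Methods

## Problem and model

`cropfuse` studies hybrid crop classification over multi-date NDVI
features.  Three probabilistic base classifiers — a random forest, an
RBF-kernel SVM, and a boosted decision-tree ensemble — are trained on
the same per-pixel NDVI time series.  Their per-pixel probability rows
are summarized by the α-quadratic entropy

    H(p) = (2^{2α} / n) · Σ_k p_k^α (1 − p_k)^α ,

and combined by majority voting with a least-uncertainty tie-break
(M-voting) or by uncertainty-weighted probability fusion (P-fusion), at
pixel level or pooled over field objects.  Accuracy is assessed from
the error matrix (PA/UA/OA/kappa) and classifier pairs are compared
with McNemar's test on discordant correct/incorrect counts.

### The entropy normalization

The prefactor is read as `2^{2α}/n` with `n = K`, the number of
classes; this is the only reading that makes H a normalized uncertainty
in [0, 1] (H = 0 iff the distribution is degenerate, H = 1 at the
uniform distribution for α = 0.5).  Because `n` is genuinely a
convention, it is exposed as `convention_n` (default `K`), as is `α`
(default 0.5, the value the analysis uses throughout).

### P-fusion weight direction

The fused score is `Σ_f w_f(x)·p_f^k(x)`.  Two weightings are shipped:
`complement` (default), `w_f = 1 − S_f(x)`, which up-weights
low-uncertainty classifiers and is the behaviour the method intends;
and `literal`, `w_f = S_f(x)`, preserving the formula with the raw
uncertainty as the multiplier.  Both are tested against a brute-force
reference; all reported experiments use `complement`.

### Tie handling

Every argmax breaks ties toward the lowest class index, and M-voting
records per pixel whether the uncertainty tie-break fired
(`FusedLabels.tie_break_used`).  If uncertainties themselves tie, the
earliest classifier in the input order wins; with continuous
probability outputs this is a measure-zero event.

### Object-level pooling

Each pixel of an object contributes its F per-classifier votes (not its
fused pixel label); the object takes the unique-plurality class, with
vote ties resolved by the least-uncertain pixel–classifier pair among
those proposing a tied class.  Object P-fusion sums the weighted
probability rows over all member pixels.  The object label is broadcast
to member pixels and accuracy is tallied per pixel.  On singleton
objects both rules reduce exactly to their pixel-level counterparts
(tested exhaustively on random instances).

## Base classifiers

The learners are scikit-learn's; the package pins the policy:

| classifier | policy |
|---|---|
| random forest | 1000 trees, `max_features = ⌊√F⌋` (F = number of dates) |
| RBF SVM | features min–max scaled to [0, 1] on the training rows; (C, γ) by cross-validated accuracy over a 2-D grid; pairwise-coupling probability estimates |
| boosted trees | AdaBoost (SAMME) over unpruned CART trees, 10 boosting iterations — a boosted-decision-tree stand-in for C5.0-with-boosting, which has no maintained Python implementation |

The default SVM grid is the classic libSVM search space
(C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}, steps of 2², 5-fold CV; ties to the
smallest C, then γ).  The experiment protocol (`run_experiment`) uses a
coarser 4×3 grid with 3-fold CV (C ∈ 2^{−1,3,7,11}, γ ∈ 2^{−7,−3,1})
so that repeated retraining over many training sizes and runs stays
proportionate; the full grid is available via the `svm_grid` parameter.
Trees are scale-invariant and see raw NDVI; only the SVM is scaled.
Classes missing from a training draw receive zero probability, and
probability rows are renormalized to sum to one.

## Synthetic scenes

The generator emulates the statistical structure of an irrigated-oasis
crop mosaic observed at 30 m every ~15 days:

* **Phenology curves.**  Two logistic limbs joined at `peak_doy`, each
  normalized so the curve attains exactly the peak-envelope midpoint at
  the peak date; limb slopes span 5%→95% of the amplitude between
  green-up (or senescence) and peak, so longer seasons rise more
  gently.  This piecewise form was chosen over a single
  difference-of-logistics because it pins the maximum exactly at
  `peak_doy` and allows asymmetric rise/fall (spring maize senesces
  faster than cotton).  Double-season classes (winter wheat followed by
  a summer crop) take the pointwise maximum of two curves.
* **Fields.**  The scene is tiled into axis-aligned rectangular fields
  (default 8×8 pixels — tens of 30-m pixels per field, no mixed
  pixels).  Crops are allocated to fields by largest-remainder rounding
  of the class proportions followed by a seeded permutation, so every
  class is always present and pixel frequencies match the proportions
  to within one field.
* **Noise.**  One Gaussian offset per field (sd `field_sd`, clipped so
  the field's peak stays inside the crop's peak envelope) plus
  independent per-pixel, per-date Gaussian noise (sd `pixel_sd`);
  values clipped to [−1, 1].
* **Seeding.**  A single integer seed drives a `SeedSequence` hierarchy
  keyed by purpose and field id, so enlarging the grid does not
  reshuffle unrelated draws.

Two presets encode the study sites' crop mixes: `bole6` (cotton 46%,
grape, watermelon, winter wheat, wheat–summer, spring maize) and
`manas5` (cotton 44%, spring maize, winter wheat, tomato,
wheat–summer).  Peak envelopes follow the crops' seasonal behaviour:
cotton 0.7–0.9 near DOY 200, watermelon/tomato 0.6–0.7, grape high over
DOY 170–270 with the widest envelope (0.42–0.70) and the largest
`field_sd` (0.085), wheat green before late June.  The noise magnitudes
(`field_sd` 0.03–0.085, `pixel_sd` 0.03–0.04) are not measurable from
published figures; they were fixed once to reproduce the qualitative
separability ranking — wheat classes easy, cotton/grape/maize
confusable in `bole6`, `manas5` well separated — and are part of the
preset definition.

What the generator does **not** emulate: mixed boundary pixels, cloud
gaps, atmospheric residuals, irregular field geometry, spatially
correlated noise.  Passing tests therefore demonstrate the correctness
and the directional behaviour of the method (fusion helps most when
training is scarce; accuracy saturates with training size), not
absolute accuracy levels on real imagery, which are several points
lower.

## Experiment protocol

`run_experiment` draws, for each training size and run, a seeded simple
random subset (without replacement; a proportional-stratified option
exists) from a fixed training pool, trains the three base classifiers,
and evaluates the 3 singles + 4 hybrids on a fixed validation pool
(predictions are made on validation pixels only; object pooling runs
over the validation members of each field).  Mean and sample standard
deviation (divisor runs−1) are aggregated per configuration and size;
per-run predictions are retained so `aggregate_mcnemar` can tally
S+/N/S− per ordered pair and size group.  Sub-seeds come from
`SeedSequence((seed, size_index, run))`, so the validation pool and all
draws are reproducible.

The full protocol of the underlying study (12 sizes from 50 to 4000,
10 runs each, ~5,000-pixel pools) is expressible directly; the
package's own tests and the acceptance script run a scaled protocol —
sizes {50, 100, 500, 1000}, 5 runs, 96×96-pixel scenes with ~4,600-pixel
training pools — which preserves the regimes of interest (scarce
training, pre-saturation, saturation) at about a minute of compute.

## Cross-sensor consistency

`generate_paired_sensor` images NDVI through `gain·x + offset` plus
Gaussian noise, clipped to [−1, 1]; `extract_window_means` averages
odd-sized windows (default 3×3) fully inside the raster;
`fit_sensor_consistency` fits y-on-x OLS (scipy) and reports slope,
intercept, R² and the window count.  NaNs (flagged NDVI pixels) are
excluded from window means and fits.  Only the y-on-x direction is
fitted; the reverse fit is the caller's transposition.

## Numerical conventions and limitations

* NDVI with `red + nir = 0` → NaN sentinel; an all-NaN result raises.
* Min–max scaling maps zero-range features to 0 with a warning;
  apply-set values outside the training span are not clipped.
* P-fusion with all-zero weights (possible only in `literal` mode with
  all-certain classifiers) falls back to the unweighted mean with a
  warning.
* McNemar's Z is defined as 0 when both discordant counts are zero;
  the boundaries ±1.96 belong to the "N" category.
* Undefined PA/UA (empty reference or prediction marginal) are NaN,
  excluded from summaries.
* Rasters are written as plain TIFF (one page per acquisition date;
  page description carries the DOY list) without georeferencing tags;
  the CSV long table is the lossless interchange format.
* The brute-force fusion references used in tests live in
  `tests/_oracles.py` and share no code with the package.
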