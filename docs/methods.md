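# Methods

## The estimation problem

Chronological age in months is regressed on morphometric ratios read
off a pantomogram.  The 21 indicators are ratios of Euclidean segment
lengths between named landmarks (see `dentage.indicators` for the full
table).  Ratios make the features dimensionless and therefore robust
to the 3–10 % magnification differences between panoramic devices; no
pixel calibration is needed.  Anatomically the families track three
maturation signals: inter-arch crown distances (X01–X06), root
elongation and apex closure against projected reference segments
(X07–X10, X15–X18), crown-width proportions at the cemento-enamel
junction (X11–X14) and between-teeth apex–border proportions
(X19–X21).  All of these change monotonically during mixed dentition,
which is what makes age recoverable in the 48–144-month window; the
models are not valid outside it, and ingestion enforces the window
unless explicitly overridden.

## The regression model

A radial-basis-function network with one Gaussian hidden layer and a
linear output:

    f(x) = b + Σ_j w_j exp( −‖x_s − c_j‖² / (2 σ_j²) )

* **Scaling.**  Inputs and the output are min–max scaled to [0, 1]
  with parameters estimated on the training partition only, so
  validation/test values may fall slightly outside [0, 1].  Reported
  errors are RMSE on the scaled output; multiply by the training age
  range (≈ 96 months) to get months.  A constant training target is
  centred in a unit output range so the fit degenerates to a constant
  predictor instead of failing.
* **Centers.**  Seeded k-means (k = H, 10 restarts) on the scaled
  training inputs.  When H reaches the number of distinct training
  points the distinct points themselves are the centers — the
  interpolation regime.  Coincident centers (possible only on
  adversarial ties) are deduplicated and replaced by unused training
  points.
* **Widths.**  σ_j = max(distance to nearest other center, 1e−6) ×
  spread, with spread = 2.0 by default.  A broad spread gives a
  smooth, well-conditioned fit for the moderate hidden counts used
  here; it is exposed for experimentation.  A single-unit network has
  no neighbour, so its width uses the data radius around the center.
* **Output weights.**  Ridge least squares on [activations | 1] with
  the bias unpenalized, solved through the augmented-rows formulation
  (never the explicitly squared normal equations, which would square
  the condition number).  Default ridge 1e−8 stabilizes the solve;
  ridge 0 is allowed and then a rank check raises a diagnostic
  pointing at ridge when the design is singular (e.g. duplicated
  centers).  With ridge 0, H = n and distinct inputs the network
  interpolates (training RMSE below 1e−6), which the tests assert.

Model "quality" per partition is the Pearson correlation between
predicted and observed age — the standard close-to-1 agreement measure
consistent with the magnitudes reported for this methodology
(0.96–0.999).  The alternative reading (an S.D.-ratio statistic) was
considered and rejected because only correlation matches the
"closer to 1 is better" description.

## Split and search protocol

Cases are shuffled by a seeded generator and allocated 2:1:1:
floor(n/2) training, floor(n/4) validation, remainder test (for n =
619: 309/154/156).  The candidate search ("designer") draws `n_test`
(H, fit-seed) pairs from the candidate hidden sizes, trains each on
the training partition and retains up to `n_retain` ranked by
validation RMSE, subject to a diversity rule — at most ⌈n_retain/2⌉
retained networks may share one H — so the short-list never collapses
onto a single topology.  Everything is deterministic given the seed.

## Sensitivity analysis and pruning

The quotient of input k is the ratio of the model's RMSE with that
input replaced in every case by its training-partition mean to the
full-model RMSE, evaluated by default on the validation partition
(the training partition of a near-interpolating model has numerically
zero baseline error and is rejected).  Mean substitution is the
classic missing-value treatment that makes an input uninformative
without refitting.  Rankings sort quotients descending with a stable
tie-break: the earlier-listed variable keeps the smaller rank, which
is exactly the convention visible in the published reference tables
shipped under `dentage/data/` (two variables tied at 1.0051 appear in
listing order).  Pruning drops inputs with quotient below a threshold
(default 1.0 — "quotient above 1 means the model relies on it") and
refits with the same hidden count; the threshold is exposed because
published final models retain some inputs marginally below 1.

## The synthetic cohort generator

No deposited dataset exists for this methodology, so the generator
emulates the study population: 296 girls and 323 boys, ages drawn as
uniform integers on [48, 144] months.  Each indicator follows a
monotone age-response curve: logistic maturation (start → end around a
per-tooth midpoint, rate 0.05/month) for the root- and crown-related
ratios, with later midpoints for the later-developing second premolar
and second molar; gentle linear trends for the arch and apex–border
proportions.  Girls run 3 months ahead of boys (curve evaluated at age
+ 3), reflecting earlier dental maturation.  Gaussian noise with
s.d. = 5 % of each curve's range is the default ("low-noise")
condition; `high_noise_params` scales it up for stress testing, and a
flat trajectory with an absolute noise s.d. makes an indicator a pure
noise input for pruning experiments.

Four indicators are exact products of others because they share
segments (X02 = X01·X04, X03 = X01·X04·X06, X05 = X04·X06,
X20 = X19·X21).  The generator draws the 17 free indicators from their
noisy curves and derives the other four, so every synthetic case is
geometrically consistent — realizable by actual landmark positions.
`generate_landmarks` performs that realization on a parametric jaw
template (fixed denominator segments, numerator endpoints positioned
per ratio; the apex sits on the |AM| circle at border height so the
crown–apex segment is always constructible) and inverts
`compute_indicators` to ~1e−15, which is how the landmark I/O and
indicator geometry are tested end to end.

What the generator does **not** emulate: annotation error correlated
across landmarks of one image, non-monotone pathology, secular trends,
heteroscedastic noise across age, and realistic covariance between
indicator families beyond the shared-segment identities.  Passing
recovery tests therefore shows the pipeline extracts a monotone
multivariate growth signal at realistic noise — not clinical accuracy.

## Problem sizes and defaults

Default pipeline settings: hidden-size candidates {5, 10, 15, 20, 25},
20 candidates tested, 10 retained, prune threshold 1.0, ridge 1e−8,
spread 2.0.  On the default 619-case cohort one full pipeline run
takes well under a second of CPU; the five-seed recovery check in
`scripts/acceptance.py` completes in a few seconds.  Reduced cohorts
(60–160 cases) are used in unit tests purely to keep fixtures small.

## Known limitations

* The landmark-export schema is this package's own contract; upstream
  annotation tools must be mapped to it.
* Sensitivity quotients depend on the partition they are evaluated on;
  only the validation-partition default is exercised broadly.
* Pruning is a single cycle per invocation; iterate explicitly (the
  CLI composes) if further reduction is wanted.
* The published clinical models themselves cannot be reconstructed —
  only their sensitivity rankings ship as reference data.
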