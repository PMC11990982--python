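# Methods

This note documents the models, conventions and design choices behind
bloomcam, in the spirit of a package methods appendix.  It states no
empirical result that the test suite does not itself compute.

## Color indices

For an ROI with pixels `(R, G, B)` (8-bit digital numbers, 0–255) the
per-pixel indices are

    BRI  = R + G + B
    RI   = R / BRI,  GI = G / BRI,  BI = B / BRI
    GEI  = 2·G − (R + B)

Each image × ROI record holds the mean and within-ROI standard deviation of
R, G, B, BRI, RI, GI, BI and GEI — 16 features.  Indices are computed per
pixel and then summarized (not ratio-of-means): the SD features are the
point of the method, because petals against foliage inflate within-crown
heterogeneity even when the mean color shift is modest.

Conventions:

* **Sample SD** (n−1 denominator), configurable via `ddof`.  A one-pixel
  ROI reports SD 0.
* Pixels with `BRI = 0` have undefined chromatic coordinates; they are
  excluded from the RI/GI/BI statistics and counted in `excluded_pixels`.
  An all-dark ROI reports the chromatic fields as NaN.  (Such records
  always have zero raw-channel SDs and are removed by the zero-SD filter
  anyway.)
* No gamma or white-balance correction: raw DNs as recorded.
* Timestamps are parsed from file names (configurable strftime pattern);
  the camera clock is assumed UTC and converted to the configured site zone
  for solar filtering and per-day grouping.

## Preprocessing

Three filters, provably order-insensitive (property-tested):

1. **Solar window** — keep records in `[sunrise + buffer, sunset − buffer]`
   for the record's local date.  Sunrise/sunset come from a built-in
   NOAA-style sunrise-equation routine (~1 min accuracy; verified in tests
   against an independent solar-elevation formulation); a user-supplied
   schedule table overrides it and serves as the polar-day/night fallback.
2. **Exclusion windows** — explicit `[start, end]` windows (e.g. evening
   light shows) with per-reason drop counts logged.
3. **Zero-SD filter** — drop records where any of the 8 SD features is 0
   (within 1e-12): the signature of a too-dark ROI.

## Labeling treatments

Flowering is BBCH 61–67; 60 and 68–69 are transitional edges treated as
non-flowering.  "No signs of flowering" means a code outside 60–69.

* **A** — records on days in the observed `[first 61–67, last 61–67]`
  interval are positive; everything else negative.  The optional edge
  extension takes explicit per-side day offsets (default off) because no
  general extrapolation formula is defensible from visit records alone.
* **B** — days strictly between the last no-signs observation and the
  first in-range observation (and symmetrically after the phase) are
  *removed*; BBCH 60/68/69 observation days inside those gaps are removed
  too.  B never relabels a record relative to A (invariant-tested).
* **C** — positives: the observed BBCH 62–67 day span (62 rather than 61,
  so the uncertain first-flowers stage must prove itself); negatives: the
  10 days (configurable) ending at the pre-flowering no-signs observation
  and starting at the post-flowering one.  An inner kknn, tuned on this
  core with the standard search, predicts the transitional gap days.  The
  negative windows anchor on the flanking no-signs *observations* (the
  wording of the underlying protocol admits anchoring on the BBCH 61/67
  days instead; the window length parameter lets users explore both).

## The classifier

Kernel-weighted k-NN, from scratch (scikit-learn appears only as an
independent test oracle):

* Minkowski distance, p = 2 default, on z-scored features (training
  statistics only; constant columns get scale 1 with a warning).
  Standardization is on by default and switchable.
* Neighbor distances are normalized by the (k+1)-th neighbor distance, so
  d ∈ [0, 1] for the k voters.  If that distance is 0 all k neighbors
  duplicate the query and an unweighted vote is used.
* Kernels: rectangular 1; triangular 1−d; epanechnikov ¾(1−d²); biweight
  (15/16)(1−d²)²; triweight (35/32)(1−d²)³; cos (π/4)cos(πd/2); inv 1/d
  capped at 1e12; gaussian exp(−d²/2); `rank` k+1−rank(d); `optimal` the
  asymptotically optimal rank weights
  `w_i = (1/k)·(1 + d/2 − d/(2k^{2/d})·(i^{1+2/d} − (i−1)^{1+2/d}))` with
  d = feature dimension.  Multiplicative constants that cannot affect the
  argmax are immaterial and simplified.
* Ties: distance ties break by training-row index (stable sort); an exact
  weighted-vote tie returns non-flowering — conservative for a rare
  positive class.  k must be odd (3–15 in tuning) so rectangular votes
  cannot tie.
* Brute-force distances only: a season is ~2·10⁴ records, for which
  vectorized exhaustive search is faster than tree indices would be worth.

Metrics: `REC = TP/(TP+FN)`, `PREC = TP/(TP+FP)`, and their harmonic mean
`F = 2·PREC·REC/(PREC+REC)`.  Zero denominators yield a defined 0 with an
`undefined` flag.  A featureless majority-class baseline (ties →
non-flowering) anchors comparisons.

## Tuning and transformations

* **Subsampling validation**: ⌈0.75·n⌉ training records drawn without
  replacement, remainder test, 10 repetitions, all seeded; every candidate
  is scored on identical splits.
* **Grid**: odd k ∈ {3,…,15} × 10 kernels = 70 candidates, walked in a
  seeded random permutation (the search order is unspecified in the
  underlying protocol; randomizing it is what makes the no-progress
  terminator meaningful).  Stop after 30 consecutive evaluations without
  strict improvement in mean recall, or on grid exhaustion.  Recall is the
  selection measure throughout: with a whole season of data the flowering
  class is rare and false positives are cheap.
* The (k, kernel) pair tuned on the untransformed (`nt`) dataset of a
  treatment is reused for that treatment's `fs`, `df` and `fs.df` variants.
* **`df`**: per local day, drop records with `gei.sd` strictly below the
  day median (ties kept, so ≥ half of each day survives; single-record days
  untouched).  Applied to training *and* test data when active.
* **`fs`**: greedy forward wrapper selection maximizing mean subsampling
  recall; strict improvement required (ties prefer fewer features, then
  the canonical feature order).  The concrete algorithm is a design choice
  — any per-plant calibrated list can be injected verbatim instead.

## Diel evaluation

* A day is flowering iff `P·100/(P+N) ≥ threshold` (inclusive, default
  50%).  Days with no retained images are uncovered and excluded from all
  period counts rather than imputed.  Lowering the threshold can only grow
  the flowering-day set (property-tested).
* **Predicted onset** = first day of the longest maximal run of consecutive
  flowering days (earliest on ties), so isolated out-of-season false
  positives — snow days are the canonical case — cannot set the onset.
  A `first_positive` rule is available.  `ODS = OD_pred − OD_obs`, signed
  days.
* **Periods**: flowering = the observed 61–67 interval; extremes = days
  strictly between the last observation before flowering and the onset,
  plus days strictly between the end and the first no-signs observation
  after the phase (68/69 observation days fall here); non-flowering =
  every other covered day.  Disjointness and coverage are exact set
  identities, property-tested.
* `FDS = FD_pred·100/FD_obs` per period, reported to 1 decimal (raw value
  retained).  **Duration** is inclusive: `end − onset + 1` days.
* Best-model ranking: (|ODS| ascending, undefined last; flowering FDS
  descending; non-flowering FDS ascending; variant name).  This is an
  explicit, documented rule; informal expert choice could differ.

## Synthetic scenarios

The generator emulates what the method consumes, not photorealism:

* A piecewise-linear seasonal canopy color (dormant → green-up → full-leaf
  plateau → senescence → dormant).  By default green-up completes *before*
  the flowering window, i.e. flowering happens on the stable full-leaf
  plateau.  This is the common case for summer-flowering woody plants and
  it makes the null-contrast control meaningful: with the petal pulse
  amplitude at zero, the flowering window is not identifiable from
  seasonal color alone, so any recovery must come from the flowering
  signal itself.  (Species flowering on bare branches are representable by
  moving the anchors.)
* The flowering pulse is a petal-colored pixel mixture fraction (default
  45% white petals) ramping linearly over 3 days at each window edge —
  reproducing both the chromatic mean shift and the `gei.sd` inflation.
* Per-pixel texture noise (SD 10 DN), shared per-frame illumination jitter
  (SD 6 DN), constant near-black night frames (caught by the zero-SD
  filter), bright low-GEI snow days, and amber artificial-light evening
  frames (handled by the solar/exclusion filters).
* Every frame's pixels come from an RNG keyed by (seed, year, doy, minute),
  so the image renderer and the fast feature-table shortcut are
  bit-identical and fully reproducible.
* Observation schedules visit at seeded 2–4-day gaps with BBCH codes read
  off the true per-day schedule, giving the treatments realistic
  transitional ambiguity; a 1-day gap setting yields a dense observer whose
  interval equals the ground truth.

What passing synthetic tests do **not** show: robustness to camera shake,
exposure drift, partial occlusion by neighboring crowns, subtle
green-on-green flowering, or observer misclassification of BBCH codes —
real archives add all of these.

## Problem sizes and end-to-end validation

The end-to-end check trains on one synthetic season and tests on a second
whose onset is shifted by +3 days, at a 2-hour frame cadence (≈ 2,200
daylight records per year after filtering) over the A/B/C × {nt, df} grid —
sizes chosen to exercise every stage while keeping the default suite
desk-scale.  Training labels come from the sparse 2–4-day schedule; the
test season is evaluated against a daily schedule, so ODS and FDS measure
recovery of the *true* interval rather than agreement with a lagged
observer.  The acceptance requirement is |ODS| ≤ 1 day and flowering FDS
≥ 90% for the selected best model, and for the zero-contrast control a
flowering FDS at most 25% (the featureless baseline gives 0%; the margin
allows a few chance positive days in a ~16-day window).

## Known limitations

* The solar routine targets mid-latitudes; above the polar circles a
  schedule table must be supplied.
* Treatment C inherits whatever bias the camera perspective has: it
  relabels transitional days by image similarity, which is exactly its
  point and its risk.
* ROI polygons are fixed; no registration of shifted frames, automatic ROI
  delineation, or camera calibration.
* The classifier is binary; flowering-peak (BBCH 65) estimation is out of
  scope by design.
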