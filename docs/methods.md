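# Methods

This note documents the models, rules and numerical choices behind
`foxphase`, and what the synthetic validation does and does not show.

## Track construction

Raw fixes are processed per individual in this order:

1. **Spatial outlier filter.** A fix is removed when the speed implied to
   both temporal neighbours (its single neighbour, at the record edges)
   exceeds `max_speed` (default 8 m/s — far above sustained fox travel).
   One worst offender is removed per pass and speeds are recomputed, so a
   single teleported fix cannot drag its neighbours out; the filter is
   idempotent on clean data.
2. **Capture-window exclusion.** All fixes within 24 h of capture are
   dropped (trapping bias).
3. **Burst building.** Walking the fixes in time, a gap below `dt_min`
   (10 min) drops the later fix (re-measuring from the last kept fix), a
   gap within [`dt_min`, `dt_max` = 60 min] extends the burst, a larger
   gap starts a new burst; single-fix bursts — fixes isolated from both
   neighbours — are discarded.  Sub-10-minute gaps cannot arise from the
   modelled collar schedule but can from arbitrary input; dropping the
   later fix keeps the emitted dt contract exact.
4. **Step metrics.** sl (m), dt (min), speed = sl/dt (m/s), ta = signed
   heading change in (−π, π] with headings measured counter-clockwise
   from east, pv = speed·cos(ta).  The first step of a burst, and steps
   adjacent to a zero-length step (undefined heading), carry NaN ta/pv
   and never reach the feature table.  Mirroring a track (y → −y) flips
   the sign of ta and leaves pv unchanged; this convention is tested.

## Phase segmentation

The dispersal template is S1 → T → S2.  Detection is a deliberately
simple two-cluster procedure, not an early-warning-signal method:

* k-means (k = 2) runs on spatially *declustered* locations (unique
  100 m grid cells), with the two centres initialised at the medians of
  the record's first and last 12 h.  Declustering stops the months-long
  settled range from outweighing a thin transit path; endpoint
  initialisation anchors the solution to where the record begins and
  ends.  If the converged centres collapse below `min_separation`
  (default 2 km) but the endpoint anchors themselves are separated, the
  anchors are kept as centres (records caught or truncated in transit
  leave too thin a path for centroid iteration); otherwise the
  individual is a non-disperser and is excluded.
* The maximal initial run in the first fix's cluster and maximal final
  run in the last fix's cluster are candidate states; each must span
  `min_residency_days` (default 7 d).  Runs bridge interruptions shorter
  than 36 h that return to the run's cluster — a one-night excursion
  that briefly crosses the cluster bisector must not truncate a
  stationary run, while a transit never returns and therefore always
  ends one.  Records with only a final (initial) qualifying run are
  classed caught-in-transit (truncated), with T open at the start (end).
* Because cluster assignment switches at the spatial midpoint between
  centres, raw run ends would place the S1/T and T/S2 boundaries near
  the middle of the transit.  Run ends are therefore trimmed to the
  state's occupancy core: fixes within `core_radius_factor` (default 4)
  × the median distance to the run's median centre.  The median is
  robust to the small transient and excursion contamination of the run;
  factor 4 puts the core edge at ≈ 4 × 1.18 σ ≈ 4.7 σ of a Gaussian
  home range — outside virtually all residency movement but crossed
  within the first few transit fixes.
* Externally computed boundaries can be supplied verbatim instead
  (`accept_external_segmentation`), for use with any dedicated dispersal
  classifier.

**Envelopes and exploratory labelling.**  For each state the empirical
[q_lo, q_hi] = [1.5 %, 98.5 %] quantiles (linear interpolation) of x, y
and displacement-from-origin define a closed-interval envelope; the
displacement origin is the trap location for S1 and the state's first fix
for S2, and the S2 envelope uses only the state's first 28 days (settled
records can run for months).  A fix inside a state's timespan is
out-of-envelope when x or y or displacement leaves its interval (OR
rule, boundaries inclusive).  Contiguous out-of-envelope runs bounded on
both sides by in-envelope fixes of the same state are excursions and are
labelled exploratory; runs touching the data edge or a phase boundary
lack the required return and stay stationary.  Two trap rules guard S1:
any S1 fix within `trap_radius` (1 km) of the trap is stationary
regardless of the envelope, and transient-interval fixes whose
displacement from the trap drops below 1 km are relabelled stationary.
The kilometre threshold is applied to displacement (the square root of
the squared-displacement series), keeping it dimensionally a distance.

## Covariates

Eleven predictors per eligible step, sampled at the step **end** point
(start-point anchoring is available for sensitivity checks): sl, ta, pv;
land class (codes 1–7: tree cover, greenland, agricultural field,
settlement, sparse vegetation, water, wetland); distances to flowing
waters, protected areas, district roads, agricultural roads; the minimum
of the distances to state roads, federal highways and railways (linear
anthropogenic structures); season (Dec–Feb winter, Mar–May spring,
Jun–Aug summer, Sep–Nov autumn); and day/night by solar elevation at the
configured site coordinates (default 47.86° N, 9.54° E), computed with a
NOAA-style declination/hour-angle approximation (a fixed clock window can
be substituted).  Raster sampling is nearest-cell with the half-open
convention x ∈ [left, right), y ∈ (bottom, top].  A Spearman screen
reports predictor pairs with |ρ| ≥ 0.4; nothing is excluded
automatically.  No covariate is standardized: tree ensembles are
invariant to monotone rescaling.

## Balancing and the forest

Telemetry is doubly imbalanced (phases differ in length, individuals in
fix counts).  Per (individual, phase) cell, `n_select` = 10 steps are
drawn without replacement, then `n_boot` = 120 bootstrap replicates of
10 are drawn from that subset: exactly 1,200 rows per cell.  A one-stage
variant (draw 1,200 directly from the cell) is available; the two-stage
scheme is the default because selection and bootstrapping are distinct
operations with different duplication structure.  Cells below 10 rows
raise an error by default (`top_up` draws the initial selection with
replacement instead, with a logged warning).

The classifier is five independently seeded scikit-learn random forests
(300 CART trees each, Gini, unlimited depth, min leaf 1, bootstrap
sampling, mtry = ⌊√p⌋ = 3 of the p = 11 predictors) concatenated into one
1,500-tree model.  Categorical predictors enter as single integer-coded
columns (1 = winter … 4 = autumn; 1 = night, 2 = day; land-class codes as
is) rather than one-hot indicators: with indicators a 7-level variable
would occupy 7 of 21 encoded columns and enter ~7× more mtry draws than
a numeric predictor, which distorts both the mtry semantics and
minimal-depth comparisons across variables.  Integer coding keeps one
candidate slot per variable, at the cost of imposing an ordering on the
land-class codes — an accepted approximation to unordered-factor splits.

* **OOB validation.**  A row's OOB prediction pools the hard votes of
  every tree (across the five forests) whose bootstrap missed the row;
  ties break toward the first class in the fixed order (exploratory,
  transient, stationary).  Overall and class-conditional error rates are
  percentages of OOB-covered rows; rows covered by no tree are excluded
  and counted (with 1,500 trees, coverage is complete in practice).  The
  per-tree OOB fraction concentrates near (1 − 1/n)ⁿ → e⁻¹ ≈ 36.8 %.
* **Minimal depth.**  Per tree, a variable's minimal depth is the depth
  of the shallowest node splitting on it (root = 0); a tree not using
  the variable contributes that tree's maximum depth + 1 (a documented
  fill-in convention isolated in one function).  The report is the mean
  over all trees plus the count of trees using each variable.
* **Partial dependence.**  Default mode is the dataset-averaged profile
  (Friedman): for each grid value the variable is overwritten in a
  seeded subsample of training rows (default 500, for tractability) and
  predicted class probabilities are averaged; the grid is equally spaced
  quantiles for numeric variables and all levels for categoricals.  An
  `at_means` mode predicts a single profile with other numeric variables
  at their means and categoricals at their modes.  The three class
  probabilities sum to one at every grid point by construction.

## The synthetic cohort

The generator emulates a rural south-German collaring study of dispersing
subadult foxes; defaults define the *strongly separated* scenario used in
validation.  Per individual: a mean-reverting (OU) walk (per-axis sd
300 m, relaxation 6 h) around a natal centre; out-and-back excursions
(at most two per stationary segment, at least one, expected rate
0.025/day) that commute outward along a fixed bearing with von Mises
heading noise (κ = 1.5) at ~0.32 m/s, loiter briefly at ≥ 2.5 km, and
return before dawn; a night-travelled transient leg toward a second
centre 16–20 km away (speed ~0.35 m/s, gamma shape 16, heading κ = 30,
day rests with 15 m jitter), departing only with ≥ 6 h of night left; and
settlement into a second OU range.  Fix cadence is 10 min when active
(18:00–06:00) and 60 min by day, with fixes dropped independently at
probability 0.05 — exercising the dt rules, including >60-min gaps.
Twelve individuals (8 full dispersers, 3 caught in transit with a 1.5-day
post-release hold that the 24-h exclusion mostly removes, 1 truncated
record) draw individual centre pairs in the western/eastern thirds of a
30 × 20 km landscape.  A fix during an excursion is truly *exploratory*
once beyond the theoretical 98.5 % displacement radius (≈ 2.89 σ) of its
range centre, matching the envelope definition the segmentation applies.

The landscape is a Voronoi mosaic of 800 seed patches whose class counts
follow the target shares (41.5 % tree cover, 25.6 % greenland, 25.5 %
agricultural fields, 5.4 % settlement, 2 % other), with random polyline
features per linear class (plus one state road along the inter-centre
corridor), disc-shaped protected areas, and exact Euclidean-distance
transforms.  Grids default to 10 m cells for both land class and
distances; the distance resolution is configurable down to 1 m where
memory allows.  Rasters are read and written as Esri ASCII grids, a
plain-text single-band format portable across GIS tools, with the CRS
identifier in a JSON sidecar.

**What the synthetic validation shows — and does not.**  Against the
hidden labels, the segmentation recovers the transient interval with
temporal Jaccard ≳ 0.9 and pools ≳ 0.9 exploratory sensitivity, and the
full pipeline separates the phases with ~100 % combined-forest OOB
accuracy, with persistence velocity first by minimal depth.  Two caveats
frame these numbers.  First, the balanced table repeats 10 unique steps
120 times per cell, so sibling replicates of an OOB row are almost
always in-bag for the same tree: OOB error behaves like resubstitution
error, and near-perfect accuracy is a property of the resampling design
on separable data, not evidence about field data.  Second, the generator
draws movement phases with crisp parameter contrasts and ignores real
complications — terrain-dependent movement, collar error, behavioural
states within phases, inter-individual interaction — so passing tests
validate the *machinery* (rules applied exactly, statistics computed
correctly), not ecological transferability.

## Degenerate inputs and numerical conventions

Quantiles use linear interpolation.  Envelope intervals are closed; a
fix exactly on a bound is inside.  Zero-length steps make adjacent
turning angles undefined rather than arbitrary.  Ties in OOB votes break
by fixed class order; k-means uses a fixed `random_state`.  All
stochastic stages (simulation, selection, bootstraps, tree seeds, PDP
subsampling) derive from one master seed through independent spawned
streams, so any result in the manifest is bit-reproducible from the seed.

## Problem sizes used in validation

The shipped test suite and the acceptance script run the full default
cohort (12 individuals, 120 days, ~110k fixes, 43,200 balanced rows,
1,500 trees) once, and smaller replicates (single forests of 300 trees
across ten seeds; 3-individual, 60-day pipelines) where a property is
about stability across seeds rather than about one run — sizes chosen to
keep a complete validation cycle in the single-digit minutes on one core.

## Known limitations

The two-cluster detector assumes one dispersal event; multi-range or
nomadic records need external boundaries.  A non-disperser whose record
*ends* mid-excursion can in principle be mistaken for a truncated
disperser when the endpoint-anchor fallback engages.  The quantile
envelope inherits the classical contamination issue — heavy excursion
activity inflates the envelope and lowers exploratory sensitivity; the
S2 four-week window and the return requirement mitigate but do not
eliminate it.  Land-class ordinal coding approximates factor splits.
Distances are sampled at raster resolution with no sub-cell
interpolation.
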