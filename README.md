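# foxphase

Movement-phase analysis for GPS-collared red foxes (*Vulpes vulpes*):
segment dispersal tracks into **stationary**, **transient** and
**exploratory** phases, attach habitat and time covariates, and
characterize the phases with a combined random-forest classifier.

## Who this is for

Movement ecologists with projected GPS telemetry of dispersing animals
(one row per fix: individual, timestamp, x/y in meters) and raster layers
of land cover and distances to landscape features, who want a reproducible
pipeline from raw fixes to phase-specific movement signatures.  Because
such telemetry is rarely shareable, the package ships a first-class
synthetic-telemetry generator with known ground-truth phase labels, so
every stage is testable without field data.

## The model in brief

* **Tracks.** Fixes are cleaned (speed-based outlier filter, 24 h
  post-capture exclusion) and partitioned into bursts whose successive
  time gaps dt satisfy 10 min ≤ dt ≤ 60 min; a fix isolated from both
  neighbours by more than 60 min is discarded.  Each step carries step
  length *sl*, *speed = sl/dt*, signed turning angle *ta* ∈ [−π, π] and
  persistence velocity **pv = speed · cos(ta)** — the velocity component
  persisting in the previous direction of travel.
* **Phases.** Two stationary states S1/S2 are found by k-means (k = 2) on
  x/y with residency and separation checks; the interval between them is
  the transient phase T.  Within a stationary state a fix is
  *exploratory* when its x, y, or displacement from the state origin
  falls outside the state's empirical [1.5 %, 98.5 %] quantile envelope
  and its out-of-envelope run returns to the envelope on both sides
  (out-and-back excursion).  S1 fixes within 1 km of the trap, and
  transient fixes that return to within 1 km of the trap, are stationary.
* **Covariates.** Eleven predictors per step, sampled at the step end
  point: *sl*, *ta*, *pv*; land class (7 ESA-style categories); distances
  to flowing waters, protected areas, district roads, agricultural roads;
  the minimum distance to state roads / federal highways / railways
  ("linear anthropogenic structures"); season; solar day/night.
* **Balancing.** Per (individual, phase) cell: select 10 steps without
  replacement, then bootstrap 120 replicates of 10 with replacement →
  exactly 1,200 rows per cell (43,200 for 12 individuals).
* **Forest.** Five 300-tree CART ensembles (Gini, unlimited depth,
  mtry = ⌊√11⌋ = 3) are combined into one 1,500-tree model; validation is
  out-of-bag (OOB), importance is mean minimal depth, and effects are
  shown as partial-dependence profiles of the three class probabilities.

## Worked example

```python
from foxphase import pipeline

result = pipeline.run(pipeline.PipelineConfig(seed=1), outdir="out")
print(result.manifest["resampled_rows"])       # 43200
print(result.manifest["oob_accuracy_pct"])     # 100.0
print(result.importance.head(3))
```

Output from this exact run:

```
               variable  mean_minimal_depth  trees_used
0                    pv            1.501333        1500
1  dist_protected_areas            1.674000        1500
2    dist_district_road            1.796000        1500
```

The simulated 12-fox cohort (108,726 raw fixes) yields 36 balanced cells
of 1,200 steps each.  The combined 1,500-tree forest separates the three
phases with 100 % OOB accuracy on this strongly separated scenario, and
persistence velocity ranks first by mean minimal depth (1.50): the most
phase-diagnostic variable is how persistently the fox keeps its heading —
high and tight during directed dispersal, low during tortuous
exploration, near zero within a home range.  `out/` also receives the
per-fix segmentation, feature table, OOB confusion matrix and
partial-dependence grids as CSV, plus a JSON manifest with row counts at
every filtering stage.

The same pipeline runs from the shell:

```bash
foxphase run-all --out out --seed 1
foxphase simulate --out sim --seed 1 --include-truth
```

To analyse real telemetry instead of simulating, set `telemetry_csv` and
`raster_dir` in the config (rasters as Esri ASCII grids, one per layer).

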