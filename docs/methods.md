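# Methods

This note documents the models, algorithms, parameter choices and
numerical conventions behind `maxsdm`, and what the synthetic study
system does and does not establish about real-data behaviour.

## Grids, areas and geodesy

All spatial objects live on a regular north-up WGS84 lon/lat grid of
square cells; row 0 is the northernmost row, cell centers sit at
`(x_min + (c+0.5)s, y_max − (r+0.5)s)`, and point-in-cell tests use
half-open intervals `[edge, edge+s)` so occurrence thinning and value
extraction are unambiguous.  Grid equality between layers is exact,
field by field, with no epsilon: silently tolerating near-miss headers
is how resampling bugs enter pipelines, so two rasters either align
bit-for-bit or raise.

The Earth is a sphere of radius 6371.0 km throughout.  Cell areas use
the spherical-zone closed form `A = R²·Δλ·(sin φ_top − sin φ_bot)`
(one 0.25° cell: 772.77 km² at the equator, falling toward the poles;
a global 1° grid closes to 4πR² at machine precision), and centroid
shifts use haversine distances with initial bearings clockwise from
north.  At the precision of the reported tables (0.01 × 10⁴ km²,
0.01°) the WGS84 ellipsoid would change nothing material.  Areas are
carried in km² internally and reported in 10⁴ km² rounded to two
decimals only at report time.

Rasters are exchanged as ESRI ASCII grids (written at full `repr`
precision so round trips are exact) or single-band float32 GeoTIFFs
(EPSG:4326, minimal GeoTIFF tag set written and parsed explicitly).

## Synthetic study system

The generator emulates the statistical structure of a regional
niche-modelling study without any downloaded data.

* **Environmental stack.** Default window 120 × 90 cells at 0.25°
  (lon 92–122°E, lat 18.5–41°N).  Eight layers named for the variable
  families they mimic (bio2, bio4, bio9, bio12, bio17, Ele, UVB4,
  S_BS) are smooth Gaussian-filtered white-noise fields (σ = 3–6
  cells), exactly standardized, mixed through the Cholesky factor of a
  target correlation matrix, then scaled to per-variable means/sds.
  The default target correlation includes one strongly collinear pair,
  r(bio12, bio17) = 0.85, so the screening stage always has something
  real to prune, and moderate temperature/elevation structure
  (r(bio9, Ele) = −0.65).
* **Ground truth.** The true niche is a quadratic form on standardized
  layers passed through the cloglog link,
  `suit = 1 − exp(−exp(η))`.  The default truth activates 3 of the 8
  variables — linear-negative bio2 (−5.0) and Ele (−4.5), quadratic
  bio9 (−4.5), intercept −5.5.  These magnitudes were chosen from the
  truth's own separability: they put ~15% of the window above HSI 0.2
  and give the *true* response a presence-vs-background AUC near 0.91,
  the "excellent discrimination" regime characteristic of rare,
  range-restricted species; a weaker truth would cap any fitted
  model's AUC well below that regardless of estimator quality.
* **Occurrences.** Cells are drawn without replacement with
  probability ∝ suitability, with a contamination fraction (default
  0.05) drawn uniformly to exercise robustness, then jittered
  uniformly within the cell.  Cell-weighted sampling (not a point
  process) matches the one-record-per-cell world the thinning stage
  enforces.  The default three-species pipeline uses 41, 12 and 79
  records — deliberately including a severely data-poor species.
* **Scenarios.** Future stacks are per-layer affine maps
  `v' = v·scale + shift`.  The nine defaults (3 pathways × 3 periods)
  shift bio9 by +1.0 to +5.5 °C with matching bio2/bio4 increases and
  scale the precipitation-like layers by 1.0/0.97/0.92 — low, medium
  and high-forcing caricatures, not GCM emulation.
* **Protected areas.** Random rectangles unioned until coverage is
  within ±20% of the target (default 3% of the window), mirroring the
  few-percent protection levels that make gap analyses bite.

What the synthetic system does *not* emulate: spatial sampling bias,
coordinate uncertainty, non-Gaussian layer marginals, categorical
soils, and dispersal limits.  Green tests therefore certify the
*estimator and pipeline*, not the ecological fidelity of any real-data
conclusion.

## The MaxEnt engine

Features are built from background min–max-scaled variables
(`z ∈ [0,1]`): linear `z`, quadratic `z²`, pairwise products, forward
and reverse hinges `max(0,(z−k)/(1−k))` / `max(0,(k−z)/k)`, and step
thresholds `1[z>k]`, with knots at 10 equally spaced background
quantiles per variable (MaxEnt uses up to 50; 10 keeps desk-scale
problems fast while retaining the nonparametric flavour).  All
features lie in [0,1], which makes the L1 penalty commensurable across
classes.  On projection, base variables are clamped to the training
range, so extrapolated cells get the boundary response.

The penalty is `β_j = RM · β_class(m) · s_j / √m` with m the presence
count, s_j the feature's presence standard deviation floored at 5% of
its background range, and β_class(m) linearly interpolated from the
documented per-class schedule (linear/quadratic 1.0→0.2→0.05 at
m = 10/30/100; product 0.5/0.3/0.1; hinge 0.5; threshold
2.0/1.5/1.0), clamped outside the node range.

Fitting is cyclic coordinate descent.  Each cycle starts with a KKT
screen — one matrix-vector product gives all gradients; zero
coordinates with |gradient| ≤ β are provably optimal and skipped —
then the remaining coordinates get a one-dimensional Newton step
passed through the soft-threshold operator, with step halving until
the penalized gain does not decrease (so gain monotonicity is a
structural guarantee, asserted per cycle in the tests, not a hope).
Steps are clipped to ±5 per update to keep the weight update
`w ← w·exp(δf)` overflow-safe; the running normalizer is re-offset
when it leaves [1e−250, 1e250].  Convergence is a per-cycle gain
improvement below `tol` (default 1e−5, default cap 500 cycles;
hitting the cap flags the model rather than raising).  The RM path
inside the tuner is solved from the sparsest RM down with warm starts
— same objective, same optimum, fewer cycles.  Tests pin the optimum
against a dense λ-grid search and an independent L-BFGS-B solve of the
equivalent bound-constrained split problem (λ = λ⁺ − λ⁻), both to
1e−3 in gain.

Outputs: `raw` (sums to 1 over the training background), `cloglog`
`1 − exp(−e^H·raw)` (default HSI; H = entropy of the raw background
distribution) and `logistic`.  The background is all jointly valid
cells up to 10,000, else a seeded uniform subsample — the MaxEnt
convention.  Percent contributions credit each accepted update's gain
to the updated feature's variable(s) (products split equally) and
normalize to 100; with exactly duplicated layers, cyclic descent
deterministically credits the first-visited twin — a property of any
fixed-order coordinate scheme, documented rather than averaged away.
Jackknife importance refits only-one-variable and all-but-one-variable
models (2V+1 fits) and reports regularized training gains.  Response
curves sweep one variable across its background range with the others
at background means.  AUC is the rank-based Mann–Whitney estimator
with half-credit ties; replicate AUC averages ten 75/25 presence
splits (seeded 0–9 on top of the run seed), training on the 75% side
and scoring held-out presences against the background.

## Tuning and selection

Candidates are the full RM × FC grid (default 8 × 6 = 48).  Each is
fitted on all presences; the information criterion is the
landscape-normalized AICc: raw predictions renormalized to sum to 1
over the whole valid grid, lnL summed at presence cells, k = count of
|λ| > 1e−12, `AICc = 2k − 2lnL + 2k(k+1)/(n−k−1)`, rows with
n − k − 1 ≤ 0 flagged invalid and excluded from the delta.  The
winner is the delta-AICc = 0 row; exact ties break by smaller k, then
smaller RM, then FC grid order.  Replicate test AUC is computed for
the winner only (48 replicated fits per species would dominate run
time without informing selection).

## Downstream analyses

* **Classification.** HSI cut at 0.2/0.4/0.6 into not/minimally/
  moderately/highly suitable; intervals lower-closed upper-open, top
  class closed at 1.  The cuts are configuration, defaulting to the
  conventional values.
* **Area dynamics.** Change chains run current → 2050 → 2070 → 2090
  within each scenario; `rate = 100·change/previous_total`.  The
  embedded published reference table is reproduced cell-for-cell by
  this chaining except for seven cells that differ by one unit in the
  last printed digit (the source computed them from unrounded areas)
  and two first-step rates that the source computed against the
  preceding printed column's total; the replication report classifies
  every cell by the rule that explains it instead of averaging the
  discrepancy away.
* **Niche metrics.** Schoener's D on surfaces normalized to sum 1 over
  jointly valid cells; Levins breadth standardized as Shannon entropy
  over ln(cell count) so the stated [0,1] range holds (the common
  ENMTools convention); range overlap binarizes at HSI ≥ 0.4 and uses
  the symmetric min-range denominator.
* **Conservation.** Priority cells are moderately-or-highly suitable
  (class ≥ 2) for at least `min_species` species (default 2 — with
  three study species a strict "more than two" would collapse to the
  triple intersection and contradict pairwise-coexistence mapping).
  Gap analysis reports `100·(1 − protected/priority)`; an empty
  priority mask is reported as such by the pipeline rather than
  raised.  Centroids are cell-area-weighted means of suitable cell
  centers (threshold 0.2, the total-suitable cut), chained per
  scenario from the current map.

## Variable screening

A preliminary fit (FC = LQ, RM = 1 — cheap and stable) supplies
percent contributions; variables at exactly zero are dropped.  Pearson
correlations over all jointly valid cells (deterministic, maximal
sample) then drive greedy pruning: pairs with |r| strictly > 0.80 in
decreasing |r| order, alphabetical tie-break, dropping the
lower-contribution member (contribution ties drop the alphabetically
later name).  The retained set is invariant to input variable order
given distinct contributions.

## Reproducibility and problem sizes

Every stochastic step is seeded from a single integer; rerunning a
pipeline config yields byte-identical CSVs (SHA-256 recorded in the
run manifest).  The shipped analysis sizes — 120 × 90 world,
≤ 10,000-cell background, 200-presence recovery experiments, 20-world
selection-consistency runs, 40-cell oracle problems — were chosen as
the smallest at which the statistical claims are stable; everything
scales by configuration.

## Known limitations

No categorical features, bias grids, or cumulative output; no spatial
block cross-validation or omission-rate selection criteria; no
reprojection or resampling (inputs must be co-registered); hinge/
threshold knots at 10 per variable understate MaxEnt's full
flexibility on large data; the selection-consistency statement is a
frequency over seeded worlds, not a guarantee for any single dataset;
and synthetic scenarios are affine caricatures of climate futures.
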