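# maxsdm

Presence-background maximum-entropy species distribution modelling
(MaxEnt), packaged as a complete, reproducible ecological-niche
analysis pipeline: occurrence thinning, variable screening,
AICc-based hyperparameter tuning, habitat-suitability classification
and area dynamics under climate scenarios, niche breadth/overlap
metrics, protected-area gap analysis, and range-centroid tracking.

It is aimed at conservation ecologists and biogeographers who want
the full MaxEnt/ENMeval-style workflow — the kind used to assess
rare-plant habitat under SSP climate scenarios — as a tested Python
library rather than a chain of GUI tools, and at methodologists who
want a transparent, oracle-checked implementation of the model
itself.  Because real study inputs (GBIF occurrences, WorldClim /
soil / UV-B rasters, protected-area boundaries) are often not
redistributable, the package ships a first-class synthetic-data
module that generates correlated environmental fields with a known
species-environment response, so every stage is testable end to end
with known ground truth.

## The model

Given presence cells and a background sample, MaxEnt fits the Gibbs
distribution over background cells

    P(x) = exp(λ·f(x)) / Z(λ),   Z(λ) = Σ_background exp(λ·f(x)),

maximizing the L1-penalized log-likelihood of the presences

    F(λ) = mean_presence(λ·f) − ln Z(λ) − Σ_j β_j |λ_j|,

where f(x) are feature expansions of the environmental variables
(Linear, Quadratic, Product, Hinge, Threshold — the feature
combination FC is a tuning dimension) and β_j follows the published
MaxEnt per-class regularization schedule scaled by a global
regularization multiplier (RM).  Fitting is cyclic coordinate descent
with soft-threshold updates; the penalized training gain is
non-decreasing by construction and the optimum is cross-checked in
the tests against dense grid search and an independent smooth solver.
The habitat suitability index is the cloglog transform
`1 − exp(−e^H · P(x))` with H the entropy of P over the background.

Model selection follows the ENMeval recipe: all RM × FC candidates
(RM 0.5–4 by 0.5; FC ∈ {L, H, LQ, LQH, LQPH, LQPHT}) are scored with
the landscape-normalized AICc (k = nonzero coefficients) and the
delta-AICc = 0 candidate wins.  Downstream, HSI maps are cut at
0.2/0.4/0.6 into four suitability classes; areas use exact spherical
cell areas (R = 6371 km) and are reported in 10⁴ km²; niche overlap is
Schoener's D, breadth is standardized Levins B2, range overlap is the
min-denominator binary overlap at HSI ≥ 0.4; priority conservation
areas are cells moderately-or-highly suitable for ≥ 2 species, overlaid
with a protected-area mask for gap analysis; and range centroids are
area-weighted suitable-cell centers chained with haversine distances.

## Worked example

```python
import numpy as np
from maxsdm import (
    generate_env_stack, true_suitability, sample_occurrences,
    thin_to_grid, fit_occurrence_model, predict, classify, class_areas,
)
from maxsdm.synth import default_true_model
from maxsdm.maxent import replicate_auc

stack = generate_env_stack(seed=1)              # 120x90 cells, 8 layers
truth = true_suitability(default_true_model(), stack)
occ = thin_to_grid(
    sample_occurrences(truth, 200, seed=0, noise=0.05, species="sp"),
    stack.grid, stack.joint_mask,
)
model = fit_occurrence_model(occ, stack, fc="LQ", rm=1.0)
pred = predict(model, stack)                    # cloglog HSI in [0, 1]
print(round(float(np.corrcoef(truth.valid(), pred.valid())[0, 1]), 3))
print(round(replicate_auc(occ, stack, "LQ", 1.0, seed=0)[0], 3))
print(class_areas(classify(pred)).round(2))
```

prints

```
0.946
0.91
not               555.37
minimal            63.44
moderate           38.08
high               63.05
total_suitable    164.58
total_land        719.94
Name: synthetic(seed=1), dtype: float64
```

i.e. the fitted suitability surface correlates 0.946 with the known
truth, held-out presences are separated from background with mean AUC
0.91 over ten 75/25 replicates, and of the 719.9 × 10⁴ km² window,
164.6 × 10⁴ km² is classified suitable (63.1 × 10⁴ km² highly).

The same analysis end to end, with tuning, scenarios, niche metrics,
gap analysis and centroid tracks written as CSV/JSON:

```bash
maxsdm run-all --seed 0 --out-dir my_run     # or: python -m maxsdm.cli
maxsdm replicate                             # re-derive published worked examples
```

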