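# holclink

Linking historical HOLC "redlining" grades to present-day census tracts,
and finding the tract classification that best predicts present-day
neighborhood outcomes.

## The problem

In the 1930s the Home Owners' Loan Corporation (HOLC) graded city
neighborhoods from A ("best") to D ("hazardous", drawn in red). Modern
health and mobility data live on census tracts, whose boundaries do not
match the historical polygons: most tracts intersect several differently
graded areas and are partly unrated (U). Researchers studying the
long-run effects of redlining therefore need a rule that turns a tract's
coverage composition — the vector (pct_A, pct_B, pct_C, pct_D, pct_U)
summing to 100 — into a usable exposure classification, and the ad-hoc
rules in the literature (largest grade, centroid containment, raw
proportions) differ in what they keep and discard.

`holclink` implements a systematic search over 54 candidate
classifications, varying three design axes:

* **detail kept** — coverage percentages binned at widths of 10, 20, 25,
  33.3 or 50 points (sets 1–5), or only the *rank order* of grades by
  covered area (set 6);
* **ratings considered** — the 1 to 5 most important (largest-area)
  grades per tract;
* **unrated handling** — U as a pseudo-grade, or excluded by rebasing
  percentages to the rated-area denominator.

Each scheme *j* is scored, for each outcome and each minimum-coverage
threshold *t* ∈ {1, 5, 10, 15, 25, 33, 50}%, by five-fold cross-validated
test error of the dummy-coded regression

&nbsp;&nbsp;&nbsp;&nbsp;z(y_i) = β₀ + Σ_c β_c · 1{class_j(i) = c} + ε_i,

giving 54 × 6 × 7 = 2,268 averaged MSEs. A meta-regression of these MSEs
on the design axes shows which features matter; per-scheme averages over
the 42 cells identify the predictively optimal scheme and a parsimonious
one. The 16-class rank-ordered two-rating classification is further
collapsed to a fixed 10-class scheme for applied work, and all candidates
are validated against held-out outcomes via R², per-class contrasts, and
a performance ratio.

A synthetic-data module generates coverage compositions spanning every
rank-order grade combination and correlated outcomes with a known
monotone A-best-to-D-worst gradient, so the whole pipeline is testable
without the restricted external census/health data. A shapely-based
overlay module computes coverage compositions from projected polygon
layers (GeoJSON), including a water-mask subtraction and the
centroid-assignment baseline.

## Worked example

```python
from holclink import (SyntheticConfig, generate_coverages, generate_outcomes,
                      run_grid, summarize_schemes, select_optimal,
                      select_parsimonious)

cfg = SyntheticConfig(n_tracts=1500, seed=1)
coverages = generate_coverages(cfg)
outcomes = generate_outcomes(coverages, cfg)
grid = run_grid(coverages, outcomes, seed=1)          # 2,268 CV cells
summ = summarize_schemes(grid)                        # 42 cells per scheme
print(len(grid), select_optimal(summ), select_parsimonious(summ))
```

prints

```
2268 set6_r2_noU set6_r2_noU
```

— the rank-ordered, two-rating, unrated-excluded scheme wins: with a
latent outcome gradient that follows the dominant grades, binned detail
and the unrated share only add overfitting, while a second rating adds
real signal. The `examples/` directory has one short script per
capability (simulation, overlay, classification, model selection,
collapse/profile, validation, full pipeline); each prints the numbers it
computes with a note on what they mean. A thin CLI mirrors the stages:
`holclink simulate|overlay|classify|cv|meta|collapse|profile|compare|run`.

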