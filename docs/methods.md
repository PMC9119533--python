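# Methods

## Coverage compositions and the overlay

The atom of the analysis is a tract's coverage composition over
{A, B, C, D, U}: percentages of the tract's land area overlapped by each
HOLC grade and by unrated space, summing to 100. The overlay module
computes compositions from projected polygon layers: same-grade polygons
are dissolved (unioned) before intersection so internal overlaps never
double-count; an optional mask layer (e.g. water) is subtracted from both
tracts and graded areas before any area is measured; invalid geometries
are repaired by `make_valid` and failures raise rather than drop
features. Where differently graded source polygons overlap each other,
the rated percentages are renormalized proportionally so the composition
remains a partition. All geometry is planar: the module does not choose a
projection, it refuses layers that declare a geographic (lon/lat) CRS and
otherwise trusts the input to be projected. Layers are GeoJSON or
in-memory `(key, geometry)` pairs.

The centroid baseline assigns each tract the grade of the polygon
containing an interior representative point (not the true centroid, which
can fall outside a concave tract). The minimum-coverage filter keeps
tracts whose rated share meets a threshold, with a closed comparison
(exactly 5% rated survives the 5% threshold) guarded by a 1e-9 epsilon.

## Classification schemes

Schemes form a 6 × (4 + 5) grid: sets 1–5 bin each grade's percentage at
widths 10/20/25/33.3/50 points; set 6 keeps only the rank order; each set
appears with 1–4 ratings when U is excluded and 1–5 when U participates,
54 schemes in total. Conventions:

* Bins are 1-based, half-open `[lo, hi)` with the top bin closed at 100.
  Set 4 uses the literal boundaries 33.3 and 66.6 (a percentage of
  exactly 33.3 falls in the middle bin); the resulting bins are unequal
  by 0.1 point, which is immaterial. A `zero_based` rendering option
  exists for comparability with sources that label the first bin 0.
* When U is excluded, percentages are first rebased to the rated-area
  denominator (`pct_g · 100/(100 − pct_U)`), and binned labels bin the
  rebased value.
* Grades with exactly zero coverage never appear in a label; labels list
  grades in strictly decreasing coverage, exact ties broken worst grade
  first (D, C, B, A, U). The synthetic generator produces no ties, so
  results do not depend on this convention.
* Feasible-label enumeration: for set 6, ordered arrangements of distinct
  grades up to the rating count, minus arrangements shorter than the
  rating count containing no rated grade (tracts always have rated
  coverage), giving 4/16/40/64 classes without U and 5/24/84/204/324 with
  U. For binned sets, a candidate (grade, bin) sequence is kept when a
  composition summing to 100 with strictly decreasing shares realizes it;
  the check uses the componentwise extremes of the order-constrained box,
  which bound every monotone functional of the composition. Observed
  class counts in any dataset can be smaller than the feasible counts,
  especially for detailed schemes.

## Cross-validated scoring

For each (outcome, threshold) dataset: drop missing outcomes, filter by
the threshold, z-score the outcome on the full filtered dataset (n−1
denominator) *before* fold splitting — per-fold standardization is
available behind a flag, but the default reproduces the stated procedure,
mild leakage included — and draw one five-fold split (sizes differing by
at most one) shared by all 54 schemes, so scheme comparisons are paired.
Per fold, the outcome is regressed on class indicators in the training
folds and predicted in the held-out fold; the cell's score is the
unweighted mean of the five test MSEs. Because the class-indicator model
is saturated, its least-squares predictions equal the per-class training
means; predictions are computed that way for speed, and the test suite
verifies equivalence with an explicit dummy-coded `lstsq` fit to 1e-8.
Classes unseen in training predict the training grand mean — the least
assumptive choice. A cell's `df` is the number of distinct classes in the
full threshold dataset minus one. All fold randomness derives from a
single seed via per-dataset seed sequences.

## Meta-regression and selection

The 2,268 cells are regressed (OLS, dummy coding) on five feature groups
with fixed references: ratings count (ref 2), set (ref rank-ordered),
unrated handling (ref exclude), outcome (configurable ref) and threshold
(ref 5%); one table per feature and one with all features. Per-scheme
summaries report both the mean and the median MSE over the scheme's 42
cells (selection uses the mean by default, switchable), the median `df`,
and the largest observed class count. The optimal scheme minimizes mean
MSE (ties: fewer median df); the parsimonious scheme has the fewest
median df among schemes within a relative tolerance (default 0.5%) of
the minimum — the tolerance quantifies "performs just marginally worse",
for which no numeric value exists, so it is exposed as a parameter.

## Collapse and profiles

The 16-class rank-ordered two-rating classification is collapsed by a
fixed, explicit 10-class merge table (mainly-A classes pooled;
mainly-C-or-D classes pooled by secondary A or secondary B; the two
mainly-B-with-worse-secondary classes pooled; the rest map to
themselves). Freezing the map keeps the canonical pipeline deterministic;
re-deriving merges data-dependently would re-open the overfitting door
the cross-validation closed. Class profiles report counts and the mean
composite outcome: outcomes standardized, "bad" outcomes sign-flipped so
higher is better, tract-wise mean across available outcomes (missing
cells are averaged over the non-missing ones, with a count column).
Cronbach's alpha of the sign-aligned battery justifies the averaging.

## Validation comparisons

Held-out outcomes (never used in cross-validation; the pipeline enforces
disjointness) are regressed on each approach at the 5% threshold:
continuous B/C/D shares of rated area (A omitted for identification),
the one-rating classification, the collapsed 10-class, detailed
16-class and optimal 40-class schemes, and optionally the centroid
baseline. R², RMSE and adjusted R² are recorded per cell; coefficient
tables use conventional standard errors and two-sided stars at
0.05/0.01/0.001; the performance ratio reports one approach's average R²
as a percentage of another's, rounded and unrounded.

## The synthetic universe

The generator emulates the two tables the real analysis starts from.

**Coverages.** When `ensure_all_combinations` is on (default), the first
128 tracts enumerate all 64 ordered rank combinations of 1–4 rated
grades, each with and without a nonzero unrated share. Remaining tracts
draw the number of covering grades as (40, 35, 18, 7)% for 1–4 grades —
about 60% of tracts touch multiple grades, as in the historical maps —
with grade inclusion skewed toward C and D; shares come from a Dirichlet
draw sorted descending (strict order, no ties), and the unrated share is
drawn independently (zero for ~15% of tracts, otherwise Beta with mean
≈ 1/3) before renormalizing the composition to 100. Fully unrated tracts
are never emitted; the study universe is tracts with rated coverage.

**Outcomes.** Each outcome is `intercept + slope·L + shared + noise`
with slope 1, a shared tract-level noise component and idiosyncratic
noise. The latent quality L is a *rank-weighted* grade gradient: the
grades present, ordered by covered area, contribute their weights
(defaults A=1.0, B=0.5, C=0.0, D=−0.5) with geometrically declining
influence (decay 0.4, normalized), and the unrated share contributes
nothing. This builds in, as the data-generating truth, the two
structural features the historical data exhibit: outcomes follow the
dominant grades' rank pattern far more than the exact coverage
percentages, and unrated land is uninformative (undeveloped at rating
time — missing at random). A linear-in-shares latent was considered and
rejected: it makes coverage magnitude and the unrated share genuinely
predictive, which inverts the model-selection behavior the universe is
meant to emulate. Under the rank-weighted latent the rank-ordered
two-rating scheme is selected as optimal in essentially every seed at
n = 1,500.

The default noise scale (0.35 total, 55% of its variance shared across
outcomes) puts Cronbach's alpha of the six-outcome battery in the
mid-0.9s, the regime of strongly intercorrelated neighborhood outcome
batteries. Sign flips emulate prevalence-type outcomes where higher is
worse.

**What the generator does not emulate:** spatial autocorrelation of
tract outcomes, small-area estimation artifacts in city-level outcome
data, population weighting, and compositions that exceed 100% through
overlapping source polygons. Passing tests therefore demonstrate the
correctness and internal behavior of the procedure, not effect sizes in
real census data; all coefficient-level results on real data remain
dataset-specific.

## Problem sizes and numerics

Default experiments use n = 1,500 tracts, six cross-validation outcomes,
seven thresholds and all 54 schemes (2,268 cells, a few seconds);
calibration-style checks (grand-mean CV error ≈ 1, noise R² ≈ 0,
alpha of independent items ≈ 0) use n = 5,000–10,000. Composition sums
are enforced to 1e-9 by the generator and checked to 1e-6 in I/O;
overlay percentages are validated against analytic rectangle areas to
1e-6; estimator equivalences (dummy OLS vs class means, coefficients vs
group-mean differences) hold to 1e-8. Degenerate inputs raise: constant
outcomes cannot be z-scored, fully unrated tracts cannot be rebased or
labeled under U-excluding schemes, thresholds that empty a dataset name
the threshold.

## Known limitations

* The overlay reads GeoJSON (or in-memory shapely pairs) only, and does
  not reproject; upstream tooling must supply projected layers.
  Geographic-CRS detection is a declaration check, not a full CRS parse.
* Binned-label feasibility admits boundary cases that differ from real
  data only on measure-zero compositions (exact ties).
* The 10-class collapse map is fixed by construction; an exploratory
  data-dependent merge is deliberately out of the canonical pipeline.
* Meta-regression standard errors are conventional OLS errors; cells
  sharing a dataset are correlated, so the errors understate uncertainty
  — they are reported for structure, and selection never uses them.
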