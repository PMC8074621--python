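# Methods

This note documents the statistical model behind the package, the choices
made where the design was genuinely open, and what the synthetic scenarios
do and do not establish about real data.

## Delays and indicators

A reporting delay is the whole number of calendar days between occurrence
and report; sub-day timestamps are truncated to dates, because the
indicator cutpoints (within one day ⟺ Δt ≤ 1, within one week ⟺ Δt ≤ 7,
within one month ⟺ Δt ≤ 30) are defined on integer days.  A report dated
before its occurrence is a recording error, not a long delay: such rows
are dropped with a logged count rather than clamped.

The regression target is log(1 + Δt), not log(Δt).  Same-day reports
(Δt = 0) are common and log(0) is undefined; the +1 offset keeps the
transform strictly increasing, zero exactly at same-day reporting, and is
isolated in one function (`delays.log_delay`) so an alternative offset is
a one-line change.

Seasons follow the meteorological convention (Dec–Feb winter, Mar–May
spring, Jun–Aug summer, Sep–Nov fall); weekend means Saturday/Sunday of
the occurrence date.  Holiday flags come from a bundled calendar table
covering 2012–2019: federal holidays and Easter-derived dates are
rule-computed; holidays tied to lunar/lunisolar calendars (Eid, Rosh
Hashanah, Yom Kippur, Passover, Diwali, Holi) are typed per year at their
approximate Gregorian dates.  The table is a plain CSV and can be replaced
by the caller; dates outside its coverage raise rather than silently
reading as "no holiday".

## Population-weighted areal aggregation

Census tracts b_k and police districts a_j are overlapping planar
partitions.  Under the uniform-population assumption, the population in an
intersection is x_{k∩j} = P^A_{j|k}·x_k with
P^A_{j|k} = A(b_k ∩ a_j)/A(b_k).  District values of intensive attributes
(percentages, medians, averages, household size) are population-proportion
weighted means, Σ_k P^x_{k|j}·attr_k.  Extensive attributes — totals such
as `pop.total` and `occ.units` — are instead area-apportioned and summed:
population-proportion-weighting a total would double-count it.  The
intensive/extensive classification ships as a module-level constant.
Intersections with area fraction below 1e-9 are boundary slivers and are
dropped.  All geometry is computed in the coordinates supplied; real
lon/lat inputs must be projected to an equal-area-safe CRS first.  A point
on a shared tract boundary is assigned to the smallest tract id, making
event-context lookup deterministic.

## Moran's I and permutation inference

Both Moran statistics use binary, non-row-standardised weights, matching
their double-sum definitions; a row-standardised variant exists behind a
flag but is off by default.  Queen contiguity counts any shared boundary
point (corners included).  kNN weights are exact k-nearest graphs with
lexicographic (distance, id) ordering, which matters when many events share
a district-centroid location and tie at distance zero.  Inference is by
random relabelling: B = 999 permutations by default, upper-tailed
(clustering) pseudo p = (1 + #{I_perm ≥ I_obs})/(1 + B), never zero by the
add-one convention.  Local Moran uses the (m−1)-prefactor form and
conditional permutation (unit j held fixed, the remaining values shuffled
over the remaining positions).  The permutation-null mean of the global
statistic, −1/(m−1), is verified by simulation in the test suite.

## Disparity tests

The null of spatial randomness is imposed by shuffling delay values over
fixed district slots, which preserves each district's case count exactly.
The ranked-median envelope reports, per rank, the permutation mean and the
2.5th/97.5th percentiles of sorted district medians (percentile intervals,
not mean ± 1.96 SD — the rank distributions are skewed and bounded).
The Gini coefficient uses the population form
G = Σ_{a,b}|v_a − v_b| / (2 n² v̄) without small-sample correction; it is
scale-invariant, which the tests verify.  Deciles use linear interpolation
between order statistics; medians of even-sized groups average the two
central order statistics.  Both disparity tests are one-sided upper
(greater-than-random disparity) with add-one p-values.  Degenerate
permutations in which every district median is zero are assigned Gini 0
(maximal equality) rather than raising.

## Synthetic scenarios

The generator produces unit-square census tracts tiling a rectangle and
districts as f×f blocks of whole tracts.  Delays follow

    log(1 + Δt_i) = μ + Σ_f β_f·cov_{if} + u_{d(i)} + ε_i,

rounded to nonnegative integer days and capped at 100 years.  The district
effect u is drawn iid Normal, smoothed by one pass of queen-neighbour
averaging (a cheap surrogate for a Gaussian-process draw that induces
positive spatial autocorrelation) and rescaled so its realised SD equals
`spatial_effect_sd` — the rescaling makes the nominal SD the effective
one, so power statements are about the stated effect size.  The noise is
Normal(0, σ²) plus, with probability 0.08, an Exponential(1.5) excursion
on the log scale — an approximately Pareto delay tail.  Defaults
μ = log 4 and σ = 2.5 reproduce the marginal shape of observed rape
reporting delays: median ≈ 3–4 days, ≈ 40% reported within a day, roughly
a quarter or more a month or later, and a 99th percentile far beyond ten
times the median.  Occurrence dates are uniform over 2013–2018 and heaped
to the 1st/15th of their month with probability 0.10, mimicking the
recording practice for imprecisely recalled dates.  Survivor attributes
are categorical draws (race, age band, 85% female).  Covariate effects may
reference survivor dummies, temporal flags, or tract attributes (z-scored
across tracts, so effects are per SD).

Presets: `null` (no spatial or covariate effects, 25 districts, n = 1000)
for calibration; `spatial` (u SD 0.5, 100 districts, n = 3000, effects
federal +1.0, vict.u18 +1.0, poverty +0.3/SD) for power and model
comparisons; `la_style` = `spatial` with block-level points; `ny_style`
replaces event coordinates with district centroids and withholds tract
ids, as in district-level-only disclosure.

What the scenarios do **not** emulate: realistic street geography or
irregular district shapes, spatially correlated census attributes,
non-stationary delay processes, censoring by the observation window, and
under-reporting.  Passing tests therefore establish the correctness and
calibration of the machinery under a known generative model — not that
real reporting delays follow this model.

## Predictive models

Specifications fix the feature groups: NS1 = {V}, NS2 = {Z,V},
S1 = {X,Z,V}, S2 = {Q,Z,V}, S3 = {X,C,Z,V}.  Categorical blocks are
one-hot with dropped references (race "other", age band "25.44", season
"fall", the smallest district id); coordinates enter S3 raw and bypass
feature selection.  Cross-validation is 10-fold, stratified for binary
targets, with standardisation and any selection refit inside each training
fold; out-of-sample predictions are pooled, and metrics (accuracy at 0.5,
tie-corrected rank AUC, RMSE, R² = 1 − SSE/SST) are computed on the pooled
vector.  Learner settings are fixed small defaults, not tuned: LassoCV /
L1-logistic with an inner 5-fold path of 40 alphas (10 Cs), random forest
with 200 trees and leaf size 5, gradient boosting with 200 depth-3 trees
at learning rate 0.1.  The Gaussian-process learner (S3 only) uses a
single automatic-relevance squared-exponential kernel over the
standardised coordinates and the L1-pre-selected covariates plus a white
noise term; per-dimension length-scales let the kernel act as a spatial
smoother over the coordinates and an ARD weighting over the rest, which
subsumes a sum of separate kernels while staying within one standard
kernel implementation.  Exact inference is capped at `gp_max_train`
training points (random subset beyond that), so GP runs are practical only
at moderate n.

## Diagnostics

Classification residuals are observed label minus predicted probability —
a continuous vector to which Moran's I applies; regression residuals are
observed minus predicted.  Residuals are pooled across folds before
testing.  Coefficient inference refits the L1-selected support without
penalty (OLS or ML logistic) and reports Wald p-values; these carry the
usual post-selection caveat, which the output documents.  Permutation
importance is the mean change in score over repeated single-column
shuffles, signed so that positive always means the feature helps; ranking
ties break by feature name.

## Problem sizes and numerical conventions

The bundled study runs use the preset sizes above; calibration checks use
100–200 replicates with 199–999 permutations, and power/pattern checks use
10–20 seeds.  Envelope and grouped-median computations are vectorised by
padding district blocks to a common width and sorting, which keeps the
1000-permutation envelope at n = 3000 events and 100 districts well under
a second.  Tolerances: geometric conservation identities hold to 1e-9;
Moran statistics match brute-force evaluation to 1e-10; permutation
p-values are exact given the seed.
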