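# reportdelay

Spatial analysis and prediction of crime reporting delays.

Many serious crimes — sexual violence in particular — are reported to the
police only after substantial delay, and the delay distribution is heavily
right-tailed: medians of a few days coexist with a sizeable share of cases
reported a month or later.  This package implements an end-to-end framework
for asking *where* and *why* reporting is delayed, aimed at researchers in
spatial epidemiology and quantitative criminology working with open
incident-level police data:

* **Delay construction** — the delay of incident *i* is
  Δt_i = t_i^report − t_i^occurrence in whole days, with nested binary
  indicators d_i^day (Δt ≤ 1), d_i^week (Δt ≤ 7), d_i^month (Δt ≤ 30) and
  the regression target log(1 + Δt_i); per district *j* the proportions
  p_j = (1/n_j) Σ_{i∈j} d_i and median delays.
* **Population-weighted areal aggregation** — census-tract attributes are
  transferred to police districts through polygon intersection: the area
  fraction P^A_{j|k} = A(b_k ∩ a_j)/A(b_k) apportions the tract population
  x_k (assumed uniform) into x_{k∩j} = P^A_{j|k}·x_k, and the population
  proportions P^x_{k|j} = x_{k∩j}/x_j weight intensive attributes; totals
  are area-apportioned and summed.
* **Spatial autocorrelation** — global and local Moran's I under binary
  queen-contiguity, k-nearest-neighbour or same-district weights,

      I_global = m/S0 · Σ_{j,l} w_{jl}(p_j − p̄)(p_l − p̄) / Σ_j (p_j − p̄)²,

  with permutation pseudo p-values (add-one convention, upper tail).
* **Disparity tests** — a ranked-median permutation envelope (cases
  randomly reassigned to districts with district counts fixed) and
  one-sided Gini-coefficient and inter-decile-range tests on district
  median delays.
* **Staged predictive models** — five specifications (survivor-only NS1 up
  to the combined spatial model S3 with areal covariates and coordinates),
  four learners (L1 linear/logistic, random forest, gradient boosting,
  Gaussian process), 10-fold cross-validation with in-fold standardisation
  and feature selection, and a majority-class accuracy baseline.
* **Diagnostics** — residual spatial autocorrelation (Moran tests on pooled
  out-of-sample residuals), unpenalised coefficient refits with Wald
  p-values on the L1-selected support, and permutation feature importance.

A bundled synthetic-data generator reproduces the statistical structure of
such data — heavy-tailed integer-day delays, spatially autocorrelated
district effects, survivor/holiday covariate effects, occurrence-date
heaping on the 1st/15th, and both coordinate regimes (block-level points
vs district centroids) — so the whole stack is testable without any
external download.

## Worked example

```python
import reportdelay as rd

data = rd.generate(rd.preset("spatial", seed=1))
events = data.events

summary = rd.delays.area_summaries(events, data.districts["district_id"])
qw = rd.queen_weights(data.districts["geometry"],
                      ids=data.districts["district_id"].to_numpy())
res = rd.global_moran(summary["p_month"].to_numpy(), qw, n_perm=999, seed=1)
print(f"global Moran's I on p_month: I = {res.statistic:.3f}, "
      f"pseudo p = {res.pseudo_p:.3f}")

g = rd.disparity_test(events["delay_days"], events["district_id"],
                      "gini", n_perm=999, seed=1)
print(f"district median-delay Gini: {g.observed:.3f}, "
      f"one-sided p = {g.p_value:.3f}")
```

prints

```
global Moran's I on p_month: I = 0.210, pseudo p = 0.001
district median-delay Gini: 0.462, one-sided p = 0.005
```

The scenario injects a district random effect of SD 0.5 on the log-delay
scale, so the share of incidents reported within a month clusters strongly
across neighbouring districts (I = 0.21 against a null expectation of
−1/(m−1) ≈ −0.01), and the inequality of district median delays (Gini
0.462) is far beyond what random assignment of cases to districts produces.

## Analysis workflow

The numbered drivers under `analysis/` run the full study on the bundled
scenarios and write tables under `results/tables/`:

```sh
python analysis/01_simulate.py              # scenarios -> results/data/
python analysis/02_delay_descriptives.py    # delay distributions, district summaries
python analysis/03_aggregate.py             # tract -> district aggregation
python analysis/04_spatial_autocorrelation.py
python analysis/05_disparity.py             # envelope, Gini, inter-decile range
python analysis/06_models.py                # staged CV model comparison
python analysis/07_diagnostics.py           # residual Moran tests, coefficients, importance
```

`reportdelay.pipeline.run_pipeline(RunConfig(...))` runs the same stages in
one call (from a preset or from events-CSV + GeoJSON inputs) and writes a
manifest sufficient to reproduce every output.

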