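# carecast

Multi-state health transition estimation, discrete-step Markov population
projection, and long-term-care workforce demand forecasting for an elderly
(65+) population.

The pipeline models five ordered health states — healthy, mild, moderate
and severe ADL disability, plus an absorbing death state — stratified into
five age bands (65-69 … 85+):

1. **Estimate** age-stratified 3-year transition matrices from a two-wave
   panel, either by row proportions (optionally add-α smoothed) or by a
   multinomial logit fitted by maximum likelihood (saturated or additive
   design), with Wald or bootstrap confidence limits per probability.
2. **Project** a census-style baseline forward in 3-year Markov steps with
   cohort aging (band midpoints advance each step and select the matrix to
   apply), yielding state-specific population totals at the target year.
3. **Forecast demand** for nursing staff with the population-ratio method
   under configurable low/high staffing schedules.
4. **Validate & bound**: chi-square goodness of fit against an observed
   distribution; scenario bounds by pushing all probabilities to their
   confidence limits (with row renormalization); Monte Carlo intervals by
   row-wise Dirichlet posterior resampling of the matrix.

A synthetic-data module generates panels and census baselines with the
assumed statistical structure, and the package bundles (as plain text) a
published 2008→2011 CLHLS-derived transition matrix, the 2010 census state
totals, published 2025 projection totals, and the marginal counts of the
13,269-person estimation panel, so everything runs and is testable without
any survey microdata.

## CLI

Every stage is independently runnable; `run` chains them all:

```sh
carecast simulate --seed 1 --panel-out panel.csv --census-out census.csv
carecast estimate --panel panel.csv --design saturated --matrices-out matrices.csv
carecast project  --census census.csv --matrices matrices.csv --steps 5 --out projection.json
carecast demand   --totals projection.json --out demand.json
carecast validate --observed obs.json --expected exp.json
carecast run      --config config.yaml --seed 1 --out-dir out/
carecast report   --run-dir out/
```

`run` accepts a YAML/JSON config (see `carecast.pipeline.PipelineConfig`
for the keys); identical config + seed produces byte-identical artifacts,
and every output carries a provenance header (version, seed, config hash).

## Library sketch

```python
import numpy as np
import carecast as cc

matrices = cc.load_reference_matrices(normalize=True)
panel = cc.simulate_panel(matrices, cc.default_cohort_sizes(), seed=1)
counts = cc.count_transitions(panel)
fit = cc.fit_multinomial_logit(panel, design="saturated")
est = cc.predict_matrix(fit)            # == cc.empirical_matrix(counts)

census = cc.simulate_census(cc.CENSUS_STATE_TOTALS_2010, np.full(5, 0.2), year=2010)
result = cc.project(census, est.normalized(), n_steps=5)   # 2010 -> 2025
totals = cc.totals_by_state(result)
forecast = cc.demand_by_state(totals, cc.DEFAULT_SCHEDULES["low"])
print(forecast.demand_millions(), cc.total_demand(forecast))
```

## Notes

- The bundled transition fixture is transcribed verbatim from a
  four-decimal published table, so a few row sums deviate from 1 by up to
  2×10⁻⁴; `load_reference_matrices(normalize=True)` removes this before
  sampling or long projections.
- Matrices are per-3-year-step probabilities and are assumed stationary
  over the projection horizon; populations are projected as real-valued
  masses and rounded only at reporting.
- The default staffing schedules (1:10/8/6/4 and 1:5/4/2.5/1.5) are
  configuration defaults, replaceable via `--schedules` / the
  `schedule_file` config key.
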