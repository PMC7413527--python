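# fertresponse

Site-specific N-P-K fertilizer dose-response modelling for potato field
trials, built as a tested, reusable pipeline:

* **Synthetic trial generator** (`fertresponse.synth`) — seeded randomized
  complete block trials (N / P / K / factorial) with site covariates, daily
  weather for the study season plus five historical seasons, and targets
  (marketable yield, tuber size fractions, specific gravity) produced from a
  known Mitscherlich ground-truth surface with block effects and noise.
* **Preprocessing** (`fertresponse.preprocess`, `balances`, `weather`,
  `conversions`) — isometric log-ratio balances for soil texture/carbon,
  Mehlich-3 chemistry simplexes and soil types; measurement-method
  conversions (Walkley-Black→Dumas carbon, CaCl₂→water pH, Bray-2→Mehlich-3
  P, specific gravity from weights); rainfall Shannon diversity, cumulative
  precipitation, mean temperature and growing degree-days averaged over five
  historical seasons; multiplicative zero replacement for size fractions;
  z-score outlier cleaning; block-level 70/30 train/test splitting
  stratified by trial type; extra-trees feature-importance screening.
* **Mitscherlich surface** (`fertresponse.mitscherlich`) — the tri-variate
  diminishing-returns surface `Y = A·∏(1 − exp(−R_X(E_X + dose_X)))` with
  covariate-linear parameters behind positivity links and a trial-level
  random intercept on the asymptote; multi-start least squares plus Gaussian
  marginal likelihood; level-0 (random-effects-free) prediction.
* **ML suite** (`fertresponse.ml`) — KNN, random forest, single-hidden-layer
  tanh neural network and Matérn-kernel Gaussian process, tuned by seeded
  random search with 5-fold cross-validation; joint GP posterior mean,
  covariance and seeded sample draws.
* **Dose optimization** (`fertresponse.optimize`) — net return from a price
  model (defaults: N $1.20/kg, P $1.10/kg, K $0.90/kg, tubers $250/Mg),
  economic and agronomic optima over 1000-point random dose grids
  (N ≤ 250, P ≤ 110, K ≤ 208 kg/ha by default), response curves, GP
  posterior-sampled optimal-dose distributions, and conditional-expectation
  percentile doses; elemental→oxide dose conversion (×2.291, ×1.205).
* **Pipeline + CLI** (`fertresponse.pipeline`, `fertresponse.cli`) —
  reproducible generate → preprocess → fit → evaluate → optimize runs with a
  manifest of seeds, config hash and artifacts.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the desk-scale acceptance criteria
(analytic identities, brute-force equation oracles, Mitscherlich parameter
recovery, optimizer-vs-lattice oracles, GP sampling stability, and the
end-to-end tuned-model benchmark at ~20 % irreducible noise). The full
suite takes a few minutes on one CPU.

## CLI

```bash
fertresponse generate --n-trials 12 --trial-type mixed --seed 1 --out data/
fertresponse preprocess --trials data/trials.csv --weather data/weather.csv --out prep/
fertresponse fit-mitscherlich --train prep/trials_train.csv --out params.json
fertresponse run --outdir runs/demo --seed 1        # full pipeline
fertresponse report --trials data/trials.csv        # site P/Al risk indices
```

`fertresponse run` accepts a YAML config (`--config run.yaml`) mirroring the
fields of `fertresponse.pipeline.RunConfig` (target variable, model
families, search iterations, grid bounds, prices, seeds). Every run writes
`manifest.json` with the config hash and seeds; reruns with the same config
reproduce metrics bit-for-bit.

## Typical library use

```python
from fertresponse import (GeneratorConfig, generate_trials, economic_optimum,
                          DoseGrid, PriceModel)
from fertresponse.mitscherlich import fit
from fertresponse.optimize import surface_response

trials, weather, truth = generate_trials(GeneratorConfig(n_trials=12, seed=1))
result = fit(trials, seed=0)
rec = economic_optimum(surface_response(result.params), DoseGrid.uniform(1000, seed=1),
                       PriceModel())
print(rec.optimum, rec.net_return)
```
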