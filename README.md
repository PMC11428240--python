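# bovitherm

Biophysical feature engineering and optimized machine-learning benchmarking
for predicting the core body temperature (CBT) of dairy cows.

The package implements a complete, reproducible pipeline:

1. **Synthetic cohort generation** (`bovitherm.synthetic`) — tabular cow
   observations (environment, animal covariates, infrared ROI temperatures,
   rectal CBT) drawn from a documented generative model with configurable
   missingness and outliers, so every downstream stage can be tested
   against known ground truth.
2. **Preprocessing** (`bovitherm.preprocess`) — categorical encoding
   (A.M./P.M. and standing/lying-down to 0/1), median imputation, and
   z-score outlier capping at mean ± 3·std computed from pre-replacement
   statistics.
3. **Thermal features** (`bovitherm.thermal`) — seven thermal-comfort
   indices (THI, BGHI, ATHI, CCI, DHLI, ETIC, STIC), the intermediate
   physiological state (skin/coat/exhaled-air temperatures, sweating rate,
   vapor pressures, respiratory quantities, Nusselt number), and the
   sensible/latent heat-flux partition (Qresp, Qevap, Qconv, Qrad, Qlat,
   Qsens).
4. **Feature sets** (`bovitherm.featuresets`) — the 33-entry benchmark
   registry: ENV, ANM, one set per infrared ROI (average and maximum), one
   per comfort index, one per heat flux.
5. **Model benchmarking** (`bovitherm.bench`) — six regression families
   (EN, ANN, RF and three gradient-boosting variants) behind one uniform
   interface with an 80/20 shuffled split, 5-fold CV, and R²/MAE/RMSE
   metrics.  The boosting families carry the published hyperparameter
   spaces and are backed by scikit-learn gradient-boosting estimators
   (no compiled third-party dependencies).
6. **Grey wolf optimizer** (`bovitherm.gwo`) — native GWO over mixed
   continuous/log/integer/categorical spaces on the unit hypercube, with a
   pluggable `minimize(objective, space, config)` convention for
   alternative optimizers.  Tuning fitness is mean 5-fold CV RMSE on the
   training partition.
7. **SHAP explanations** (`bovitherm.explain`) — an exact, polynomial-time
   tree-path-dependent SHAP implementation for scikit-learn tree ensembles
   (numba-accelerated, validated against brute-force Shapley enumeration),
   plus summary / dependence / waterfall data products.
8. **Orchestration** (`bovitherm.pipeline`, `bovitherm.cli`) — one-command
   end-to-end runs with YAML config, per-stage seed derivation, and a
   provenance manifest.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (formula oracles,
exact flux identities, preprocessing contract, GWO sphere convergence,
pipeline noise-floor recovery, SHAP additivity/stability, determinism).

## CLI

```bash
# full pipeline from one config
bovitherm all --seed 1 --out runs/demo

# or stage by stage
bovitherm generate --seed 1 --n-days 30 --out cohort.csv
bovitherm preprocess cohort.csv --out processed.csv --report report.json
bovitherm features processed.csv --out featured.csv
bovitherm bench featured.csv --out results.csv --seed 1
bovitherm tune featured.csv --family XGBoost --set IRTave_TK \
    --population 30 --epochs 200 --seed 1 --out tuned.json
```

A run directory contains the cohort and truth tables, the preprocessing
report, the feature table, tidy benchmark results (per set × family ×
split), tuned-model artifacts with the convergence curve, SHAP value /
summary / waterfall tables, and `manifest.json` with all seeds and
versions.  Re-running with the same config reproduces all numeric outputs.

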