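# nirboost

NIR spectral calibration for fruit quality (total soluble solids, °Brix):
robust-PCA outlier screening, z-score pretreatment, Kennard–Stone sample
partitioning, repeated noise-augmented UVE wavelength selection with
frequency-tier stratification, tier-specific PLS member models, and an
AdaBoost-style weighted ensemble. A built-in synthetic NIR spectra generator
with known informative bands makes every stage testable without proprietary
data.

## Package layout

| module | contents |
|---|---|
| `nirboost.dataio` | `SpectraSet` container, wide-CSV read/write, versioned JSON model artifacts |
| `nirboost.synthetic` | `SimConfig`/`simulate`: Gaussian-band spectra with response-coupled bands, baseline/scatter/noise nuisances, planted outliers with ground truth |
| `nirboost.preprocess` | z-score fit/apply, projection-pursuit robust PCA outlier screening (score + orthogonal distances, chi-squared cutoffs) |
| `nirboost.sampling` | Kennard–Stone max–min split (`kennard_stone`, `split_dataset`) |
| `nirboost.plsr` | NIPALS PLS1 (`pls_fit`, `pls_predict`), latent-variable path, k-fold cross-validation |
| `nirboost.uve` | single UVE run (noise-augmented coefficient stability), `uve_repeat`, frequency tiers (high ≥ 90/100, mid 30–89, low 1–29) |
| `nirboost.ensemble` | `adaboost_fit`/`ensemble_predict`: graded-loss error weighting of pre-built PLS members |
| `nirboost.metrics` | RMSE / Pearson r / MAE / bias with fixed conventions (bias = mean(predicted − measured)) |
| `nirboost.pipeline` | `run_full` end-to-end orchestration and the model-comparison table |

## CLI

```bash
nirboost simulate --n 189 --n-points 1557 --seed 7 --out spectra.csv --truth truth.json
nirboost screen   --in spectra.csv --k 2 --significance 0.95 --report screen.json --out clean.csv
nirboost split    --in clean.csv --ratio 0.7 --out-cal cal.csv --out-pred pred.csv
nirboost uve      --in cal.csv --runs 100 --noise 200 --confidence 0.99 --seed 7 --profile profile.json
nirboost fit      --in cal.csv --max-lv 15 --model m1.json
nirboost boost    --members m1.json --members m2.json --cal cal.csv --out ensemble.json
nirboost run      --in spectra.csv --seed 7 --out comparison.csv   # whole workflow
```

`nirboost run` without `--in` simulates a default dataset first. A YAML file
passed via `--config` overrides any `PipelineConfig`/`UVEConfig` field.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: PLS–OLS and
Kennard–Stone oracle equivalences, UVE false-positive calibration and
planted-band recovery, outlier-screening recovery and Monte-Carlo
calibration, closed-form ensemble weight checks, ensemble dominance over 20
seeded end-to-end runs, and determinism/no-leakage assertions.

## Conventions worth knowing

- z-score uses the sample SD (ddof = 1); standardization statistics are
  always fit on calibration data only.
- Kennard–Stone ties resolve to the lowest row index; distances are computed
  on per-column standardized spectra.
- UVE stability is mean/SD of fold-wise PLS coefficients; the cutoff is the
  confidence-level quantile of |noise-column stability| (noise columns are
  Uniform(0,1) × 1e−10 by default, Gaussian optional).
- AdaBoost weighting scores each pre-built member against uniform sample
  weights by default (identical members get exactly equal weights); pass
  `update_sample_weights=True` for the classic sequential reweighting sweep.
- Member losses use a two-knot piecewise-linear map of the absolute
  cross-validated calibration deviation with knots at 1.0 and 1.5 °Brix.
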