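# specsel

Wrapper selection of spectral variables (wavelengths): a generational
genetic algorithm searches for small subsets of variables, scored by the
training error of one-vs-rest soft-margin SVMs built on each candidate
subset. Designed for classifying absorbance spectra into concentration
classes, and validated on synthetic mid-IR-like spectra with planted
informative wavelengths.

## What's inside

| module | role |
| --- | --- |
| `specsel.spectral_data` | labeled sample sets, CSV I/O, role splits (train/test/commercial), variable projection (1-based indices everywhere) |
| `specsel.svm_core` | linear/gaussian/polynomial kernels, binary soft-margin training (libsvm backend, decision values recomputed from the stored dual expansion), classification MSE, one-vs-rest machinery, strict per-sample error accounting, random hyperparameter search |
| `specsel.ga_engine` | variable-length chromosomes of distinct indices, roulette selection, uniform crossover/mutation with duplicate repair, generational replacement with elitism, convergence/stagnation stopping |
| `specsel.fitness_bridge` | the two SVM fitness variants (`mse_train`, `mse_train_plus_test`), cached per subset, plus strict-error reports per role |
| `specsel.synthetic_spectra` | generator of spectra with planted informative wavelengths, correlated neighbors, smooth baseline and white noise; the answer key is returned with every dataset |
| `specsel.cli` | `specsel generate / optimize / select / evaluate` |

Everything is deterministic under a single master seed: SVM training uses a
deterministic solver, and the GA derives independent named substreams for
initialization, selection, crossover and mutation. Two runs with the same
seed produce byte-identical output files.

## CLI walkthrough

```sh
# 1. synthesize a dataset (5-class "high concentration" design, 151 samples)
specsel generate --preset high --seed 1 --out data/

# 2. random search over (C, epsilon, sigma); report ranked by training MSE
specsel optimize --data data/spectra.csv --n 100 --seed 1 --out search.csv

# 3. evolve 2-variable subsets (pop 100, 100 generations by default)
specsel select --data data/spectra.csv --seed 1 \
    --variant mse_train_plus_test --params 10000,0.000001,5 --out run/

# 4. re-score a stated subset
specsel evaluate --data data/spectra.csv --subset 94,95 \
    --params 10000,0.000001,5
```

`select` writes `generations.csv` (per-generation best/mean fitness),
`ranked_subsets.csv` (all distinct subsets encountered, best first),
`reports.csv` (strict error counts per role for the top subsets) and
`run_meta.json`. Every file embeds the resolved seed and configuration.

Exit codes: 0 success, 2 configuration error, 3 data error, 4 runtime
failure.

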