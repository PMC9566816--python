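# sparrowkelm

A sparrow-search-optimized kernel extreme learning machine (KELM) for binary
tabular classification, together with the apparatus used to validate the
optimizer: the 23 classical box-constrained benchmark functions, a baseline
and an enhanced sparrow search algorithm, confusion-matrix metrics, paired
signed-rank comparison, and a cross-validated disease-prediction pipeline.

## Components

| module | what it does |
| --- | --- |
| `sparrowkelm.benchmarks` | the 23 classical test functions (F1–F23) with dims, boxes and reference optima |
| `sparrowkelm.ssa` | baseline sparrow search algorithm (producer / scrounger / scout updates) |
| `sparrowkelm.egssa` | enhanced variant: hunger-state producer foraging, a decaying sign-randomized balance factor, and greedy Cauchy perturbation of the incumbent |
| `sparrowkelm.kelm` | Gaussian-kernel ELM classifier with a closed-form regularized dual solve |
| `sparrowkelm.metrics` | ACC / sensitivity / specificity / MCC from 2×2 confusion counts |
| `sparrowkelm.tuning` | search of (kernel width k, regularization c) in log2 space with 10-fold CV accuracy as fitness |
| `sparrowkelm.data_io` | delimited-text loading with schemas, missing-row removal, [−1, 1] normalization, k-fold splits, synthetic two-class generator |
| `sparrowkelm.experiments` | benchmark suites (avg/std over R seeded runs), signed-rank comparison, outer-CV prediction pipeline |

Schemas for six classic UCI-style clinical tables (breast cancer, heart
disease, Parkinson, autism screening for children, Cleveland, BUPA) ship with
the package (`sparrowkelm/schemas/`); the data files themselves are not
redistributed — the synthetic generator covers offline testing.

## CLI

```sh
# benchmark experiment: 30 runs of both optimizers on every function
sparrowkelm bench run --functions all --optimizers egssa,ssa \
    --runs 30 --pop 30 --iters 500 --seed 0 --out runs/bench
sparrowkelm bench compare --report runs/bench --pair egssa,ssa

# synthetic data + prediction pipeline
sparrowkelm synth --n 300 --sep 6 --seed 0 --out data.csv
sparrowkelm predict --data data.csv --folds 10 --pop 10 --iters 50 --seed 0

# a real table with a schema (or one of the shipped ones)
sparrowkelm predict --data breast-cancer-wisconsin.data --builtin breast_cancer

# benchmark registry dump
sparrowkelm registry --out benchmarks.csv
```

`predict --paper-mode` normalizes and tunes on the full dataset before the
k-fold evaluation (the simpler but leakage-prone protocol); the default
normalizes and tunes within each outer training partition.

## Notes

* Optimizer runs are bit-reproducible for a given seed; the RNG draw order
  is documented in `ssa.py`.
* The enhanced optimizer deliberately collapses producer coordinates to
  exactly 0 once the gap to the incumbent underflows, which is why
  origin-optimum benchmarks (F1, F9, F11) bottom out at exactly 0.0 and the
  Ackley function at its double-precision floor.
* The commonly tabulated `[1, 3]` range for the 3-d Hartmann function (F19)
  is a propagated typo; the canonical `[0, 1]^3` box is used (the tabulated
  minimum −3.86 is unreachable on `[1, 3]^3`).
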