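# pyroage

Single-locus DNA-methylation age prediction from pyrosequencing tables:
exhaustive CpG-combination model search across six regression families,
technical-replicate scheme evaluation, QC/pooling/splitting, and a
synthetic-data generator so the whole pipeline runs end to end without any
external download.

The pipeline operates on seven promoter CpG sites measured as percent
methylation. It enumerates every non-empty CpG subset (127 combinations)
for a two-CpG linear baseline, three support-vector kernels (radial,
linear, polynomial), gradient-boosted trees and a matrix-completion
approach, and every non-empty subset of the 14 quadratic-regression
variables (methylation values plus their squares; 16,383 combinations) —
17,018 models in a full six-family search. Each model is scored by Pearson
R, MAD and RMSE on both the training and testing set, and best
combinations are reported under both references.

## Modules

| module | contents |
|---|---|
| `pyroage.io_qc` | CSV/TSV methylation tables, pooling, outlier/missing-value exclusions, reproducible train/test splits, prediction I/O |
| `pyroage.synthetic` | synthetic cohorts (quadratic age curves, shared latent factor, batch offsets) and 3-PCR × 2-PSQ replicate grids |
| `pyroage.models` | predictor combinations with canonical labels; OLS (baseline + quadratic), SVR (r/l/p), gradient boosting; model archives |
| `pyroage.imputation` | age prediction by regularized iterative-PCA matrix completion (ages of the unknown set as missing cells) |
| `pyroage.search` | metrics, exhaustive search with checkpoint/resume, best-combination selection, model averaging, the five replicate schemes, VIF diagnostics |
| `pyroage.pipeline` / `pyroage.cli` | inter-laboratory optimization recipe, provenance, command-line interface |

## CLI

```bash
# synthetic cohort + replicate grids
pyroage simulate --n 1000 --seed 7 --out runs/sim

# QC -> split -> exhaustive search
pyroage qc --input runs/sim/cohort.csv --out runs/qc
pyroage split --input runs/qc/qc_table.csv --n-training 700 --seed 7 --out runs/split
pyroage search --training runs/split/training.csv --testing runs/split/testing.csv \
    --families mqr,svm_r,svm_l,svm_p,gbr,mmda --checkpoint --out runs/search

# single model fit / predict / report
pyroage fit --training runs/split/training.csv --family svm_r \
    --combination "CpG_2-3,5-7" --out runs/model.joblib
pyroage predict --model runs/model.joblib --input runs/split/testing.csv \
    --out runs/pred.csv
pyroage report --predictions runs/pred.csv --out runs/report

# replicate schemes and the local-lab optimization recipe
pyroage evaluate-replicates --replicates runs/sim/replicates.csv \
    --ages runs/sim/cohort.csv --model runs/model.joblib --out runs/schemes.csv
pyroage optimize-lab --training runs/split/training.csv \
    --validation my_lab_validation.csv --families mqr,svm_r,gbr --out runs/lab
```

Exit codes: 0 success, 2 invalid input/configuration, 3 unexpected runtime
failure. Every output directory receives a `run_config.yaml` with the
resolved configuration, seeds and package version.

Combination labels are canonical and parseable: `CpG_2-3,5-7` for CpG
subsets, `CpG_4-6 & CpG_2²-4²,6²-7²` for quadratic-regression variable
sets (linear terms, then squared terms).

## Notes

* Published-accuracy figures (testing MAD ≈ 4.4–4.8 for the best
  families) depend on the original studies' deposited datasets and
  unstated SVM/GBR hyperparameters, so they are not reproduced offline.
  If those datasets are placed under `data/supplementary/` as
  `training.csv`/`testing.csv` in the standard table layout, the stretch
  test in `tests/test_acceptance.py` checks the published 8-variable
  quadratic combination against its printed testing MAD (±0.3 years);
  otherwise it skips.
* The full six-family search on a 1,413-sample cohort takes ≈ 2 minutes
  on one CPU; the CI-scaled profile (n = 300, 100 boosting iterations)
  runs in ≈ 20 seconds.
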