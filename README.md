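# ctgsvm

Three-class fetal-state classification (normal / suspect / pathologic) from
cardiotocogram (CTG) feature tables, using a least-squares support vector
machine (LS-SVM) whose hyperparameters are tuned by particle swarm
optimization (PSO), extended to three classes with a binary decision tree
(BDT) of two node classifiers.

## What's inside

| module | role |
| --- | --- |
| `ctgsvm.lssvm` | Binary LS-SVM: Gaussian RBF kernel, training as one dense (N+1)×(N+1) KKT linear solve, decision values and sign prediction, JSON model serialization |
| `ctgsvm.pso` | Particle swarm optimizer (inertia / personal-best / social update, box-clamped) and the (γ, σ²) tuner searching log₂ space over [−4, 12]² with internal stratified-CV accuracy as fitness |
| `ctgsvm.tree` | Class-partition plans (generic R classes, R−1 splits) and the fixed CTG tree: root {pathologic, suspect} vs {normal}, then pathologic vs suspect; per-node PSO tuning; tree serialization |
| `ctgsvm.folds` | Seeded stratified k-fold assignment |
| `ctgsvm.evaluation` | Nested cross-validation, confusion matrix (rows = predicted, columns = actual), column-normalized confusion-ratio matrix, overall accuracy, sensitivity/specificity, cobweb (radar) misclassification plot with the 1/R chance polygon |
| `ctgsvm.data` | CSV reader for the 21-feature CTG schema (NSP labels 1/2/3), z-score standardization, seeded spherical-Gaussian synthetic generator with CTG-like class imbalance, prediction writer |
| `ctgsvm.cli` | `ctgsvm` command with `crossval`, `train`, `predict`, `synth`, `cobweb` subcommands |

## CLI usage

```sh
# synthesize an imbalanced three-class table (CSV with NSP column)
ctgsvm synth --counts 330,60,36 --separation 4 --seed 7 --out synthetic.csv

# 10-fold cross-validation of the full nested pipeline
ctgsvm crossval --data synthetic.csv --k 10 --seed 7 --out report/
# ... or directly on generated data: ctgsvm crossval --synthetic 330,60,36

# train on everything, then predict
ctgsvm train --data synthetic.csv --seed 7 --out tree.json
ctgsvm predict --model tree.json --data synthetic.csv --out predictions.csv

# cobweb figure from a confusion-ratio CSV (rows predicted, columns actual)
ctgsvm cobweb --ratios ratios.csv --out cobweb.svg
```

`crossval` writes `metrics.json` (fold accuracies, mean and pooled
accuracy, confusion counts and ratios, per-class one-vs-rest
sensitivity/specificity, cobweb values, per-fold chosen hyperparameters),
`confusion_counts.csv`, `confusion_ratios.csv` and `cobweb.svg`/`.png`.
A single `--seed` drives stratification, PSO and the generator, so reruns
are byte-identical. `--no-scaling` disables the default per-node z-score
feature standardization.

Swarm settings can be overridden via `--config` (YAML or JSON):

```yaml
swarm:
  n_particles: 25
  inertia: 0.75
  c1: 2
  c2: 2
  log2_bounds: [[-4, 12], [-4, 12]]
  max_iterations: 50
inner_cv_folds: 5
```

## Real CTG data

The reader consumes delimited text (comma or semicolon) with a header
containing the 21 feature names (`LB, AC, FM, UC, DL, DS, DP, ASTV, MSTV,
ALTV, MLTV, Width, Min, Max, N_max, N_zeros, Mode, Mean, Median, Variance,
Tendency`, case/underscore-insensitive) plus an `NSP` or `CLASS` column
coded 1=normal, 2=suspect, 3=pathologic. The public UCI Cardiotocography
workbook can be used after a one-line export of its data sheet to CSV.
Rows with missing or non-numeric values are rejected (with logged line
numbers), not imputed.

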