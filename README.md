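# dockvote

Consensus classification of transporter inhibitors/non-inhibitors by fusing
two prediction channels:

1. **ML votes** — a nine-member ensemble trained on undersampled,
   approximately balanced subsets of an imbalanced compound set (nested
   9-fold cross-validation with inner 5-fold hyperparameter tuning,
   majority voting, and a 0–9 vote sum as score);
2. **Docking scores** — externally supplied raw scores (more negative =
   stronger predicted binding), negated before use.

Both channels are min–max normalized against fixed, training-set-derived
bounds (votes: 0/9; negated docking: −2.80/12.073) and summed into a
consensus score in [0, 2]. Decision thresholds are taken at the crossing
of class-conditional Gaussian KDEs (shipped defaults: docking −6.52,
consensus 0.82). The package also covers molecule standardization (salt
stripping, charge neutralization, stereochemistry removal,
inorganic/metal filtering, duplicate merging), ECFP4/Tanimoto
applicability-domain analysis, full classification metrics, and a seeded
synthetic-data generator so the whole pipeline is testable offline.

## Layout

| module | purpose |
|---|---|
| `dockvote.synthetic_data` | seeded Gaussian datasets + docking scores + SMILES fixture |
| `dockvote.standardize` | standardization pipeline, duplicate merging, reject bookkeeping |
| `dockvote.descriptors` | ECFP4, Tanimoto, Crippen logP, continuous descriptor tables |
| `dockvote.imbalance_cv` | fold plans, undersampling nested CV, tuning, final ensembles |
| `dockvote.ensemble_predict` | vote predictions, majority labels, vote-sum ROC |
| `dockvote.consensus` | min–max fusion, KDE thresholds, metrics, imputation |
| `dockvote.applicability` | Tanimoto k-NN applicability domain |
| `dockvote.cli_io` | config, end-to-end pipeline, `dockvote` CLI |

## CLI

```bash
# seeded synthetic dataset (descriptors + docking scores)
dockvote simulate --n-active 84 --n-inactive 1048 --effect-size 3 \
    --dock-gap 2 --seed 1 --out-descriptors desc.csv --out-dock dock.csv

# end-to-end: split 80/20, nested CV (or --no-tune), retrain 9-member
# ensemble, predict votes, fuse with docking, write metrics
dockvote run --descriptors-csv desc.csv --dock-csv dock.csv \
    --algorithm RF --seed 1 --out-dir out/

# individual stages
dockvote standardize compounds.csv --out std.csv --duplicate-map dup.csv
dockvote featurize std.csv --out fp.csv
dockvote predict out/model new_descriptors.csv --out votes.csv
dockvote consensus votes.csv dock.csv --out consensus.csv
dockvote domain query_fp.csv reference_fp.csv --out neighbors.csv
```

Pipeline defaults (9 outer folds, 5 inner folds, 9 subsets, the fixed
normalization bounds and thresholds above) can be set in a `key = value`
config file passed via `dockvote run --config`.

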