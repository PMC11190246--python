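# gcn16s

Predict 16S rRNA gene copy numbers (GCN) directly from sequence, and use the
predictions to correct amplicon community profiles.

## Why

16S amplicon surveys measure read fractions, but prokaryotic genomes carry
1-21 copies of the 16S gene, so read share is proportional to
`cells x GCN`, not cells. Quantitative profiling therefore divides each
taxon's read fraction by an estimate of its copy number:

```
reads_i ∝ cells_i · g_i        corrected_i ∝ reads_i / ĝ_i
```

Classical estimators infer `ĝ` from taxonomy (average over a lineage tree)
or phylogeny (hidden-state prediction on a reference tree). This package
implements a third route — a stacked ensemble that regresses copies/genome
directly from the 6-mer content of the sequence — together with both
families of baselines, the correction arithmetic with mock-community
Bray-Curtis evaluation, and a Kernel-SHAP pipeline that maps the model's
attention back onto alignment coordinates.

## The model

A sequence becomes a vector of 6-mer counts. Two base learners read it:
an MLP (hidden layers 489-926-645-929-582-82; activations
GELU/ReLU/ReLU/ELU/GELU/Linear; Adam on the RMSE loss) and an RBF-kernel SVR
(C = 11, γ = 'auto') on the top-100 PCA scores. A ridge meta-learner
(α = 49, unpenalized intercept, closed form) aggregates
`[mlp_pred, svr_pred, 100 PCA scores]` into the final estimate, clamped to
≥ 1 copy/genome. The five phylogenetic baselines are subtree averaging,
empirical probabilities, Sankoff maximum parsimony, weighted squared-change
parsimony and independent contrasts; the taxonomy baseline averages child
taxa bottom-up and answers queries by deepest matched rank. See
`docs/methods.md` for the full account, including what the synthetic-data
generators do and do not emulate.

## Worked example

```python
import numpy as np
from gcn16s import (SEMConfig, sem_train, sem_predict, evaluate_rmse,
                    make_benchmark, SimulationConfig,
                    reads_from_cells, correct_composition, bray_curtis)

# a seeded synthetic study: tree, sequences, copy-number labels
bench = make_benchmark(SimulationConfig(n_tips=400, seq_length=300, seed=42))
records = bench.sequences.records
labels = np.array([bench.traits[r.id] for r in records])

# train on 300 sequences, evaluate on the held-out 100
rng = np.random.default_rng(0)
order = rng.permutation(len(records))
train, test = order[:300], order[300:]
model = sem_train([records[i] for i in train], labels[train],
                  SEMConfig.desk(seed=0, out_of_fold_stacking=True))
pred = sem_predict(model, [records[i] for i in test])
print(f"held-out RMSE: {evaluate_rmse(pred, labels[test]):.3f} copies/genome "
      f"(label SD {labels[test].std():.3f})")

# correct a 10-taxon community (taxa chosen across the copy-number range)
spread = np.argsort(labels[test])[::10][:10]
cells = rng.uniform(1e3, 2e4, size=10)
reads = reads_from_cells(cells, labels[test[spread]])
corrected = correct_composition(reads, pred[spread])
truth = cells / cells.sum()
print(f"BC uncorrected: {bray_curtis(truth, reads):.4f}")
print(f"BC corrected:   {bray_curtis(truth, corrected):.4f}")
```

Output:

```
held-out RMSE: 0.422 copies/genome (label SD 1.737)
BC uncorrected: 0.0983
BC corrected:   0.0190
```

The model explains most of the trait variance from sequence alone (RMSE 0.42
against a label SD of 1.74), and dividing the read fractions by its
predictions moves the community profile five-fold closer (Bray-Curtis 0.098
→ 0.019) to the true cell fractions.

A command-line interface wraps the same functionality
(`gcn16s --help`): `prep` (orientation + primer trimming), `kmerize`,
`train` / `predict`, `baseline-tax`, `baseline-phylo`, `correct`,
`mock-eval`, and `simulate`.

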