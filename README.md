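# atpbind

Residue-level prediction of protein–ATP binding sites from per-residue
protein-language-model embeddings, using a weighted ensemble of two
heterogeneous classifiers:

- a **local–global dual-attention transformer**: each residue's embedding
  (1280 values from ESM-2, or any configured width) is projected to a
  384-wide feature vector, treated as a sequence of scalar positions, and
  processed by a global self-attention branch (all positions) and a local
  branch (non-overlapping windows of 32 positions), fused by a learnable
  convex weight and classified through a sigmoid-gated dynamic-weight head;
- a **deep Q-network** that frames classification as a one-step decision
  process with ε-greedy exploration, shaped rewards (+1.0 correct, −0.5
  wrong, terminal bonus 2.0 × batch accuracy), experience replay and a
  periodically synchronised target network.

The final score for residue *i* is the convex combination

    p(i) = w · p_transformer(i) + (1 − w) · p_DQN(i),    w ∈ [0, 1],

with *w* selected by chain-level cross-validation to maximise mean MCC
(AUC tie-break). ATP-binding residues are rare (≈ 4% of residues in the
standard benchmarks, non-binding:binding ratios 20.8–28.1), so training
and evaluation are built around imbalance-robust machinery: focal loss
(γ = 2.0, α = 0.2), a differentiable MCC penalty 0.7 · (1 − max(MCC, 0))
on soft confusion counts, a supervised contrastive branch on an
L2-normalised 256-dim projection, positive-class oversampling, and
MCC-optimal decision thresholds with

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

The package is written for sequence-analysis researchers who want a
fully testable reference implementation: a synthetic-data generator with
a closed-form Bayes-optimal oracle stands in for external embeddings, so
every stage — losses, training loops, ensembling, evaluation — can be
exercised and verified end to end without any download.

## Worked example

Train both classifiers on a synthetic dataset with a known planted signal,
select the ensemble weight by cross-validation, and evaluate on an
independent draw:

```python
import numpy as np
from dataclasses import replace
from atpbind import SynthConfig, generate_dataset, oracle_scores
from atpbind.transformer import LocalGlobalTransformer, TransformerConfig
from atpbind.dqn import DQNClassifier, DQNConfig
from atpbind.ensemble import WeightedEnsemble, EnsembleSpec
from atpbind.evaluation import evaluate_scores, roc_auc
from atpbind.pipeline import assign_folds

base = SynthConfig(n_chains=60, chain_length_range=(100, 200), dim=64,
                   informative_dim=16, separation=4.0, seed=0)
train = generate_dataset(base)
test = generate_dataset(replace(base, n_chains=20, seed=1))

tcfg = TransformerConfig(in_dim=64, proj_dim=48, token_dim=8, heads=4,
                         window=16, max_epochs=5, patience=3, seed=0)
t_fit = LocalGlobalTransformer.from_dataset(train, tcfg).fit()
d_fit = DQNClassifier.from_dataset(train, DQNConfig(in_dim=64, episodes=20, seed=0)).fit()

folds = assign_folds(train.groups, 5, seed=0)
fold_scores = []
for k in range(5):
    m = np.array([folds[g] == k for g in train.groups])
    fold_scores.append((t_fit.predict_proba(train.X[m]),
                        d_fit.predict_proba(train.X[m]), train.y[m]))
ens = WeightedEnsemble(fold_scores, EnsembleSpec()).fit()

fused = ens.fuse(t_fit.predict_proba(test.X), d_fit.predict_proba(test.X))
print(t_fit.summary()); print(d_fit.summary()); print(ens.summary())
print("independent test:", evaluate_scores(fused, test.y).summary())
print("Bayes oracle test AUC: %.3f" % roc_auc(oracle_scores(test), test.y).area)
```

which prints:

```
Local-global dual-attention classifier
  epochs run: 5 (best epoch 3)
  validation: ACC 0.992  Sen 0.864  Spe 0.996  MCC 0.868  AUC 0.997  threshold 0.4339
  window 16, proj_dim 48, heads 4
Deep Q-network classifier
  episodes: 20  final epsilon 0.9046
  greedy training accuracy: 0.991
  validation: ACC 0.994  Sen 0.909  Spe 0.997  MCC 0.918  AUC 0.998  threshold 0.4000
Weighted probability ensemble
  transformer weight: 0.00  (DQN weight 1.00)
  selection-fold mean MCC 0.926, mean AUC 0.998
independent test: ACC 0.993  Sen 0.816  Spe 0.999  MCC 0.889  AUC 0.989  threshold 0.4074
Bayes oracle test AUC: 0.997
```

Reading the numbers: both classifiers recover the planted class structure
(validation AUC ≈ 1 against a Bayes-oracle ceiling of 0.997 on the test
draw); the ensemble weight search lands on an endpoint here because on a
task this easy the two base classifiers tie at almost every grid weight,
and ties resolve towards the smaller transformer weight. The independent
test row is the honest estimate: MCC 0.889 at the MCC-optimal threshold
0.41, sensitivity 0.816 at specificity 0.999 under ≈ 25:1 imbalance.

The same workflow is available from the shell via the `atpbind` CLI
(`simulate`, `embed`, `train-transformer`, `train-dqn`,
`optimize-ensemble`, `predict`, `evaluate`, `cv`, `window-sweep`); run
`atpbind --help` for the subcommand reference. Real embeddings come from
the optional external ESM-2 adapter (`esm2_t33_650M_UR50D`); when that
package is absent the adapter raises a clear capability error and cached
or synthetic features are used instead.

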