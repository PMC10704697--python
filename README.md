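# solubgcn

Continuous protein solubility prediction with a hybrid graph convolutional
network and adaptive per-channel feature re-weighting.

## The problem

Protein solubility — here the supernatant-to-total ratio measured in
cell-free expression experiments, a continuous value in [0, 1] — is a key
screening property in protein engineering and pharmaceutical production.
Sequence-based predictors describe each residue with several complementary
feature blocks: amino-acid probabilities from a protein language model (ESM,
20 channels), BLOSUM62 substitution rows (20), AAPHY7 physicochemical
properties (7), PSSM (20) and profile-HMM (30) evolutionary profiles, and
predicted structural properties (SPIDER3, 14).  Stacked column-wise these
give a hybrid per-residue feature `H ∈ R^{L×C}` with `C = 111` channels, but
the blocks live on different scales and are far from equally informative.

`solubgcn` implements a regression architecture that addresses this:

1. **Adaptive feature re-weighting (AFR).** A learned gate per channel:
   global average pooling `G_c = (1/L) Σ_i H_{ic}`, a dense cross-channel
   interaction `O = G Vᵀ`, rectification `P = max(0, O)`, a logistic gate
   `W_c = σ(P_c)`, and the channel-wise product `R = H ⊗ W`.  Channels that
   help the prediction are excited; the gate vector doubles as a feature
   importance diagnostic.
2. **Graph convolution over the contact map.** The L×L predicted
   contact-probability matrix (with unit self-loops, symmetric degree
   normalization `D^{-1/2}(A+I)D^{-1/2}`) defines weighted residue–residue
   edges; stacked GCN layers `X ← ReLU(Â X Θ)` fuse node and edge
   information.
3. **Self-attention readout.** Two fully connected layers with tanh and a
   per-protein softmax produce normalized residue attention; the pooled
   representation feeds a sigmoid head, so predictions lie strictly in (0, 1).
   Training minimizes RMSE, the primary evaluation metric.

The package also provides the full metric suite (RMSE, R², accuracy,
precision, recall, F1 and rank-statistic AUC at the 0.5
soluble/insoluble threshold), the 5-fold × 5-seed cross-validation and
ensembling protocol, feature/module ablation grids, and a synthetic-data
generator that plants known-relevant channels so the whole pipeline —
including gate recovery — is testable without any external feature
extractors.  The network is implemented in vectorized numpy with
hand-written, finite-difference-verified backpropagation; batches of
proteins are processed as one block-diagonal sparse graph.

## Worked example

```python
import numpy as np
import solubgcn as sg

# synthetic dataset: 120 proteins, planted signal in ESM and HMM channels
config = sg.SimConfig(n_proteins=120, length_range=(30, 60), seed=0)
records, truth = sg.simulate_dataset(config)
train, test = records[:96], records[96:]

est = sg.HybridGCNRegressor(
    gcn_hidden=64, attention_hidden=32, dropout=0.1,
    max_epochs=60, patience=15, random_state=0,
)
est.fit(train)

y = np.array([r.solubility for r in test])
metrics = sg.evaluate_predictions(y, est.predict(test))
print(f"held-out RMSE = {metrics.rmse:.3f}, R^2 = {metrics.r2:.3f}, AUC = {metrics.auc:.3f}")

report = sg.relevance_recovery_report(est, truth)
print(f"mean gate on planted channels = {report['mean_weight_informative']:.3f}")
print(f"mean gate on noise channels   = {report['mean_weight_noise']:.3f}")
```

prints

```
held-out RMSE = 0.088, R^2 = 0.902, AUC = 0.943
mean gate on planted channels = 0.742
mean gate on noise channels   = 0.531
```

The model explains ~90 % of the held-out label variance, and the trained AFR
gates sit visibly higher on the channels that actually generated the labels
than on pure-noise channels — the re-weighting module recovered the planted
relevance structure.  Because the rectifier precedes the sigmoid, gates
always lie in [0.5, 1): down-weighting is bounded at one half.

The same workflow is available from the shell:

```bash
solubgcn simulate --out data/ --n 300 --seed 0
solubgcn train --data data/ --out model/ --seed 0
solubgcn predict --model model/ --data data/ --out predictions.tsv
solubgcn cv --data data/ --folds 5 --cv-seeds 5 --out cv/
solubgcn ablate --data data/ --mode leave_one_out --out ablation/
```

Cross-validation reports are aggregated as mean ± standard deviation over
seed-level means (e.g. `0.495± 0.012`); ablation grids cover module ablation
(GCN / ESM+GCN / AFR+GCN / ESM+AFR+GCN), single-feature and
leave-one-feature-out runs, and ESM-plus-one-feature pairings.

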