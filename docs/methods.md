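# Methods

## Model

A protein of length `L` is a weighted graph `G(V, E)`: one node per residue,
edge weights from an `L×L` predicted contact-probability matrix.  Node
features are the column-wise stack of up to six per-residue blocks in a
fixed canonical order — ESM (20 channels), BLOSUM62 (20), AAPHY7 (7), PSSM
(20), HMM (30), SPIDER3 (14) — giving the hybrid feature `H ∈ R^{L×C}`,
`C = 111` with all blocks enabled.  The canonical order is enforced at
stacking time regardless of file discovery order so channel indices are
stable across runs, which the gate diagnostics and ablation audits rely on.

The regression `f: G(V,E) → s ∈ [0,1]` is composed of:

**Adaptive feature re-weighting.**  Per protein, channels are gated by
`W = σ(max(0, V·gap(H) + b))` and features re-weighted as `R = H ⊗ W`.
The "C convolution filters of support 1×C" acting on the 1×C pooled vector
are exactly a dense C→C linear map and are implemented as one; a bias is
learned by default (standard for gating blocks of this family) and can be
disabled.  Two consequences of the published form are implemented literally
and covered by tests rather than "fixed":

* the rectifier precedes the sigmoid, so every gate satisfies
  `W_c ∈ [0.5, 1)` — a channel can be attenuated at most to half its
  magnitude, never to zero;
* gates are a function of each protein's own pooled features, so each
  protein gets its own gate vector; the reported channel-importance
  diagnostic is the training-set mean gate.

Numerically, `σ` saturates to exactly 1.0 in float64 beyond arguments of
about 37; gates are clamped to the nearest representable value inside the
open interval so the strict bound `|R| < |H|` survives in floating point.

**Graph convolution.**  The raw contact diagonal is discarded, entries
below a configurable threshold (default 0.0, i.e. keep the full
probability-weighted adjacency — contact probabilities are already a soft
edge weighting) are zeroed, unit self-loops are added, and the adjacency is
normalized as `Â = D^{-1/2}(A+I)D^{-1/2}` (spectral radius ≤ 1, so deep
propagation cannot blow up; row-stochastic and unnormalized variants are
available).  Each layer computes `X ← ReLU(Â X Θ + b)` with optional
dropout; default 2 layers.

**Readout and head.**  A two-layer scorer `e_i = v·tanh(Θ_a x_i + b_a)`
followed by a per-protein softmax yields residue attention weights summing
to 1; the attention-weighted sum of node states passes through a linear
sigmoid head, so predictions are strictly inside (0, 1).  A multi-head
variant (averaging the heads' pooled vectors) exists but is off by default,
since one softmax distribution is the reference design.

**Training.**  The loss is the batch RMSE — identical to the primary
evaluation metric — optimized with Adam (lr 1e-3).  Mini-batches of
proteins are packed into one block-diagonal sparse adjacency plus
row-concatenated features, so the whole forward/backward pass is a handful
of (sparse) matrix products; pooling, segment softmax and readout are
`reduceat` operations over contiguous per-protein row ranges.  Gradients
are hand-derived and verified against central finite differences to 1e-4
relative error in the test suite.  Early stopping monitors validation RMSE
(patience 20, max 200 epochs) and restores the best parameters; the
validation set is either the held-out cross-validation fold or an internal
10 % split.

## Normalization

Feature blocks arrive on incommensurate scales (probabilities, log-odds,
physicochemical values), so channels are min–max normalized per channel
with statistics frozen on the training partition; held-out values may fall
outside [0, 1] and are deliberately not clipped.  Z-scoring and no
normalization are available.  Constant channels map to zero.

## Evaluation protocol

RMSE and R² score the regression; for comparison with binary predictors,
truth and prediction are binarized at 0.5 — strictly below the threshold is
insoluble, so exactly 0.5 counts as soluble — and scored with accuracy,
precision, recall, F1 (0 by convention when precision + recall = 0) and
AUC.  AUC uses the rank (Mann–Whitney) statistic of the *continuous*
predictions against the binarized truth, with mid-ranks for ties; a
single-class fold flags AUC undefined and the run continues.

Cross-validation: 5 folds × 5 seeds.  IDs are sorted before seeded
shuffling so the partition is invariant to input order.  The headline
spread is the standard deviation across seed-level means (fold-level sd is
logged alongside); cells render as `0.495± 0.012`.  The final "single"
model trains on all training data; the "ensemble" is the arithmetic mean of
the five fold models' predictions — a convex combination of sigmoids, so it
stays in (0, 1).

Ablation grids: module ablation (GCN on the five classic blocks, +ESM,
+AFR, both — 4 runs), single-feature (6, gating off since a single block
leaves nothing to re-weight against), leave-one-feature-out (6, gating on),
and ESM-plus-one pairings (5, gating on).  Each run's channel count is
audited against the sum of its enabled block dimensions.

## Synthetic data generator

The generator emulates the on-disk inputs end to end: FASTA sequences,
per-block `L×d` TSV matrices at the standard dimensions, `L×L` contact
maps, and a label table.  Per protein, a latent scalar `t ~ N(0,1)` is
drawn; all feature entries are standard normal, and the planted channels
(by default the first 4 channels of ESM and of HMM) receive the additional
shift `effect_size · t` in every residue.  The label is
`σ(2 · mean of planted channel means + ε)`, `ε ~ N(0, noise_sd²)` with
`noise_sd = 0.3`.  Reference conditions: 300 proteins, lengths uniform in
[30, 80], effect size 1.0.

Design rationale: the signal enters through per-protein channel *means*,
the exact statistic global average pooling extracts, so gate recovery is a
well-posed test of the re-weighting mechanism rather than of incidental
capacity.  Contact maps are within-band contacts (|i−j| ≤ 5) at probability
0.9 plus sparse long-range contacts (rate 0.02 per pair, values uniform in
[0.5, 1]); they exercise graph propagation but are label-independent, so
passing tests demonstrate feature-channel recovery, not edge learning.  At
`effect_size = 0` labels retain only an O(1/√(kL)) residual dependence on
the noise channel means — negligible against `noise_sd` — giving a usable
null dataset.

What the generator does **not** emulate: the real marginal distributions of
language-model probabilities, PSSM/HMM log-odds or predicted contacts;
correlations between blocks; length–solubility dependence.  Passing
recovery tests therefore show the architecture and gates work as designed,
not that the headline accuracy transfers to experimental solubility data —
that requires the externally extracted feature sets, which are out of scope
here.

## Experiment sizes and numerical choices

The relevance-recovery experiment (tests and `scripts/acceptance.py`) uses
the reference data conditions with a 64-unit GCN / 32-unit attention
network, batch 32, ≤ 100 epochs, 80/20 train/test split, three replicate
seeds, gated vs ungated; this width is ample for the planted-signal task
and keeps a full replicate under a minute on one CPU core.  Elsewhere the
estimator defaults to 256/128, sized for real feature sets.

Other numerical conventions: AFR kernels initialize uniform in
±1/√C (near-neutral initial gates ≈ 0.5), layer weights Glorot-uniform,
zero biases; dropout uses inverted scaling; the fold/replicate seeds derive
deterministically from the estimator seed (`random_state + 1000·seed`);
early-stopping improvement requires a 1e-6 RMSE margin; a contact threshold
of 1.0 is rejected outright (it would erase even certain contacts), and an
adjacency that is empty after thresholding proceeds with self-loops only,
with a warning.

## Known limitations

* No autodiff framework: the hand-written backward pass must be extended in
  lockstep with any architectural change (the finite-difference test guards
  this).
* AFR gates cannot fall below 0.5 by construction, so "irrelevant" channels
  are halved, not silenced; block-importance values should be read as
  relative, not absolute.
* Labels generated by the logistic link rarely reach the extremes of
  [0, 1]; heavily bimodal experimental distributions are not represented.
* Training is CPU-bound numpy; it is sized for datasets of hundreds to a
  few thousand proteins, not for large-scale screening.
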