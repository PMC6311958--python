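# Methods

## Model

`mcadet` models a binary expression matrix (samples × features, features
partitioned into an mRNA block and a miRNA block) with a deep belief
network whose bottom layer is a semi-restricted Boltzmann machine
(semi-RBM). The semi-RBM has the usual bipartite visible–hidden weights
W and biases, plus a directed weight matrix Π (n_mrna × n_mirna) from
miRNA visible units to mRNA visible units. The intended reading is
mechanistic: hidden units stand for shared upstream regulators
(transcription factors, pathways) that co-drive miRNAs and mRNAs, and
Π_ok stands for direct post-transcriptional regulation of mRNA o by
miRNA k, with a negative sign meaning repression.

The two phases are deliberately asymmetric. Hidden activation
conditions on all visibles and ignores Π, so the hidden layer competes
to explain *all* covariation. Reconstruction draws miRNA states from
the hidden layer alone and then mRNA states from the hidden layer plus
the freshly reconstructed miRNA states through Π, so pairwise
miRNA–mRNA dependence that the hidden units fail to reproduce generates
a persistent gap in the ⟨v_mrna v_mirna⟩ statistics — exactly the
gradient signal that feeds Π under contrastive divergence:

    ΔW_ij ∝ ⟨v_i h_j⟩_data − ⟨v_i h_j⟩_model
    ΔΠ_ok ∝ ⟨v_mrna_o v_mirna_k⟩_data − ⟨v_mrna_o v_mirna_k⟩_model

Visible row order is fixed throughout: mRNA block first, then miRNA
block; the model archive records this convention.

### Assumptions

- Visible units are binary dysregulation calls, not abundances; the
  model sees "changed vs. normal", in either direction, unless the sign
  sidecar from binarization is consulted downstream.
- Confounding acts through binary hidden regulators whose effect on
  visibles is monotone (captured by logistic loadings).
- Direct miRNA→mRNA effects are pairwise and additive on the logit
  scale.

## Training

Greedy layer-wise pre-training: the bottom semi-RBM is trained by CD-k
(default k = 1) on the data; each upper layer is a standard RBM trained
on the mean activations (probabilities, not samples) of the layer
below. Within a CD step, reconstructed miRNA states are *sampled
binary* before entering the mRNA reconstruction — binary units are the
data model — while the deterministic mean-field pass (probabilities all
the way) is reserved for reconstruction-error evaluation. The update is
gradient ascent with momentum on mini-batches.

The sparsity penalty λ Σ_j |p − mean_j|² acts on the batch-mean hidden
activations of the first hidden layer only; its gradient w.r.t. the
means, 2λ(mean − p), is chained into the hidden-bias update through the
exact derivative of the batch-mean activation w.r.t. the bias (the
batch mean of p(1−p)). A configuration switch extends the penalty to
the second hidden layer; Π is regularized only by (optional) weight
decay.

Fine-tuning unrolls the stack into an autoencoder with untied encoder/
decoder copies and descends the summed reconstruction cross-entropy by
full-batch gradient descent. The down-pass honours the bottom
asymmetry: miRNA outputs come from the first hidden layer alone, mRNA
outputs from the first hidden layer plus the miRNA *reconstruction*
through Π. The gradient is exact (verified against central finite
differences to 1e-5), including the extra path from the miRNA outputs
into the mRNA logits. Because the loss is a sum over samples, the
fine-tune learning rate is small; at 2e-3 on the benchmark scenario the
causal model's loss oscillates (the Π feedback path stiffens the
curvature), at 1e-3 it descends monotonically, which is why the
reference protocol uses 1e-3.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `hidden_sizes` | (1500, 1000, 500, 250) | layer widths; full-scale default documented for transcriptome-scale runs, desk-scale analyses use (64, 32) |
| `learning_rate` | 0.05 | CD step size ε |
| `cd_steps` | 1 | CD chain length k |
| `momentum` | 0.5 | heavy-ball coefficient |
| `batch_size` | 100 | samples per CD estimate |
| `weight_decay` | 0 | L2 shrinkage on W and Π per update |
| `sparsity_target` p | 0.2 (when enabled) | desired mean on-fraction of first-layer hidden units |
| `sparsity_lambda` λ | 0 | penalty weight |
| `init_scale` | 0.01 | s.d. of Gaussian weight initialisation (biases start at 0) |
| extraction `quantile` | 0.05 | fraction of mRNAs kept per miRNA, count ⌈q·n_mrna⌉, ties broken by larger \|weight\| then lexicographic mRNA id |

The reference benchmark protocol (`mcadet.benchmark`) is 150 epochs per
layer at the defaults above with weight decay 0.01, sparsity 0.2/λ 0.1,
batch 50, then 30 fine-tune epochs at 1e-3. Weight decay 0.01 matters:
without it Π accumulates a diffuse positive component from confounded
correlations early in training (before W has learned the regulators),
which dilutes downstream ranking and reconstruction.

## Preprocessing

Continuous tumor tables are binarized against a per-feature summary
(median by default) of normal samples plus a pseudocount (default 1.0):
a call is 1 when the ratio reaches the fold threshold (default 3,
inclusive) in either direction — "up", "down" or "both" is selectable,
and the direction of each call is kept in a sign sidecar. Duplicate
sample IDs keep the first occurrence after a deterministic sort. The
binarized miRNA and mRNA matrices are inner-joined on sample IDs.

## Synthetic data

The generator emulates the statistical structure the model assumes:
per sample, hidden regulators switch on independently with probability
q = 0.3; each visible turns on with probability σ(bias + loadings·h),
loadings sparse (1–2 regulators per visible, magnitude 3) and bias −2,
giving ~12% baseline on-rates and ~73% regulator-driven on-rates —
roughly the shape of dysregulation-call matrices; mRNAs additionally
receive the planted effects (default −4, i.e. repression) of whichever
miRNAs are on, on 15 planted (miRNA, mRNA) pairs out of 30 × 120.
Pairs sharing a regulator but carrying no planted edge are emitted as
the confounded set; by construction they co-vary marginally with zero
direct effect.

What it does **not** emulate: read-count noise and normalisation
artefacts, sequence or seed-match structure, continuous dose–response,
regulator–regulator correlation, and miRNA–miRNA interactions. Passing
the recovery benchmark therefore shows that the machinery separates
planted causal structure from planted confounding under the model's own
assumptions — not that it would do so at transcriptome scale on real
tumors.

## Numerical choices

- Sigmoids via `scipy.special.expit`; probabilities are clipped to
  [1e-12, 1−1e-12] only inside log-loss computations, never in sampling.
- Reconstruction error defaults to the summed squared difference
  (per-sample reduction in reports); cross-entropy is available.
- Model selection splits samples 80/20 by a seeded permutation and
  ranks candidates by held-out error; a "permute" candidate trains on a
  column-permuted copy of the training split and serves as the negative
  control.
- The exact-enumeration oracles (≤ 12 total units) assign the energy
  E(v,h) = −a·v − b·h − vᵀWh − v_mrnaᵀΠv_mirna. The asymmetric
  reconstruction chain is the Gibbs kernel of that joint only when
  Π = 0; for Π ≠ 0 the chain's own stationary law is computed exactly
  from its 2^n transition matrix and used as the reference for
  long-chain statistics. This is a testing construct: the training
  procedure itself never needs a normalised joint.
- Serialization is a deterministic single-file archive (JSON header +
  length-prefixed `.npy` payloads), so identical seeds and configs give
  byte-identical model files.

## Design choices where the design was open

- CD depth k = 1; persistent CD and continuous visibles are out of
  scope.
- Upper layers consume mean activations rather than samples (standard
  greedy practice; configurable at the code level).
- Π is updated during fine-tuning by default (it parameterizes the
  reconstruction path) and frozen automatically when causal edges are
  disabled.
- Interactions are extracted from the fine-tuned Π by default; a flag
  selects the pre-trained Π. On the benchmark scenario both rank the
  planted edges essentially perfectly when the fine-tune step size is
  in its stable regime.
- The sparsity penalty applies to the first hidden layer only, with a
  switch for the second.
- Zero-denominator evaluation metrics are reported as 0 with an
  explicit flag, never NaN, so reports stay comparable.

## Known limitations

- The mean-field reconstruction feeds the *reconstructed* miRNA
  probabilities through Π, so the causal pathway improves
  reconstruction only to the extent that the hidden code pins down the
  miRNA states; on the benchmark scenario the causal model's
  reconstruction error is statistically indistinguishable from the
  baseline DBN's (within ~1.5%) even though only the causal model
  recovers the planted edges (AUROC ≈ 1.0). Reconstruction error is a
  model-selection signal here, not the headline claim.
- Mechanism classification labels a pair "confounded" when both RNAs
  carry a top-5% |W| loading on one common hidden unit. With a 64-unit
  first layer each regulator is represented in a distributed fashion,
  so this label is conservative: planted causal edges classify as
  causal essentially always, confounded pairs are reliably *not*
  causal, but only a minority earn the explicit "confounded" label at
  the default 95th-percentile threshold. Lowering the threshold (e.g.
  to the 90th percentile) trades precision for coverage.
- Problem sizes in the tests and benchmarks (300 samples, 150 features,
  (64, 32) hidden units, 5 seeds) are desk-scale choices; the
  full-scale architecture is documented but not exercised by the suite.
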