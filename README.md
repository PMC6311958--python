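# mcadet

Causal deep belief network for inferring miRNA → mRNA regulation from
paired expression profiles.

## The problem

Micro-RNAs repress messenger RNAs post-transcriptionally, and finding the
targets of each miRNA from tumor expression data is confounded by shared
upstream regulation: a transcription factor or pathway that drives both a
miRNA and an mRNA produces strong co-expression with no regulatory edge
between them. Sequence-based target predictors over-call (most predicted
duplexes are not functional), and correlation screens cannot tell a
causal pair from a confounded one.

`mcadet` addresses this with a hybrid model. A deep belief network over
binary dysregulation calls (tumor vs. normal fold change) learns hidden
units that play the role of the shared regulators, while the bottom layer
— a **semi-restricted Boltzmann machine** — additionally carries directed
weights π<sub>ok</sub> from each miRNA visible unit *k* to each mRNA
visible unit *o*. Correlation explained by co-regulation is absorbed by
the hidden units; correlation that survives conditioning on them is
absorbed by π, whose sign encodes activation (+) or repression (−).

The bottom-layer conditionals are

- positive phase: P(h<sub>j</sub>=1 | v) = σ(b<sub>j</sub> + Σ<sub>i</sub> W<sub>ij</sub> v<sub>i</sub>), with both blocks of
  visibles driving the hidden units and π playing no role;
- negative phase (asymmetric): P(v<sup>miRNA</sup><sub>k</sub>=1 | h) = σ(a<sub>k</sub> + Σ<sub>j</sub> W<sub>kj</sub> h<sub>j</sub>)
  from the hidden layer alone, then
  P(v<sup>mRNA</sup><sub>o</sub>=1 | h, v<sup>miRNA</sup>) = σ(a<sub>o</sub> + Σ<sub>j</sub> W<sub>oj</sub> h<sub>j</sub> + Σ<sub>k</sub> π<sub>ok</sub> v<sup>miRNA</sup><sub>k</sub>).

Training is contrastive divergence,
Δw<sub>ij</sub> = ε(⟨v<sub>i</sub>h<sub>j</sub>⟩<sub>data</sub> − ⟨v<sub>i</sub>h<sub>j</sub>⟩<sub>model</sub>) and
Δπ<sub>ok</sub> = ε(⟨v<sub>o</sub>v<sub>k</sub>⟩<sub>data</sub> − ⟨v<sub>o</sub>v<sub>k</sub>⟩<sub>model</sub>),
optionally with a sparsity penalty λ Σ<sub>j</sub> |p − mean<sub>j</sub>|² that keeps only a
fraction *p* of first-layer hidden units active on average. Upper layers
are standard RBMs trained greedily; the stack can then be unrolled into
an autoencoder and fine-tuned. Predicted interactions are the top 5% of
|π| per miRNA, scored against a gold-standard pair list by recall, PPV
(precision) and F1, with a pooled two-proportion z-test comparing PPVs
between methods.

## Worked example

Everything below runs in well under a minute on one CPU; no downloads
are needed because the package ships a generator that plants known
causal edges on top of known hidden-regulator confounding.

```python
import numpy as np
import mcadet as mc

data, truth = mc.simulate(mc.SimConfig(seed=7))
arch = mc.Architecture(hidden_sizes=(64, 32), sparsity_target=0.2)
cfg = mc.TrainConfig(epochs=150, batch_size=50, weight_decay=1e-2,
                     sparsity_lambda=0.1, seed=7)
res = mc.MCadet(data, arch).fit(cfg, finetune_epochs=30, finetune_lr=1e-3)
print(res.summary())
```

```
Causal deep net (mCADET) results
========================================
samples:            300
features:           120 mRNA + 30 miRNA
hidden layers:      [64, 32]
causal edges:       enabled
sparsity target:    0.2
epochs per layer:   150
fine-tune epochs:   30
bottom recon err:   33.1651 -> 18.4584 (per sample, squared)
|pi| mean / max:    0.2939 / 2.1176
```

```python
pred = mc.extract_interactions(res).kept_pairs()      # top 5% |pi| per miRNA
gold = {(m, t) for m, t, _ in truth.causal_edges}
print(mc.score_predictions(pred, gold).to_text())
print("AUROC of |pi| vs planted edges:",
      round(mc.pair_auroc(np.abs(res.pi), truth.pi_true != 0), 3))
```

```
Prediction benchmark
  TP = 15   FP = 165   FN = 0
  recall (sensitivity)       = 1.0000
  PPV (precision)            = 0.0833
  F1                         = 0.1538
AUROC of |pi| vs planted edges: 0.999
```

All 15 planted edges are recovered (recall 1.0); the top-5% rule keeps
⌈0.05·120⌉ = 6 mRNAs for each of the 30 miRNAs, hence 180 predictions and
a PPV ceiling of 15/180 ≈ 0.083, which the fit reaches. Ranking all
3 600 pairs by learned |π| separates planted from unplanted pairs almost
perfectly (AUROC 0.999), while a pairwise-regression correlation screen
truncated to the same 180 pairs reaches only about a third of that PPV —
the confounded pairs it cannot tell apart from causal ones.

The same pipeline is available from the shell:

```sh
mcadet simulate --seed 7 --out-dir sim/
mcadet train --matrix sim/matrix.tsv --types sim/feature_types.tsv \
       --hidden-sizes 64,32 --sparsity-target 0.2 --epochs 150 \
       --weight-decay 0.01 --seed 7 --out model.bin
mcadet predict --model model.bin --out interactions.tsv
mcadet evaluate --pred interactions.tsv --gold sim/truth_edges.tsv
```

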