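# fsdta — few-shot drug–target affinity prediction by meta-learning

`fsdta` is a Python library for predicting drug–target binding affinity
(DTA) for proteins with very little labeled data. It treats each target
protein as one *task* — the protein together with all of its measured
compound affinities on the p-scale (pKd/pKi/pIC50, −log10 molar) — and
meta-learns across tasks so that a handful of labeled pairs (5–40) suffices
to adapt to a previously unseen target. The intended users are
computational chemists and method developers working on cold-target
affinity prediction and early-stage virtual screening.

## The model

**Base learner.** `f_θ(t, d)` scores a (protein, drug) pair: the drug is a
heavy-atom molecular graph (atom symbol, heavy-neighbor count, H count,
implicit valence, aromaticity as node features) encoded by a two-layer
graph neural network (GCN, GAT, GIN, or a hybrid GAT→GCN with max+mean
pooling); the protein is an integer-encoded sequence passed through a
three-layer 1-D CNN; the pooled embeddings feed a dense head that outputs
one affinity. All operations take the flat parameter vector θ explicitly,
and gradients come from reverse-mode automatic differentiation.

**Bi-level meta-learning.** Each task `T_i` is split into a support set
`S_i` and query set `Q_i`. The inner loop adapts the shared initialization
θ₀ with n = 5 full-batch gradient steps on `S_i`,

    θ_i = θ₀ − α ∇_θ Loss(S_i; θ₀)   (iterated n times),

and the outer loop updates θ₀ with one Adam step against the mean
post-adaptation query loss, differentiated through the inner steps
(second-order; a first-order approximation is available for speed):

    θ₀ ← θ₀ − β ∇_θ₀ E_i [ Loss(Q_i; θ_i) ].

**Adaptive task sampling.** Not all tasks deserve equal attention: noisy or
unrepresentative tasks can dominate meta-training. Before every
meta-update, B candidate tasks are summarized by two statistics — the query
loss after adaptation and the cosine similarity of the support and query
loss gradients at θ₀ — and a small learned adapter `g_φ` (two bidirectional
LSTM feature extractors, one per statistic channel, plus a linear softmax
head) turns them into sampling weights `ω_i`. N_slct tasks are resampled
with those weights to form the meta-batch. φ itself is trained by
bi-level optimization with a one-step approximation: take the virtual
ω-weighted meta-step θ̃₀(φ) = θ₀ − β Σ_i ω_i(φ) g_i, measure the validation
loss at θ̃₀, and step φ down its exact hypergradient through the weights.

**Label-noise regularization.** During meta-training each selected task's
support and query labels are perturbed with i.i.d. uniform noise
`ε ~ U(−σ, σ)` (σ = 0.1 p-units by default), which discourages overfitting
to noisy affinity annotations.

**Evaluation.** Regression: MSE, concordance index (CI, with 0.5 tie
credit), R², Spearman, Pearson. Virtual screening: EF@k% (enrichment
factor), precision@n, and BEDROC(α = 80.5), the exponentially
early-weighted enrichment score.

Because public DTA benchmarks are large and external, the package ships a
synthetic task generator with the same statistical shape: a frozen random
"teacher" network defines a shared drug-response surface, each task
perturbs it with its own affine transform (so meta-knowledge transfers but
per-task adaptation is still required), labels get Gaussian observation
noise, and a configurable fraction of tasks have their labels permuted
within the task — signal-free decoys the adaptive sampler should learn to
avoid.

## Worked example

`examples/` contains one short script per capability. The central one,
`examples/03_meta_train_synthetic.py`, meta-trains on a 40-task synthetic
family (2 outer epochs of 20 meta-updates for the demo) and then adapts to
four held-out targets from 5 labeled pairs each:

```
$ python examples/03_meta_train_synthetic.py
32 train / 4 val / 4 test tasks; learner has 553 parameters
ran 40 meta-updates; validation loss per epoch: [1.795, 0.712]
task SYN033: query MSE  0.713 from meta-init vs 20.947 from scratch (meta wins)
task SYN001: query MSE  0.379 from meta-init vs 19.780 from scratch (meta wins)
task SYN013: query MSE  2.705 from meta-init vs 12.935 from scratch (meta wins)
task SYN008: query MSE  0.409 from meta-init vs  7.602 from scratch (meta wins)
```

The meta-initialization reaches query MSEs of 0.4–2.7 p-units² after five
gradient steps on five labeled pairs; a freshly initialized network given
the identical adaptation budget stays at 7–21, i.e. it has learned nothing
transferable. `examples/04_adaptive_task_weights.py` shows the sampler
demoting permuted-label tasks (mean weight 0.014 vs 0.156 for clean tasks
after five epochs), and `examples/05_virtual_screen.py` ranks a 210-
compound deck for a held-out target after adapting on 10 known actives
(EF@1% = 5.6, BEDROC = 0.50 for its seed; per-target screening metrics on
decks this small are intrinsically high-variance).

## Command-line interface

A thin CLI wraps the library for shell use:

```bash
fsdta train    -c config.yaml   # meta-train + evaluate, per seed
fsdta screen   -c config.yaml   # few-shot virtual screening
fsdta simulate -c config.yaml -o family/   # emit a synthetic family (CSV+FASTA)
fsdta evaluate -p predictions.tsv          # metrics for a predictions table
```

The YAML config covers the synthetic-family or table inputs, the split
strategy (`random` 8:1:1 or `novel`, which clusters proteins at 40%
global-alignment identity and keeps whole clusters inside one partition),
the learner and schedule, and the seed list (5 by default); unknown keys
are rejected. Every run writes a config snapshot, JSON-lines training
logs, split manifests, checkpoints and TSV summaries.

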