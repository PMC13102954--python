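# Methods

This note documents the models and procedures implemented in `fsdta`, the
assumptions behind them, the parameters that matter, and the numerical and
design choices made where the design was genuinely open.

## Problem formalism

Affinity prediction is cast as protein-anchored few-shot regression. A
task `T_i` is one target protein `t_i` with all of its measured compound
affinities `{(t_i, d_s, y_s)}`; labels live on the p-scale (−log10 molar
for Kd/Ki/IC50, or a dataset's native composite score passed through
unchanged). Each task is partitioned into a support set `S_i` (the few
labels available for adaptation; 5 in the few-shot setting, 40 in the
majority setting) and a query set `Q_i` (held-out pairs used for
evaluation). Tasks are split 8:1:1 into meta-train / meta-validation /
meta-test, either at random (largest-remainder apportionment, so the
counts are exact for any task number) or by sequence identity ("novel"
split): proteins are clustered greedily at a 40% global-alignment identity
threshold and whole clusters are allocated to partitions, so no protein in
one partition has ≥40% identity with any protein in another — the
cold-target evaluation regime.

Identity is computed as `identities / alignment length` from a
Needleman–Wunsch global alignment (match +1, mismatch −1, gap open −1,
extend −0.5, via Biopython). The denominator choice (alignment length, not
shorter-sequence length) is pinned because the two conventions disagree on
gapped pairs; clustering is greedy-incremental against cluster
representatives, longest sequences first. A hook accepts precomputed
clusters (including CD-HIT `.clstr` files) for parity runs.

## Base learner

`f_θ(t, d)` is deliberately simple. Drug path: heavy-atom graph, node
features = one-hot atom symbol over {C, N, O, S, F, Cl, Br, I, P, B, Si,
other} + one-hot heavy-neighbor count (0–10, clipped) + one-hot attached-H
count + one-hot implicit valence + aromaticity bit (46 features total);
two graph layers (GCN / GAT / GIN / hybrid GAT→GCN); mean pooling (max+mean
concatenated for the hybrid). Protein path: tokens 1–26 for A–Z with 0 as
padding, right-truncation at `max_len` (default 1000; synthetic runs use
the family's maximum length); learned embedding; three 1-D convolutions
(valid padding, ReLU); global max pool. Head: one hidden dense layer to a
scalar. Bond/edge features and 3-D structure are deliberately out of
scope.

Every forward/loss/gradient operation takes the flat parameter vector
explicitly — the bi-level algebra needs losses at both θ₀ and θ_i, and the
named↔flat mapping is a fixed-order lossless layout. Gradients are exact
reverse-mode derivatives (autograd), verified against central finite
differences for all four architectures in the test suite. Default widths
(graph 64→128, conv channels 32, head 128) follow the lineage this
architecture descends from; the `tiny` preset (graph 4→4, channels 4, head
8, 553 parameters for GCN) is used throughout the tests so that full
meta-training runs finish in minutes on one CPU. The same code path runs
at both scales.

## Meta-learning loop

Inner loop: `n = 5` full-batch gradient-descent steps on the support set
at rate α (default 0.01). "Full-batch" is the natural reading for 5–40
support pairs. Outer loop: one Adam step (rate β, default 0.001; 0.01 in
the desk protocol) on the *mean* post-adaptation query loss of the
selected batch — the mean keeps β's scale batch-size-invariant; a summed
objective is a switch. Second-order differentiation through the inner loop
is the default and is what the analytic tests verify; `mode="first_order"`
(query gradient at θ_i, treating θ_i as detached) is used inside the
longer training loops for speed. The two modes coincide exactly when
`n_steps = 0`, which is a regression test. Test-time adaptation reuses the
training α and n.

Meta-training draws B candidate tasks per update (B = 16 by default, 8 in
the desk protocol) and resamples each candidate's support/query partition
fresh (episodic convention). Validation model selection keeps the θ₀ with
the lowest mean validation query loss, evaluated after every epoch.

## Adaptive task sampling

Per candidate: `TaskStats = (query loss at θ_i, cosine(∇Loss(S_i; θ₀),
∇Loss(Q_i; θ₀)))`. Cosine rather than a raw inner product makes the
statistic scale-free across training stages; the raw product is a config
switch (`similarity="dot"`). A zero-norm gradient yields similarity 0 and
the task stays in the pool.

The adapter `g_φ` uses two bidirectional LSTM feature extractors, one per
statistic channel, each scoring tasks independently; the per-task
forward/backward hidden states of both channels are concatenated and
scored by a linear head, softmax-normalized over the batch. Scoring tasks
independently (rather than running the recurrence across the candidate
sequence) makes the module exchangeable: a batch of identical statistics
gets exactly uniform weights for any ordering, which is the invariant the
tests pin down. Inputs are z-scored within the candidate batch before the
LSTM cells — early-training query losses of 20–50 would otherwise saturate
the gates and kill the φ-gradient; a constant channel maps to zeros, which
preserves the uniformity invariant.

φ is trained against validation performance with a one-step
approximation. With per-candidate meta-gradients `g_i` (constants in φ),
the virtual meta-parameters are

    θ̃₀(φ) = θ₀ − β Σ_i ω_i(φ) g_i ,

the validation loss `L_val(θ̃₀)` is evaluated with inner adaptation per
validation task, and because θ̃₀ is linear in ω the hypergradient is the
exact chain rule `∂L_val/∂ω_i = −β g_iᵀ ∇L_val(θ̃₀)` back through the
softmax — verified against central finite differences of the very same
objective. Sampling itself is not differentiable; importance-weighting the
per-task losses is the standard relaxation, and the hard resampling (N_slct
tasks, sequential weighted draws without replacement) uses the refreshed
weights. The adapter step is plain gradient descent at rate 1.0 in the
desk protocol — the coefficients scale with β and are therefore tiny — with
the hypergradient norm clipped at 10: early loss spikes can otherwise blow
φ up until the softmax saturates into a degenerate one-hot. If the
remaining probability mass underflows during sequential sampling, the
leftover draws fall back to uniform over the unchosen candidates.

## Label noise

Each selected task's support and query labels are shifted by i.i.d.
`ε ~ U(−σ, σ)` with copy semantics (featurized inputs and originals
untouched). σ is in p-scale units; the default 0.1 is a few percent of the
typical 5–11 label range. σ = 0 is the exact identity.

## Synthetic task families

The generator produces data with precisely the structure the method
assumes, so every stage is testable without downloads:

- **Molecules** are random valence-respecting single-bond graphs over
  {C, N, O, S} (random spanning tree + ring-closing extras), built with
  RDKit so each has a real SMILES and the exact 46-feature layout of the
  featurizer. No realistic chemistry beyond valence consistency is
  attempted.
- **Proteins** are uniform random 20-letter sequences (length 30–60 by
  default); a configurable fraction are mutated copies of earlier ones so
  identity clustering has non-trivial structure.
- **Labels**: a frozen random instance of the base learner (the "teacher")
  maps each (molecule, protein) pair to a raw score. Scores are z-scored
  *within each task* and placed at `8 + 0.8·z` p-units: the teacher's
  protein main effect would otherwise dwarf the drug effect and leave
  within-task spreads far below the ~1 p-unit within-target spreads of
  real kinase panels. Between-task heterogeneity is injected explicitly:
  each task applies its own affine transform (scale ~ U(0.8, 1.2), offset
  ~ N(0, 1)) — shared structure a meta-initialization can capture plus
  task-specific variation that still requires adaptation. Gaussian
  observation noise (sd 0.3) is added and labels are clipped to [5, 11].
- **Noisy tasks**: a configurable fraction have labels permuted within the
  task — the multiset is preserved but all signal is destroyed; they are
  flagged in the generator metadata.
- **Screening decks**: the same construction without per-task affine
  terms; compounds above the family-level quantile of the pre-noise score
  (per-task standardized, so each target's active rate is close to the
  nominal fraction) are flagged active. Within a task every active sits
  above every inactive on the pre-noise score.

What passing tests on this generator do and do not show: the teacher is by
construction representable by the student architecture, molecules carry no
real pharmacology, and task heterogeneity is a clean affine family —
success here demonstrates that the meta-learning machinery, the sampler
and the evaluation stack behave as designed, not that the learned
representations transfer to laboratory affinity data.

## Study conditions and problem sizes

The shared desk protocol (`fsdta.presets.desk_protocol`) fixes the
small-scale conditions used by the tests, examples and the reproduction
script: 40 tasks of 12–24 records, molecules of 6–12 atoms, proteins of
30–60 residues, tiny learner widths, 5 outer epochs × 20 meta-updates,
B = 8 candidates with N_slct = 4, validation batch 2, first-order
meta-gradients, α = β = 0.01, adapter rate 1.0, σ = 0.1. The reproduction
script trains its regression readout for 15 epochs (held-out ranking keeps
improving well past the short schedule: CI 0.53 → 0.79 in a calibration
run against a teacher-oracle ceiling of 0.875) and uses 15 targets × 220
compounds with 10% actives for screening, pooling six held-out targets
across two independent families because single-target early-enrichment
metrics on ~200-compound decks hinge on 2–3 top ranks and are intrinsically
high-variance.

Two behaviors observed under these conditions are worth naming. First,
five 0.01-rate adaptation steps correct within-task ranking faster than
the per-task offset (sd 1 p-unit), so held-out CI/Spearman can be solid
while within-task R² is still negative; the paired meta-vs-scratch
comparison is the cleaner readout of what meta-training buys. Second, the
adapter consistently down-weights permuted-label tasks even when their
post-adaptation query losses are *lower* than clean tasks' (a
mean-predicting fit to a permuted task is cheap); the separation it learns
is driven by validation performance, not by either statistic alone.

## Numerical choices and degenerate inputs

- CI gives tied predictions 0.5 credit (constant predictor scores 0.5) and
  raises when all true labels are tied; R², Pearson and Spearman raise on
  constant inputs and are reported as absent in bundled reports.
- Ranking ties in screening metrics are broken by stable original index;
  the EF@k% cutoff takes ⌈k%·N⌉ compounds; EF@100% is identically 1.
- Spearman uses average ranks + Pearson-on-ranks (reduces to the rank-
  difference formula when untied); BEDROC follows the standard
  exponential-weighting formula and is cross-checked against an
  independent reference implementation at 1e−9.
- Softmax weights are computed with max-subtraction and renormalized to
  sum to 1 within 1e−9.
- Duplicate (drug, protein) table rows keep the first occurrence; rows
  that fail featurization are skipped and counted. Affinities are assumed
  nM unless the schema declares otherwise.
- Everything stochastic flows from explicit seeds through
  `numpy.random.Generator`; two runs with one seed are bit-identical
  (checked down to the JSON training logs).

## Known limitations

- The learner stack runs on CPU-bound dense linear algebra; it is sized
  for method research and desk-scale studies, not for training on
  million-pair public benchmarks.
- Inner-loop divergence is possible at aggressive inner rates (α ≳ 0.05
  with 5 steps at tiny widths); the loop does not adapt α.
- Active-only screening supports bias adapted predictions upward by
  construction; ranking quality on a new target therefore leans on the
  meta-initialization, and per-target screening outcomes vary substantially
  at small deck sizes.
- The novel split guarantees pairwise identity < 40% across partitions
  under the package's own alignment convention; other aligners or identity
  denominators may score borderline pairs differently.
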