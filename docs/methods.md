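# Methods

## Problem setting

A spatial transcriptomics slice is a pair (X, S): a spot-by-gene count
matrix X ∈ R^{N×G} and planar spot coordinates S ∈ R^{N×2}. Given a
*source* slice whose spots carry expert region labels (cortical layers,
tumor compartments, ...) and an adjacent or replicate *target* slice
without labels, the package predicts the target's region labels — with
the source's label names, not anonymous cluster ids — by (1) learning a
spatially informed embedding and a supervised region classifier on the
source and (2) adversarially aligning the target's embedding distribution
with the source's so the classifier transfers.

## Graphs

Two graphs per slice, both built from coordinates only:

- **KNN adjacency A** — each spot linked to its k nearest Euclidean
  neighbours (self excluded, ties to the lower index), OR-symmetrized.
  Default k = 6, matching the hexagonal neighbourhood of Visium arrays.
- **PPMI matrix P** — from truncated random walks on A. With Π the
  row-normalized adjacency, the default "expected" estimator uses the
  exact occupancy F = (1/T) Σ_{t=1..T} Π^t instead of simulating walks;
  it is deterministic and equals the walk expectation, and a seeded
  "sampled" estimator is available and converges to it. F is symmetrized,
  normalized to a joint distribution P(i,j), and
  p_ij = max(0, ln P(i,j)/(P(i)P(j))) with a zeroed diagonal. Default
  horizon T = 3, matching the three-layer convolutional receptive field.
  PPMI up-weights pairs that co-occur on walks more than chance, encoding
  structure beyond immediate neighbours.

Both graphs enter convolution as D̃^{-1/2}(G+I)D̃^{-1/2}. The PPMI graph
is used as a weighted graph directly (no binarization); its self-affinity
enters only through the +I, avoiding double self-weighting.

Limitations of the closed-form occupancy worth knowing: on bipartite-like
graphs the Cesàro average retains an alternating eigen-term that decays
like 1/T, so PPMI of a "factorizing" walk distribution vanishes only as
T → ∞ (≈ 5e-3 residual at T = 50 on a 4-clique), which the tests assert
at its true magnitude.

## Encoder

Expression (preprocessed, see below) is linearly embedded to d = 128
dimensions, then passed through two parallel three-layer GCN branches —
one per graph — each step being σ(Ĝ H W) with ReLU on the trunk
(widths 64, 32) and three parallel depth-3 heads (width 32): a ReLU
feature head f_G and linear heads μ_G and log σ²_G. A latent sample
z_G = μ_G + σ_G ⊙ ε (ε ∼ N(0, I)) is drawn per branch; prediction uses
ε = 0 (the posterior mean), making inference deterministic.

Branch pairs are fused per spot by scalar softmax attention:
score_G = wᵀu_G + b with one shared (w, b) per fuser,
α = softmax over the two scores (computed as a sigmoid of the score
difference, the numerically stable equivalent), and
f = α_f f_A + (1−α_f) f_P, likewise for z. The embedding is h = [f, z]
(width 64). Single-graph ablations bypass fusion entirely rather than
learning a degenerate α.

No KL or reconstruction penalty is applied: the classification and
adversarial losses are the only objectives, and the variational sampling
acts as stochastic regularization of the embedding. A `kl_weight` option
(default 0) adds the standard Gaussian KL for experimentation.

## Classifier and discriminator

The region classifier stacks two residual blocks
ResBlock(h) = h + ReLU(BN(W h)) (batch statistics in training, running
statistics at prediction) and a final linear-softmax layer over the C
source classes; it minimizes mean cross-entropy on the source slice. An
MLP variant (plain dense ReLU layers, no skip/BN) with the same contract
is the classifier ablation.

The domain discriminator is a small feed-forward net (64 → 64 → 32 → 1,
sigmoid) scoring source (1) vs target (0). Losses are the standard
adversarial pair: L_D = −E[log D(h_s)] − E[log(1 − D(h_t))] for the
discriminator and the non-saturating L_G = −E[log D(h_t)] for the target
encoder. All logs are clamped at 1e-12.

## Training procedure

**Phase 1 (source).** Encoder and classifier are jointly optimized
full-batch with Adam (lr 1e-3) for up to 200 epochs, stopping when the
loss has not improved by 1e-4 for 20 epochs. Full-batch is deliberate:
slices up to ~10^4 spots fit in memory and it removes mini-batching
nondeterminism.

**Phase 2 (adaptation).** The target encoder starts as a copy of the
trained source encoder; the source encoder and the classifier are frozen
(their parameters are byte-identical before and after this phase, which
the tests assert). Each iteration performs one discriminator update
(Adam, lr 3e-4) on embeddings of both slices, then two target-encoder
updates (Adam, lr 1e-4) against the frozen discriminator, with fresh ε
draws throughout. A 20% random subset of spots per slice is held out of
all adversarial updates; balanced discriminator accuracy on those
held-out embeddings (ε = 0) is the convergence monitor. The loop stops
when that accuracy stays in [0.45, 0.55] for 20 consecutive iterations
(after a 100-iteration warmup — at the start an untrained discriminator
sits at chance, which is not convergence), with a cap of 600 iterations
and a divergence guard if L_G exceeds 10× max(initial, ln 2).

The asymmetric schedule (discriminator 3× faster, generator two steps)
was chosen for stability of the adversarial game: with a discriminator no
faster than the generator, the target encoder can overshoot the decision
boundary (held-out accuracy collapsing toward 0 rather than 0.5) and
scramble class structure; with a much stronger discriminator the game
never reaches the fooled equilibrium. Under the shipped defaults the
held-out accuracy settles in [0.44, 0.55] across ten generator seeds of
the synthetic benchmark.

**Prediction.** ε = 0 forward pass of the slice through its encoder
(adapted encoder for the target), then the source classifier in running-
statistics mode; labels are the argmax class names, ties to the lowest
index. Same seed ⇒ bit-identical results on one machine.

## Preprocessing

Standard recipe, fully configurable: total-count normalization to 1e4
per spot (all-zero spots dropped with a warning), log1p, top-3000 genes
by dispersion (variance/mean of the normalized log data; panels with few
genes set `n_hvg=0`), per-gene z-score clipped at ±10. Two choices are
deliberate and non-standard relative to single-slice pipelines:

- HVG selection is computed on the source slice only and applied to the
  target, guaranteeing identical input spaces without letting the target
  influence gene choice.
- Scaling statistics are likewise fit on the source and applied to both
  slices. Scaling each slice with its own statistics would absorb most of
  any gene-wise multiplicative batch effect during preprocessing, leaving
  the adaptation module nothing to align and silently hiding real shifts;
  fitting on the source preserves the target's displacement in the
  classifier's input space, which is exactly what adaptation is for.

## Synthetic benchmark

The generator emulates the intended use case with closed-form-checkable
structure. Layout: a jittered √N×√N grid banded into C contiguous layers
by y-quantiles ("strips", cortical-layer-like; a Gaussian "blobs" mode
exists). Expression: log-normal counts — baseline per-gene log-means
~ N(0,1) shared by both slices, +δ on each domain's disjoint marker set
(defaults: 8 markers/domain, δ = 2), spot noise N(0, 0.6²) on the log
scale, exponentiate and round. A negative-binomial switch exists for
realism checks; the log-normal default keeps every tested moment in
closed form. Batch effect: a seeded random half of the genes in the
target slice is multiplied by shared per-gene factors exp(N(0, 1²)) — a
library/platform-style technical shift. Defaults are N = 400 spots per
slice, G = 60 genes, C = 4 domains.

Under these defaults the shift is consequential but recoverable: a
source-trained model without adaptation loses ≥ 0.05 accuracy moving to
the target, and adaptation recovers most of it.

What the generator does **not** model: spatially autocorrelated noise
beyond domain structure, within-domain expression gradients, zero
inflation and dropout, histology, doublets, or platform-specific count
distributions. Passing the benchmark therefore demonstrates the
machinery's correctness and the adaptation mechanism's effectiveness
against multiplicative gene-wise shifts — not performance on any real
tissue.

## Numerical and design notes

- The graph-convolution weight update runs on an in-repo reverse-mode
  autodiff core over numpy float64 arrays; every primitive's
  vector-Jacobian product is tested against central finite differences.
  Full-batch training plus fixed seeds makes every pipeline stage
  bit-reproducible.
- Softmax rows are computed with a constant max-shift; attention softmax
  over two scores uses the sigmoid-of-difference form.
- Batch-norm uses biased batch variance, momentum 0.1, eps 1e-5;
  prediction before any training step is an error (no running
  statistics exist).
- Degenerate inputs: isolated graph nodes raise with advice to increase
  k; duplicated coordinates are allowed (ties by index); disjoint gene
  panels and mismatched spot ids raise alignment errors listing
  offenders; all-zero co-occurrence is an error.
- Problem sizes in the test suite: unit tests run at tens of spots;
  the study-scale checks run the full pipeline at the generator defaults
  (400 + 400 spots), one run per ablation variant.

## Known limitations

- Pairwise transfer only; multi-slice chains are realized by repeated
  pairwise runs. The target's class set is assumed to be the source's
  (no novel-region discovery).
- The adversarial game aligns marginal embedding distributions; with
  strong shifts or mismatched domain proportions it can align the wrong
  regions onto each other. The no-harm and direction tests cover the
  benchmark's regime, not arbitrary shifts.
- Dense N×N graphs and full-batch gradients bound practical slice size
  to roughly 10^4 spots on a laptop-class machine.
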