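# Methods

This note documents the models and procedures `issbec` implements, the
defaults it ships, the numerical choices that matter, and what the
synthetic benchmarks do and do not demonstrate.

## Normalization and splitting

Features are min-max rescaled to [0, 1] per feature.  Parameters are fit
on the training split only and test values outside the training range are
clipped — the leakage-safe order.  Pipelines that want normalization of
the full matrix before splitting (the order some published workflows use)
can set `normalize_before_split=True`; because min-max is idempotent under
refitting on its own output, the two orders differ only through the test
rows' influence on the extrema.  Constant features map to 0 and are kept,
preserving column indexing for selection provenance.  Missing values are
rejected by default; per-feature median imputation is available in the
reader.  Splits are stratified 80:20 and deterministic given a seed.

## Deep fuzzy partitioning (IDFC)

**Model.**  An autoencoder input → 64 → ν (default ν = 10) with tanh
hidden layers and linear output maps samples to latent codes z.  Fuzzy
membership of code x to center y uses an inverse-power rule on

D_{x,y} = ‖z_x − β_y‖² − μ·‖β_y − β̄‖² / Σ_v ‖β_v − β̄‖²,

i.e. the squared distance discounted by the (normalized) separation of the
target center from the center mean, weighted by μ (default 0.1).  The
normalization of the separation term is a deliberate reading: it bounds
the discount by μ and keeps D positive for any reasonable geometry,
whereas an unnormalized between-cluster ratio diverges as a center
approaches the mean.  D is clamped at 1e−12 before the −1/(fuz−1) power;
a code exactly on a center gets the one-hot limit membership.

The self-training target squares the membership, divides by the cluster
mass Σ_x Υ_{x,y}, and renormalizes rows — the reading that satisfies the
row-stochastic constraint.  The affinity matrix applies a hybrid
Gaussian/exponential kernel (mixing weight α, width σ) raised to δ, zeroed
across pseudo-label boundaries, with unit diagonal.  The joint loss adds
the mean squared reconstruction error (plus L2 weight penalty γ), η₁ times
the KL divergence of the membership from the target, and η₂ times the
affinity-weighted sum of squared latent distances.

**Optimization.**  Plain (full- or mini-batch) gradient descent with fixed
learning rate 1e−3; 100 pretraining epochs on the reconstruction loss,
then 100 joint epochs.  Targets, pseudo-labels and affinities are
recomputed every epoch (configurable via `target_update_interval`) and
held fixed within a step; the gradients through the membership — including
the μ-term's dependence on the centers via their mean — are analytic and
verified against central finite differences at 1e−4 relative tolerance in
the test suite.  With frozen targets, full batch and a small step the
recorded loss trajectory is non-increasing to 1e−9, which the suite
asserts.

**Defaults.**  fuz = 2, μ = 0.1, η₁ = 0.1, δ = 1, kernel α = 0.5,
σ = median pairwise latent distance after pretraining, batch = min(256, n),
C = 3 clusters.  η₂ = 1e−4: the affinity term is a raw sum over all
ordered sample pairs, so its magnitude grows with the square of the batch
size; at batch sizes around 150 a weight of order 1e−2 dominates the
objective, collapses the latent spread and measurably degrades partition
purity below the initialization, while 1e−4 keeps the term a regularizer.
All of these are configurable and logged.

**Initialization and degeneracy.**  Centers are initialized by classical
fuzzy c-means on the pretrained codes, itself started from spread data
points (k-means++-style), because a uniform random membership start sits
exactly on FCM's degenerate fixed point (all centers at the grand mean).
FCM with fuzzifier 2 still converges to that fixed point whenever cluster
overlap is high — a known property, observed routinely on
high-dimensional, weakly clustered inputs — so whenever centers
effectively coincide (pairwise distance < 1e−4 of the latent scale) they
are replaced by seeded Lloyd k-means centers.  Partitions are argmax
memberships; any partition with fewer than two samples of any class is
merged into the partition with the nearest center, so the downstream
per-partition classifier fit is always well-posed.

## Feature selection (SVM-MRFE)

Per feature, the classical Fisher score is
s(f) = Σ_d n_d (μ_{d,f} − μ_f)² / Σ_d n_d σ²_{d,f}, with n_d the class
sizes.  The modified score studentizes the global mean against the grand
mean of the partition matrix, φ(f) = (μ_f − μ₀)/SE(f) with
SE(f) = sd(f)/√n, and scores
Ms(f) = Σ_d n_d (μ_{d,f} − φ(f))² / (n·SE(f)).  The denominator is
implemented literally as written in the source formulation even though its
units are unusual; a `classic-denominator` variant substitutes the
classical within-class denominator for sensitivity analysis.  Zero
denominators yield score 0.

Ranking blends max-normalized squared linear-SVM weights with
max-normalized Ms at weight α (default 0.5).  Backward elimination refits
the SVM on the surviving features each iteration and drops the
lowest-ranked 10% (ceil, floor 1, never crossing the target size, default
50 per partition); ties drop the higher original index first, which makes
the procedure fully deterministic.  More than two classes use one-vs-rest
squared weights summed per feature.  Fusion is the deduplicated sorted
union of the partitions' selections with per-feature provenance.

## Subspace-rotation ensemble

Each of n_blocks (default 3) blocks:

- draws M = max(2, round(γ·|fused|)) primary features uniformly without
  replacement (sorted), an independent secondary draw of the same size,
  per-column weights W ~ U(0.5, 1.5), and multiplies columns present in
  the secondary draw by (1 + λ) — the overlap bonus realizing the
  "weighted subspace + intersection" construction multiplicatively, since
  the additive set expression has no dimensional meaning.  γ defaults to
  0.5, λ to 0.3.
- partitions the M columns into random groups of size g drawn from
  {2, 3, 4} ("multi-scale"), fits a full PCA per group on a 75% row
  subsample (without replacement, the rotation-forest convention; a
  with-replacement flag exists), and assembles the block-diagonal loadings
  back in original column order.  Retaining all components makes the
  rotation exactly orthogonal (asserted to 1e−6 on every build);
  zero-variance groups get identity loadings.  A pure random orthogonal
  rotation (QR of a Gaussian draw) is available via
  `mse_rotation="random"`.
- blends H = α·S + (1−α)·S·R (α default 0.5) and fits its base learner:
  random forest (100 trees), RBF SVM (C = 1), or the improved KNN, cycling
  in that order.

Prediction is a plurality vote; ties break by the larger summed per-class
learner score, then the lower class index (binary tasks with three voters
cannot tie).  Per-class vote fractions serve as ROC scores.  With one
block, γ = 1, unit weights, λ = 0 and α = 1, the ensemble provably equals
its base learner — the do-no-harm baseline the suite asserts.

## Improved KNN

The distance is weighted Minkowski,
WM(a, b) = [Σ_i W_i |a_i − b_i|^ρ]^{1/ρ} with ρ = 2 by default.  Weights
derive from a leave-one-feature-out probe: acc_e is the 3-fold stratified
CV accuracy of conventional Euclidean KNN averaged over k ∈ {3, 5, 7};
acc₀(i) the same with feature i removed; ν_i = 1 − (acc₀(i) − acc_e)
clamped at 1e−6; W = ν/Σν.  The probe precomputes per-feature
squared-difference contributions so each of the t evaluations subtracts
one slice from a pooled distance matrix instead of refitting; equality
with the explicit per-feature recomputation is unit-tested.

Two decision rules ship because the source description is internally
inconsistent: the default takes the k (default 5) nearest neighbours under
the weighted distance and holds a plurality vote, which is the rule the
method's own motivation implies and the one that matches or beats
conventional KNN on data with a dominant informative feature; the
`average_distance` variant instead averages each class's distances among
the k neighbours and predicts the smallest average (with a `scope="all"`
sub-variant averaging over all training points).  Measured on the
one-dominant-feature benchmark the average rule loses to conventional KNN
in most seeds, which is why it is not the default.

## Evaluation protocol

Per seed: stratified 80:20 split; optional 5-fold CV on the training side
over a hyperparameter grid (default γ ∈ {0.2..0.8} × α ∈ {0.25, 0.5,
0.75}; a one-point grid skips CV and fits exactly once); refit on the full
training side; metrics on the untouched test side.  Metrics with zero
denominators report 0 and carry an "undefined" flag rather than raising,
since test sides can be as small as a handful of samples per class.
Multiclass metrics are one-vs-rest macro averages; accuracy stays plain.
ROC curves sweep the unique score values and AUC is trapezoidal, equal to
the pairwise concordance probability with ties at ½ (asserted).

The sensitivity sweep varies (γ, α) only, so the sweep fits the
normalization/partition/selection/fusion stages once per seed and refits
only the ensemble per cell — an exact factorization, not an approximation.
The ablation harness runs the full model against a single-Gaussian-kernel
partitioning variant (kernel α = 1) and a margin-only ranking variant
(rank α = 1) on identical splits.

## Synthetic data

`generate_classification` draws n × d Gaussian noise, plants a known set
of informative features whose class means differ by `effect_size` noise
SDs (random sign per feature), optionally adds equicorrelation among
informative features, class-independent latent cluster structure (centers
orthonormalized so every pairwise distance equals the nominal separation),
and an `equalize_variance` mode that shrinks informative features'
within-class noise so their marginal variance matches the noise features —
hiding the signal from variance filters, as co-expression-normalized real
data tends to.  `generate_clustered` embeds separated Gaussian blobs from
a low-dimensional latent space via a random linear map plus noise and
returns true cluster labels.

The default benchmark (n = 200, d = 500, 30 informative, effect 1.5,
balanced binary, 3 latent clusters) sits inside the dimensionality regime
of the published microarray benchmarks while remaining desk-scale: the
repeated-split evaluation, sweep and ablations complete in about a minute
on one CPU.  What passing these benchmarks shows: the stack recovers
planted signal, its invariants hold, and its accuracy is insensitive to
(γ, α) within five points.  What it does not show: performance under
platform noise, batch effects, probe-level artifacts, or class-correlated
cluster structure — none of which the generator emulates — nor any claim
about the published benchmark datasets themselves.

A caveat the ablation harness makes visible: on this benchmark the
partitioning ablation (hybrid vs Gaussian kernel) changes the pipeline
only through a weakly-weighted regularizer and a reshuffle of the
partition geometry, and all variants operate at the accuracy ceiling, so
their ordering over ten seeds can come down to a single test sample and is
effectively noise.

## Determinism and parallelism

A single master seed derives all module seeds (partitioner, selector,
per-block ensemble seeds) through seed sequences.  The per-partition
selection stage runs through a backend-agnostic `parallel_map` (serial or
process pool) whose results are guaranteed identical to sequential
execution in task order; failed tasks retry once.  The suite asserts
bit-identical predictions across repeated runs and across backends.

## Known limitations

- The autoencoder is a fixed two-hidden-layer architecture optimized by
  plain gradient descent; very large d would want minibatching and a
  better optimizer.
- The leave-one-feature-out probe is O(t) CV runs; it is intended for the
  post-fusion regime (t up to a few hundred), not raw feature spaces.
- No ARFF/MTX/HDF5 readers; delimited text (optionally gzipped) only.
- No distributed execution; the process-pool backend is the only shipped
  parallelism.
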