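# Methods

## Problem setting

The package targets a small-sample medical-imaging classification setting:
a binary target task (e.g. distinguishing gastric cancer from primary
gastric lymphoma on venous-phase CT) with too few labeled target images to
train a deep model well, plus several *source* cohorts — different
modalities or acquisition sites (pathology slides, arterial-phase CT) —
that are plentiful but distributionally shifted. The method learns deep
features on which each source–target pair is aligned, then classifies with
a lightweight, analytically solved network.

## Divergence model

For a source sample set X^s and target set X^t the marginal discrepancy is
the squared maximum mean discrepancy (MMD) with a Gaussian kernel
k(x,y) = exp(−‖x−y‖²/2σ²), estimated by the biased V-statistic

    M(X^s, X^t) = (1/n²)ΣΣ k(s,s) − (2/nm)ΣΣ k(s,t) + (1/m²)ΣΣ k(t,t).

The cross term carries factor 2: expanding the squared RKHS norm of the
mean-embedding difference forces it (a factor-1 variant sometimes seen in
print is not the norm of anything and can go negative).

Class-conditional discrepancies M^(l) are the same estimator restricted to
class-l samples on both sides. A class missing from either side is dropped
from the conditional sum and from the weight sum below, consistently, with
a warning.

The two kinds of discrepancy are combined with an adaptation factor
μ ∈ [0,1] computed from empirical Wasserstein-1 distances:

    μ = Σ_l W_l / (W_g + Σ_l W_l),
    combined = (1−μ)·M + μ·Σ_l M^(l).

W_g is the exact Wasserstein-1 distance between the pooled empirical
measures (Euclidean cost, linear-program solution; assignment problem when
the sides have equal size; refused above 512 samples per side — subsample
first). W_l is the class-l distance computed **after centering each domain
on its own pooled mean**. The centering is load-bearing: for balanced
two-class mixtures the raw class distances satisfy W_g ≤ (W_0+W_1)/2, so
the raw-distance factor would sit at μ ≥ 2/3 even under a pure global
translation — the opposite of the intended reading in which a dominant
*global* shift drives μ down (marginal adaptation prioritized). Centering
removes the translation shared by every class, so W_l responds only to
class-structure discrepancy: a translated domain gives μ near 0, a domain
with oppositely displaced class conditionals but matched pooled mean gives
μ near 1. Even so the factor's *null* (identical distributions, finite
samples) sits near 2/3 rather than 0.5, because the numerator sums two
noise-floor class distances against one global distance; the μ < 0.5
regime therefore indicates a genuinely dominant marginal shift, not any
marginal shift at all. When W_g and all W_l are exactly zero (identical
sets) μ is undefined and the reported fallback is 0.5 — any value yields
zero combined divergence.

Bandwidth σ defaults to the median pairwise Euclidean distance of the
pooled pair (the standard two-sample heuristic), resolved per pair per
batch; a fixed numeric σ is accepted. `n_kernels > 1` averages Gaussians
at σ·{2⁻²…2²} and is off by default.

## Transfer network

A common extractor (default: a tiny two-stage CNN — 3×3 conv, ReLU, 2×2
max-pool, twice — so the package builds with no downloads; other backbones
plug in through a registry) maps all domains to a shared feature space.
Each source–target pair has its own specific extractor, a 1×1 → 3×3 → 1×1
convolution stack with ReLUs, global-average pooled to a feature vector.
Each pair also has a linear softmax sub-predictor on its target stream;
the ensemble prediction is the arithmetic mean of the sub-predictor
outputs and the task loss is the cross-entropy of that mean against the
target labels (true target-train labels by default; a pseudo-label mode
uses the current ensemble argmax for unlabeled targets). The objective is

    l_total = α·l_MMD + l_task,      l_MMD = mean over pairs of combined.

μ and σ are recomputed from each mini-batch and treated as constants of
the step — no gradient flows through the Wasserstein weights or the
bandwidth. Mini-batches are class-balanced per domain (both classes must
be present for the conditional terms; a domain missing a class is a
sampler error naming the domain). Optimization is SGD with momentum 0.9
and weight decay 1e−4, learning rate 0.001 for the common extractor and
0.01 for the specific extractors and predictors, batch 32 per domain and
up to 2000 iterations at the full-scale operating point; tests and the
built-in experiments run scaled-down instances (batch 8, 15–200
iterations, 16–32 px images), sizes chosen so the full suite runs on one
CPU.

**α schedule.** Two modes over normalized progress p = iter/total:
`clamped_exp_decay` (default), max(0, 2·exp(−θp) − 1) with θ = 10 —
starts at 1 and decays, clamped where the raw formula turns negative
(a negative weight would reward divergence); and `progressive`,
2/(1+exp(−θp)) − 1, the standard ramp that keeps alignment active
throughout. The transfer-benefit experiments use the progressive mode:
the clamped formula is ≈0 after the first 7% of training, which would
make an "alignment on vs off" comparison vacuous.

**Feature standardization.** Each specific extractor's pooled output
passes through a non-affine batch standardization (running statistics at
evaluation time). Without it the MMD loss has a degenerate minimum —
collapse every sample to one point — and at this model scale training
reliably found it (alignment loss → 0, ensemble stuck at chance). Pinning
the batch variance at 1 removes the collapse direction while leaving
distribution shape free to align; it is the role batch norm plays inside
full-size backbones. Because the loss is scale-invariant under this
normalization, activation magnitudes drift over training and the
momentum-tracked running statistics would lag behind; training therefore
ends with a short statistics-only recalibration (20 forward passes over
freshly drawn joint batches with the final weights), after which
evaluation-mode normalization matches what the predictors were trained
against.

**Deep-feature export.** Features are global-average-pooled channel
activations: both common stages plus each specific extractor's final
stage, so the count is Σ common-stage channels + n_sources × specific
output channels (names encode the layer of origin); the feature inventory
follows this formula rather than any fixed constant.

## Feature selection

Greedy mRMR keeping ceil(fraction × p) features, fraction 0.10 by
default. Relevance and redundancy are mutual information estimated on
10-bin equal-frequency discretized columns; the default criterion is the
difference form (MID), with the quotient form (MIQ) behind a flag. First
pick is the max-relevance feature; ties break to the lowest index;
constant columns get MI 0. The selection depends only on values, not
column order, beyond that tie rule.

## Extreme learning machine

Hidden layer: ω, b drawn i.i.d. uniform [−1,1] from a seeded generator (a
standard ELM initialization), activation sigmoid by default, L = 1000 by
default (the built-in pipeline uses 200 at desk scale). Labels are one-hot; the class-1 score
column is the ROC score. Three solvers for the output weights φ:

* `pinv` — minimum-norm least squares, φ = G⁺Y;
* `ridge_closed_form` (default) — φ = (GᵀG + (1/β)I)⁻¹GᵀY, kept verbatim.
  Note the 1/β placement: β = 0.05 is a penalty of 20, and *larger* β
  means *weaker* regularization — the reverse of the usual +βI convention;
* `l1_coordinate_descent` — the lasso ½‖Gφ−y‖² + β‖φ‖₁ per output column
  (coordinate descent to 1e−6), giving sparse weights.

The L1 objective and the ridge closed form are different problems (no L1
problem has that closed form); both are exposed so either reading of the
regularized ELM can be reproduced, and the discrepancy is deliberate.

## Evaluation

Sen, Spe, Acc, Pre, F1 from the binary confusion matrix; zero-denominator
ratios report 0 with an `undefined_metrics` flag instead of raising. AUC
is trapezoidal over the full ROC (equivalently the tie-corrected
Mann–Whitney U, normalized), invariant to monotone score transforms. An
optional grouping key averages scores per group (per patient) before
evaluation, since image- vs patient-level evaluation is a study choice.
KDE comparison projects two feature sets on the first principal direction
of the pooled data (or a named feature), estimates Gaussian KDEs with
Silverman bandwidth on a shared grid, and summarizes with the L1 distance
between curves (0 identical, →2 disjoint).

## Synthetic data

Feature domains are two-component Gaussian mixtures (one per class,
default 10 dimensions, class means ±1.5 along the first axis, unit
covariance). Marginal shift adds one offset to every sample; conditional
shift adds per-class offsets that cancel in the pooled mean. The preset
magnitudes (marginal 8/6/5, conditional 4/3/2.5) were calibrated once
against the generator's null: the empirical Wasserstein noise floor at
50 samples per class in 10 dimensions is ≈2 per class weight, so marginal
offsets must clearly exceed the summed floor for the global shift to
dominate μ.

Image domains are 32×32 single-channel renderings: class 0 a filled
Gaussian blob, class 1 an annulus, on Gaussian noise backgrounds with
per-image center jitter. Marginal shift = brightness/contrast transforms;
conditional shift = per-class pattern displacement and scale. The
`transfer_benchmark` condition has clean, well-sampled sources (noise
σ = 0.25, 30 per class) and a scarce, noisy target (σ = 0.6, 3 training
images per class, 40 test per class) — the regime the method is for, where
class-conditional alignment to source clusters adds information the few
target labels cannot. The generator's job is to exercise the machinery
with controllable shifts, not to imitate CT or histology appearance: it
has no anatomy, no texture statistics, no label noise, and its shifts are
exactly parametric. Passing tests therefore demonstrate the estimators,
the optimization, and the directional transfer effects under known
conditions — not clinical performance.

## Numerical choices

* Probabilities are floored at 1e−12 inside cross-entropy.
* MMD values are clipped at 0 (the V-statistic can round to −1e−17).
* The median-bandwidth fallback for all-coincident points is σ = 1
  (MMD is 0 there regardless).
* All randomness flows from explicit integer seeds; the pipeline fans one
  global seed out to per-stage seeds by a fixed stride, so stages are
  individually reproducible and training histories are bit-reproducible.
* Checkpoints and run artifacts serialize at full precision; displayed
  tables round to 3 decimals.

## Known limitations

* The adaptation factor's balanced null is ≈2/3, not 0.5 (see above);
  comparisons of μ across pairs are meaningful, its absolute level less so.
* Exact optimal transport is O(n³); the 512-sample guard is a hard error,
  not an automatic subsampler.
* The tiny CNN backbone is a testbed, not a competitive image model; real
  applications should register a pretrained backbone.
* With identically distributed domains the mini-batch alignment loss
  starts at its sampling-noise floor, so "training reduces l_MMD" is only
  observable under genuine shift.
* mRMR recomputes pairwise MI lazily but is still O(k·p) MI evaluations
  per selected feature; at 10⁴+ features expect minutes, not seconds.
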