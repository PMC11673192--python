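# Methods

## Problem setting

For a patient with multi-omics profiles (here: gene expression `X(1)` and
microRNA expression `X(2)`) we observe a follow-up time `O` and an event
indicator `δ`: when `δ = 1` the death was observed and `O` is the survival
time `T`; when `δ = 0` the patient was right-censored at `O = C`. Event and
censoring times are assumed independent. The goal is a relative risk score —
higher score, shorter expected survival — learned from very few labelled
target samples (10–20 patients, the rare-cancer regime), with the shortfall
of data made up by cohorts of related cancers.

## Model

Each omics view `v` is encoded by a highway network: an initial linear
projection to the working width followed by `n_layers` gated layers

    x_out = H(x) * T(x) + G(x) * (1 - T(x)),

where `H` is a tanh-nonlinear transform, `G` an affine carry path
(initialised at the identity) and `T = sigmoid(W_T x + b_T)` the transform
gate. The gate bias starts negative (default −2), so a freshly initialised
encoder is close to the identity plus a small perturbation; this keeps deep
stacks trainable from random initialisation. The default encoder for the
desk-scale experiments is 2 layers at width 16; widths and depth are
configuration fields (a full-scale analysis would use 5 layers at width 80).

Two losses are combined on a batch of `n` patients:

**Similarity loss.** With per-view embeddings `z_i1, z_i2` and cosine
similarity `sim`, each anchor `i` contributes the hinge

    max(0, M - (sim(z_i1, z_i2) - sim(z_i1, z_j2))),

averaged over anchors. Same-patient view pairs must beat cross-patient
pairs by a margin `M` (default 0.2, a free parameter — moderate values
0.1–0.5 behave similarly; `M` only sets how far apart the hinge keeps
activating). The negative `j ≠ i` is chosen by a policy: `one_random`
(default; resampled each step from a seeded generator), `all_pairs` (mean
over all negatives; deterministic, used by the algebraic tests), or
`hardest` (most similar negative). The printed form is asymmetric (view 1
anchors); a symmetrised variant is available behind a flag. Inside the
training loss, embedding norms get a 1e-12 guard; the standalone
`cosine_similarity` operation instead rejects zero vectors.

**Cox loss.** The fused embedding `z_i = (z_i1 + z_i2)/2` feeds a risk head
`h_β` (default: a single linear layer; a one-hidden-layer variant is a
config option) and the negative mean log Cox partial likelihood

    l_cox = -(1/n) Σ_i δ_i [ h(z_i) - log Σ_{j ∈ R_i} exp(h(z_j)) ].

The risk set `R_i` is `{j : O_j ≥ O_i}` by default (Breslow-style; always
contains `i`, so every event term is defined, and tied event times share
the full tied group). A strict rule `{j : O_j > O_i}` is available; it
errors when the latest event has an empty risk set. This choice is the
single most consequential convention in the model and is surfaced in the
configuration. The log-sum-exp is stabilised by subtracting the risk-set
maximum (held constant, which leaves the gradient exact). All-censored
batches contribute zero loss and a warning.

The total loss is `l_cox + w_sim · l_sim` with `w_sim = 1` by default;
`w_sim = 0` is the similarity ablation. Gradients come from reverse-mode
autodiff (autograd) over a single flat parameter vector, which makes the
meta-learning arithmetic below plain vector algebra.

## Meta-learning

Training has two phases. In the meta-learning phase, each iteration samples
`m` tasks of `task_size` patients from the pool of related cohorts,
stratified at 25% uncensored / 75% censored (uncensored count rounded half
up). Each task is adapted independently from the same current
initialisation θ by `k` steps of full-batch gradient descent with rate α
(first-order Reptile inner loop). The meta update moves θ toward the mean
adapted parameters: either literally, `θ ← θ + γ · mean(θ_τ^k − θ)`, or —
the default, matching the experimental protocol — by feeding the negated
mean displacement to Adam with step size γ. Per-task displacements are
summed in sorted order per coordinate, so the update is exactly invariant
to task order. In the final learning phase the returned initialisation is
fine-tuned on the few target samples by full-batch gradient descent
(default 50 epochs at the inner rate α).

Defaults α = 1e-2, γ = 1e-3, k = 5, m = 3, task_size = 50 sit on the
standard search grids (α ∈ {1e-1…1e-3}, γ ∈ {5e-3…5e-5}, k ∈ {5,10,20},
m ∈ {3,5,10}, task_size ∈ {50…800}); the `grid-search` subcommand searches
at 20 shots and reuses the choice at 10 shots. The meta-iteration budget is
a free config field (60 in the reference desk-scale experiments — enough
for the inner losses to plateau at these problem sizes). There is no early
stopping.

A single global seed fans out to named generators (parameter init, task
sampling, similarity negatives, simulation), so every component's stream is
independently reproducible and checkpoints resume bit-identically.

## Comparison schemes

All schemes share the survival model and identical few-shot draws and test
splits within a replicate (paired comparison): `direct` (few-shot samples
only, random init), `pretrain` (Adam on pool batches for the same iteration
budget as meta-training, then fine-tune), `multitask` (shared parameters,
alternating one pool batch and one target batch per round, equal weights —
the mixing weight is exposed), `meta_single_gene` / `meta_single_mirna`
(one-view meta-learning; the unused view is never read),
`meta_wo_similarity` (two views, `w_sim = 0`), and `meta_multi_omics` (the
full method).

## Metrics

Harrell's C-index: pair `(i, j)` comparable iff `O_i < O_j` and `δ_i = 1`;
concordant when `h_i > h_j`; tied scores get half credit. The
time-dependent AUC is the Uno-style cumulative/dynamic estimator at a
horizon (default: median observed time): cases have an observed event by
the horizon, controls survive past it, and both are weighted by the inverse
of a Kaplan–Meier estimate of the censoring distribution (taken from
scikit-survival; left limits for cases). Both implementations are pinned
against brute-force pair enumeration and against scikit-survival's
estimators in the test suite. Scheme ranks are averaged over targets with
ties shared (lower is better). The paired one-sided Wilcoxon signed-rank
test compares schemes over replicate×draw pairs.

## Synthetic task families

Each patient has latent factors `u ~ N(0, I_r)` shared by both views:
`X(v) = u W_v' + ε`, `ε ~ N(0, noise_sd²)`. The linear predictor is
`η = w_task · u`; event times are Weibull with proportional-hazards rate
`λ0 · exp(η)` (shape 1 = exponential, the default); censoring times are
independent Weibulls whose rate is calibrated by log-scale bisection on a
simulated censored fraction with common random numbers — a closed form
exists for the exponential case, but the simulation-based calibration stays
correct when the Weibull shape is changed. A family shares loadings
`W1, W2` and a base risk vector `w` across tasks; each task jitters `w`
(sd 0.2 by default against `|w| = 1`), so tasks are related but not
identical. With `complementary_views` each view loads a disjoint half of
the latent coordinates: both views informative, neither sufficient — the
regime where multi-omics integration has something to contribute.

Defaults are desk-scale: r = 10, p1 = 500, p2 = 100, 400 patients per task,
9 tasks (8 pool + 1 target), censoring target 0.7 (mid-range for cancer
cohorts, which span roughly 0.14–0.86). The generator does **not** mimic
RNA-seq count distributions, batch effects, or pathway structure — passing
tests show the method recovers planted low-rank PH signal under Gaussian
noise and transfers across jittered tasks; they do not certify performance
on real sequencing data.

## Preprocessing

For TCGA-style matrices: drop features whose missing fraction strictly
exceeds 10% (exactly 10% is kept), impute remaining gaps with the feature
median, `log2(x + 1)` (base and pseudocount configurable), drop features
with sample variance below 1e-8 (the "almost unchanged" cutoff is not a
literature value; it is this package's default), and standardise to zero
mean and unit variance (population 1/n scaling by default; the sample
convention is available). Standardisation statistics can be fit on the
meta-training pool and reused for target data, so 10-sample cohorts never
contribute their own unstable estimates. Samples are aligned across views
and the survival table by sorted intersection of identifiers.

## Reference desk-scale experiment

`metasurv.benchmarks.few_shot_transfer_benchmark` pins the configuration
used for the end-to-end checks: the synthetic defaults above with
complementary views, the reduced model (2 highway layers, 16-dim
embeddings), 60 meta-iterations, and 10 draws × 3 repeats of 10-shot
fine-tuning with a 20% stratified test split — sized to finish in a few
minutes on one CPU while keeping the full paired protocol. The quantities
it reports (per-scheme mean C-index/AUC, Wilcoxon p, simulator calibration)
are computed fresh on every run.

## Known limitations

- No baseline-hazard estimation: scores are relative risks only, never
  absolute survival curves.
- Breslow-style tie handling only (no Efron correction).
- The strict printed risk-set rule is reproduced but not usable as a
  default, since it is undefined for the latest event.
- Two views are wired throughout the schemes layer; the data model is
  v-view generic but the similarity loss pairs exactly two.
- The multitask scheme's loss-mixing schedule (alternating equal-weight
  batches) is one reasonable choice among several; only the weight is
  exposed.
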