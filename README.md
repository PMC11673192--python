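# metasurv

Few-shot multi-omics survival prediction via first-order meta-learning of a
deep Cox model.

## The problem

Survival models for rare cancers face a double bind: omics profiles have
tens of thousands of features, but cohorts may hold only dozens of
patients, many of them right-censored. `metasurv` addresses this by
meta-learning a parameter initialization for a multi-omics deep Cox model
across tasks sampled from pools of *related* cancers, so that 10–20
labelled target patients suffice to fine-tune a usable risk model. It is
aimed at computational biologists and biostatisticians studying few-shot
transfer for survival analysis; everything — data generation, training,
evaluation — runs from synthetic task families with known ground truth, so
no external downloads are needed.

## The model

Each omics view (gene expression `X⁽¹⁾`, microRNA expression `X⁽²⁾`) is
encoded by a highway network — gated layers
`x_out = H(x)·T(x) + G(x)·(1−T(x))` — into a shared embedding space. A
margin hinge on cosine similarities pulls the two views of the same patient
together and pushes different patients apart:

    l_sim = mean_i max(0, M − (sim(z_i1, z_i2) − sim(z_i1, z_j2))),  j ≠ i

The fused embedding `z_i = (z_i1 + z_i2)/2` feeds a risk head `h_β` scored
by the negative mean log Cox partial likelihood over risk sets
`R_i = {j : O_j ≥ O_i}`:

    l_cox = −(1/n) Σ_i δ_i [ h_β(z_i) − log Σ_{j∈R_i} exp(h_β(z_j)) ]

Training minimises `l_cox + l_sim`. The initialization θ is learned by
first-order Reptile: per meta-iteration, m censoring-stratified tasks are
adapted independently with k full-batch gradient steps (rate α), and θ
moves toward the mean adapted parameters (rate γ, Adam by default). Risk
scores are relative log-hazards; the model predicts ranking, not absolute
survival curves. Comparison schemes (direct learning, pretraining,
multitask learning, single-omics meta-learning, a similarity-loss ablation)
share the same model and identical data draws. Metrics are Harrell's
C-index and IPCW cumulative/dynamic AUC. See `docs/methods.md` for
conventions, defaults, and limitations.

## Worked example

```python
import numpy as np
from metasurv import (SyntheticConfig, generate_family, pool_union,
                      ModelConfig, HighwayEncoderConfig, MultiOmicsSurvivalModel,
                      MetaConfig, meta_train, finetune, concordance_index)
from metasurv.evaluation import draw_few_shot, stratified_split, time_dependent_auc

# a family of 5 related synthetic cohorts; the last is the held-out target
syn = SyntheticConfig(n_tasks=5, n_per_task=300, p1=120, p2=40, seed=7)
pool_tasks, target = generate_family(syn)
pool = pool_union(pool_tasks)

model = MultiOmicsSurvivalModel(ModelConfig(encoders=[
    HighwayEncoderConfig(input_dim=120, n_layers=2, embed_dim=16),
    HighwayEncoderConfig(input_dim=40, n_layers=2, embed_dim=16)]))

# phase 1: meta-learn an initialization across pool tasks
theta0 = meta_train(model, pool, MetaConfig(meta_iterations=40, seed=7))

# phase 2: fine-tune on 10 target patients, score the held-out rest
rng = np.random.default_rng(7)
train, test = stratified_split(target.dataset, test_fraction=0.3, rng=rng)
few = draw_few_shot(train, shots=10, uncensored_fraction=0.25, rng=rng)
theta = finetune(model, theta0, few, epochs=50, lr=1e-2, rng=rng)

scores = model.risk_scores(theta, test.view_values())
eta_test = target.eta[np.isin(target.dataset.sample_ids, test.sample_ids)]
print(f"10-shot C-index: {concordance_index(scores, test.times, test.events):.3f}")
print(f"10-shot AUC:     {time_dependent_auc(scores, test.times, test.events):.3f}")
print(f"oracle C-index:  {concordance_index(eta_test, test.times, test.events):.3f}")
```

Output:

```
10-shot C-index: 0.658
10-shot AUC:     0.743
oracle C-index:  0.727
```

Ten labelled patients plus a meta-learned initialization rank the 90
held-out patients at C = 0.658 — most of the way from random (0.5) to the
oracle score computed from the generator's true linear predictor (0.727).
The AUC (here at the median observed time) reads the same discrimination at
a fixed horizon.

## Command line

`metasurv` exposes `simulate`, `preprocess`, `meta-train`, `finetune`,
`evaluate`, `benchmark` and `grid-search` subcommands driven by one YAML
config; every run directory receives the echoed config, an input hash and a
log, and re-running from the echoed config reproduces outputs
byte-identically:

```sh
metasurv simulate  --config config.yaml --out runs/sim
metasurv benchmark --config config.yaml --out runs/bench
```

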