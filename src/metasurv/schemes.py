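"""Interchangeable training schemes sharing one survival model.

Seven strategies for the few-shot target task:

* ``direct`` — train on the few target samples only, from a random init.
* ``pretrain`` — conventional transfer: train on pool batches, then fine-tune.
* ``multitask`` — jointly optimise pool-batch and target losses with shared
  parameters, alternating one full batch of each per round.
* ``meta_single_gene`` / ``meta_single_mirna`` — Reptile meta-learning on one
  omics view (no similarity loss is possible with a single view).
* ``meta_wo_similarity`` — two-view meta-learning with the similarity loss
  ablated (weight 0).
* ``meta_multi_omics`` — the full method: two-view meta-learned
  initialization with the cross-omics similarity loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._utils import named_rng
from .evaluation import EvaluationResult, concordance_index, time_dependent_auc
from .io_preprocess import MultiOmicsDataset
from .meta import AdamState, MetaConfig, MetaTrainer, finetune, sample_task
from .model import ModelConfig, MultiOmicsSurvivalModel

SCHEME_NAMES = (
    "direct",
    "pretrain",
    "multitask",
    "meta_single_gene",
    "meta_single_mirna",
    "meta_wo_similarity",
    "meta_multi_omics",
)

_SINGLE_VIEW = {"meta_single_gene": 0, "meta_single_mirna": 1}


@dataclass
class SchemeSpec:
    """A named entry of the closed scheme registry plus overrides."""

    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme '{self.name}'; choose from {SCHEME_NAMES}")


def scheme_model(spec: SchemeSpec, base: ModelConfig) -> MultiOmicsSurvivalModel:
    """The model variant a scheme trains: view subset and similarity weight."""
    if spec.name in _SINGLE_VIEW:
        v = _SINGLE_VIEW[spec.name]
        cfg = dataclasses.replace(base, encoders=[base.encoders[v]], sim_weight=0.0)
    elif spec.name == "meta_wo_similarity":
        cfg = dataclasses.replace(base, sim_weight=0.0)
    else:
        cfg = base
    return MultiOmicsSurvivalModel(cfg)


def _views_for(spec: SchemeSpec, dataset: MultiOmicsDataset) -> list[np.ndarray]:
    if spec.name in _SINGLE_VIEW:
        return [dataset.views[_SINGLE_VIEW[spec.name]].values]
    return dataset.view_values()


def train_on_pool(
    model: MultiOmicsSurvivalModel,
    theta: np.ndarray,
    pool: MultiOmicsDataset,
    meta_config: MetaConfig,
    iterations: int,
    rng: np.random.Generator,
    view_picker=None,
) -> np.ndarray:
    """Adam training on stratified pool batches (the pretraining baseline)."""
    adam = AdamState.zeros(len(theta))
    for _ in range(iterations):
        task = sample_task(pool, meta_config.task_size, meta_config.uncensored_fraction, rng)
        data = task.support
        views = data.view_values() if view_picker is None else view_picker(data)
        _, grad = model.loss_value_and_grad(theta, views, data.times, data.events, rng=rng)
        theta = adam.step(theta, grad, meta_config.gamma)
    return theta


def prepare_pool_artifacts(
    schemes: list[SchemeSpec],
    pool: MultiOmicsDataset,
    model_config: ModelConfig,
    meta_config: MetaConfig,
    seed: int,
) -> dict:
    """Train each scheme's pool-level artifact (shared across few-shot draws).

    Meta schemes get a Reptile-learned initialization, ``pretrain`` an
    Adam-trained one with the same iteration budget; ``direct`` and
    ``multitask`` have no pool-level artifact.
    """
    artifacts = {}
    for spec in schemes:
        if spec.name in ("direct", "multitask"):
            continue
        model = scheme_model(spec, model_config)
        cfg = dataclasses.replace(meta_config, seed=seed, **spec.hyperparams)
        if spec.name == "pretrain":
            rng = named_rng(seed, "pretrain")
            theta = model.init_parameters(rng)
            theta = train_on_pool(
                model, theta, pool, cfg, cfg.meta_iterations, rng,
                view_picker=lambda d, s=spec: _views_for(s, d))
        else:
            trainer = MetaTrainer(model, _pool_view_subset(spec, pool), cfg)
            theta = trainer.run()
        artifacts[spec.name] = (model, theta)
    return artifacts


def _pool_view_subset(spec: SchemeSpec, pool: MultiOmicsDataset) -> MultiOmicsDataset:
    """Single-omics schemes see only their own view of the pool."""
    if spec.name in _SINGLE_VIEW:
        return MultiOmicsDataset([pool.views[_SINGLE_VIEW[spec.name]]], pool.outcomes)
    return pool


def _train_multitask(
    model: MultiOmicsSurvivalModel,
    pool: MultiOmicsDataset,
    few: MultiOmicsDataset,
    meta_config: MetaConfig,
    rng: np.random.Generator,
    aux_weight: float = 1.0,
    rounds: int | None = None,
) -> np.ndarray:
    """Shared-parameter joint training: alternate one pool and one target batch."""
    theta = model.init_parameters(rng)
    adam = AdamState.zeros(len(theta))
    few_views, few_t, few_e = few.view_values(), few.times, few.events
    n_rounds = meta_config.meta_iterations if rounds is None else rounds
    for _ in range(n_rounds):
        task = sample_task(pool, meta_config.task_size, meta_config.uncensored_fraction, rng)
        d = task.support
        _, g_pool = model.loss_value_and_grad(theta, d.view_values(), d.times, d.events, rng=rng)
        theta = adam.step(theta, aux_weight * g_pool, meta_config.gamma)
        _, g_tgt = model.loss_value_and_grad(theta, few_views, few_t, few_e, rng=rng)
        theta = adam.step(theta, g_tgt, meta_config.gamma)
    return theta


def evaluate_scheme(
    spec: SchemeSpec,
    model: MultiOmicsSurvivalModel,
    theta: np.ndarray,
    test: MultiOmicsDataset,
    horizon: float | None = None,
    replicate: int = 0,
    draw: int = 0,
) -> EvaluationResult:
    scores = model.risk_scores(theta, _views_for(spec, test))
    c = concordance_index(scores, test.times, test.events)
    try:
        auc = time_dependent_auc(scores, test.times, test.events, horizon)
    except ValueError:
        auc = float("nan")  # no cases or controls at the horizon on a tiny split
    return EvaluationResult(spec.name, replicate, draw, c, auc, test.n_samples)


def run_scheme_on_draw(
    spec: SchemeSpec,
    artifacts: dict,
    pool: MultiOmicsDataset,
    target_train: MultiOmicsDataset,
    target_test: MultiOmicsDataset,
    model_config: ModelConfig,
    meta_config: MetaConfig,
    rng: np.random.Generator,
    horizon: float | None = None,
) -> EvaluationResult:
    """Fit one scheme on one few-shot draw and score it on the test split."""
    model, theta = fit_scheme(spec, artifacts, pool, target_train, model_config,
                              meta_config, rng)
    return evaluate_scheme(spec, model, theta, target_test, horizon)


def fit_scheme(
    spec: SchemeSpec,
    artifacts: dict,
    pool: MultiOmicsDataset,
    target_train: MultiOmicsDataset,
    model_config: ModelConfig,
    meta_config: MetaConfig,
    rng: np.random.Generator,
) -> tuple[MultiOmicsSurvivalModel, np.ndarray]:
    epochs = meta_config.finetune_epochs
    lr = meta_config.effective_finetune_lr
    if spec.name == "direct":
        model = scheme_model(spec, model_config)
        theta = finetune(model, model.init_parameters(rng), target_train, epochs, lr, rng)
    elif spec.name == "multitask":
        model = scheme_model(spec, model_config)
        theta = _train_multitask(model, pool, target_train, meta_config, rng,
                                 aux_weight=spec.hyperparams.get("aux_weight", 1.0))
    else:
        model, theta_init = artifacts[spec.name]
        few = target_train if spec.name not in _SINGLE_VIEW else MultiOmicsDataset(
            [target_train.views[_SINGLE_VIEW[spec.name]]], target_train.outcomes)
        theta = finetune(model, theta_init, few, epochs, lr, rng)
    return model, theta


def run_scheme(
    spec: SchemeSpec,
    pool: MultiOmicsDataset,
    target_train: MultiOmicsDataset,
    target_test: MultiOmicsDataset,
    model_config: ModelConfig,
    meta_config: MetaConfig,
) -> tuple[tuple[MultiOmicsSurvivalModel, np.ndarray], EvaluationResult]:
    """Self-contained single run: pool artifact (if any) + fit + evaluation."""
    artifacts = prepare_pool_artifacts([spec], pool, model_config, meta_config,
                                       seed=spec.seed)
    rng = named_rng(spec.seed, f"scheme/{spec.name}")
    model, theta = fit_scheme(spec, artifacts, pool, target_train, model_config,
                              meta_config, rng)
    result = evaluate_scheme(spec, model, theta, target_test)
    return (model, theta), result
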