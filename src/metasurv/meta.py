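"""First-order Reptile meta-training and few-shot fine-tuning.

Meta-training alternates two loops. The inner loop adapts the current
initialization theta to each of m sampled tasks independently with k steps
of full-batch gradient descent on the combined Cox + similarity loss. The
meta loop treats the mean parameter displacement (1/m) sum(theta_tau^k -
theta) as a gradient: either applied directly scaled by gamma ("plain"), or
fed with flipped sign to Adam ("adam"). After meta-training, the final
learning phase fine-tunes the returned initialization on the few labelled
target samples with plain full-batch gradient descent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._utils import named_rng, round_half_up
from .io_preprocess import MultiOmicsDataset
from .model import MultiOmicsSurvivalModel

# hyper-parameter search grids for the few-shot protocol
ALPHA_GRID = [1e-1, 5e-2, 1e-2, 5e-3, 1e-3]
GAMMA_GRID = [5e-3, 1e-3, 5e-4, 1e-4, 5e-5]
K_GRID = [5, 10, 20]
M_GRID = [3, 5, 10]
TASK_SIZE_GRID = [50, 100, 200, 400, 800]


@dataclass
class Task:
    """A support set sampled from the meta-training pool."""

    support: MultiOmicsDataset
    source_label: str = "pool"


@dataclass
class MetaConfig:
    """Knobs of the two training phases.

    alpha / k govern the inner loop (full-batch gradient descent), gamma / m
    the meta loop, ``task_size`` the per-task batch. ``uncensored_fraction``
    fixes the censoring stratification of sampled tasks. Fine-tuning reuses
    alpha unless ``finetune_lr`` is set.
    """

    alpha: float = 1e-2
    gamma: float = 1e-3
    k: int = 5
    m: int = 3
    task_size: int = 50
    meta_iterations: int = 100
    uncensored_fraction: float = 0.25
    meta_optimizer: str = "adam"  # 'adam' | 'plain'
    finetune_epochs: int = 50
    finetune_lr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.uncensored_fraction < 1:
            raise ValueError("uncensored_fraction must be in (0, 1)")
        if self.meta_optimizer not in ("adam", "plain"):
            raise ValueError(f"unknown meta_optimizer '{self.meta_optimizer}'")
        if min(self.alpha, self.gamma) <= 0 or min(self.k, self.m, self.task_size) <= 0:
            raise ValueError("rates, k, m and task_size must be positive")

    @property
    def effective_finetune_lr(self) -> float:
        return self.alpha if self.finetune_lr is None else self.finetune_lr


@dataclass
class AdamState:
    """Adaptive-moment optimizer state over the flat parameter vector."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def zeros(cls, size: int) -> "AdamState":
        return cls(np.zeros(size), np.zeros(size))

    def step(self, theta: np.ndarray, grad: np.ndarray, lr: float) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return theta - lr * mhat / (np.sqrt(vhat) + self.eps)


def sample_task(
    pool: MultiOmicsDataset,
    n_task: int,
    uncensored_fraction: float,
    rng: np.random.Generator,
    source_label: str = "pool",
) -> Task:
    """Draw a censoring-stratified task without replacement from the pool.

    The uncensored count is round-half-up(n_task * fraction); the remainder
    is censored.
    """
    events = pool.events
    n_unc = round_half_up(n_task * uncensored_fraction)
    n_cen = n_task - n_unc
    unc_idx = np.where(events == 1)[0]
    cen_idx = np.where(events == 0)[0]
    if len(unc_idx) < n_unc:
        raise ValueError(f"pool has {len(unc_idx)} uncensored samples, need {n_unc}")
    if len(cen_idx) < n_cen:
        raise ValueError(f"pool has {len(cen_idx)} censored samples, need {n_cen}")
    chosen = np.concatenate([
        rng.choice(unc_idx, size=n_unc, replace=False),
        rng.choice(cen_idx, size=n_cen, replace=False),
    ])
    return Task(pool.subset(np.sort(chosen)), source_label)


def gradient_descent(theta: np.ndarray, value_grad_fn, alpha: float, k: int) -> np.ndarray:
    """k steps of theta <- theta - alpha * grad; errors on non-finite values."""
    theta = theta.copy()
    for step in range(k):
        val, grad = value_grad_fn(theta, step)
        if not np.isfinite(val) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite loss or gradient at inner step {step}")
        theta = theta - alpha * grad
    return theta


def inner_adapt(
    model: MultiOmicsSurvivalModel,
    theta: np.ndarray,
    task: Task | MultiOmicsDataset,
    alpha: float,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Adapt theta to one task with k full-batch gradient-descent steps.

    The input theta is never modified. Random negatives for the similarity
    loss are resampled each step from ``rng``.
    """
    data = task.support if isinstance(task, Task) else task
    views, times, events = data.view_values(), data.times, data.events

    def value_grad(th, step):
        return model.loss_value_and_grad(th, views, times, events, rng=rng)

    return gradient_descent(theta, value_grad, alpha, k)


def reptile_meta_update(
    theta: np.ndarray,
    adapted: list[np.ndarray],
    gamma: float,
    optimizer: str = "plain",
    adam_state: AdamState | None = None,
) -> np.ndarray:
    """Move the initialization toward the mean adapted parameters.

    Plain mode: theta + gamma * mean(adapted - theta). Adam mode: the negated
    mean displacement is fed to Adam as a pseudo-gradient with step size gamma.
    The per-task displacements are summed in sorted order per coordinate, so
    the update is exactly invariant to the order tasks were adapted in.
    """
    if not adapted:
        raise ValueError("adapted parameter list is empty")
    for a in adapted:
        if a.shape != theta.shape:
            raise ValueError("adapted parameter shape mismatch")
    stack = np.stack([a - theta for a in adapted])
    displacement = np.sort(stack, axis=0).sum(axis=0) / len(adapted)
    if optimizer == "plain":
        return theta + gamma * displacement
    if optimizer == "adam":
        if adam_state is None:
            raise ValueError("adam mode needs an AdamState")
        return adam_state.step(theta, -displacement, gamma)
    raise ValueError(f"unknown optimizer '{optimizer}'")


class MetaTrainer:
    """Stateful Reptile loop with checkpointing and a progress log.

    Three named generators derive from the config seed: parameter init, task
    sampling, and similarity-loss negatives — so each component's stream is
    reproducible on its own and a saved state resumes bit-identically.
    """

    def __init__(self, model: MultiOmicsSurvivalModel, pool: MultiOmicsDataset,
                 config: MetaConfig):
        self.model = model
        self.pool = pool
        self.config = config
        self.rng_task = named_rng(config.seed, "task-sampling")
        self.rng_neg = named_rng(config.seed, "similarity-negatives")
        self.theta = model.init_parameters(named_rng(config.seed, "parameter-init"))
        self.adam = AdamState.zeros(model.n_parameters)
        self.iteration = 0
        self.progress: list[dict] = []  # iteration, mean loss before/after adaptation

    def run(self, n_iterations: int | None = None) -> np.ndarray:
        budget = self.config.meta_iterations if n_iterations is None else n_iterations
        cfg = self.config
        for _ in range(budget):
            tasks = [
                sample_task(self.pool, cfg.task_size, cfg.uncensored_fraction, self.rng_task)
                for _ in range(cfg.m)
            ]
            before, after, adapted = [], [], []
            for task in tasks:
                data = task.support
                before.append(self.model.loss(
                    self.theta, data.view_values(), data.times, data.events,
                    neg_idx=self.model.sample_negatives(data.n_samples, self.rng_neg)).total)
                th_k = inner_adapt(self.model, self.theta, task, cfg.alpha, cfg.k, self.rng_neg)
                after.append(self.model.loss(
                    th_k, data.view_values(), data.times, data.events,
                    neg_idx=self.model.sample_negatives(data.n_samples, self.rng_neg)).total)
                adapted.append(th_k)
            self.theta = reptile_meta_update(
                self.theta, adapted, cfg.gamma, cfg.meta_optimizer, self.adam)
            self.iteration += 1
            self.progress.append({
                "iteration": self.iteration,
                "loss_before_adapt": float(np.mean(before)),
                "loss_after_adapt": float(np.mean(after)),
            })
        return self.theta

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Single .npz archive holding parameters, optimizer and rng state."""
        manifest = {
            "iteration": self.iteration,
            "config": asdict(self.config),
            "n_parameters": self.model.n_parameters,
            "rng_task_state": self.rng_task.bit_generator.state,
            "rng_neg_state": self.rng_neg.bit_generator.state,
            "adam_t": self.adam.t,
        }
        np.savez(
            path,
            theta=self.theta,
            adam_m=self.adam.m,
            adam_v=self.adam.v,
            manifest=json.dumps(manifest),
        )

    def load(self, path) -> None:
        with np.load(path, allow_pickle=False) as archive:
            manifest = json.loads(str(archive["manifest"]))
            if manifest["n_parameters"] != self.model.n_parameters:
                raise ValueError("checkpoint parameter count does not match model")
            self.theta = archive["theta"]
            self.adam = AdamState(archive["adam_m"].copy(), archive["adam_v"].copy(),
                                  t=manifest["adam_t"])
        self.iteration = manifest["iteration"]
        self.rng_task.bit_generator.state = manifest["rng_task_state"]
        self.rng_neg.bit_generator.state = manifest["rng_neg_state"]

    def write_progress(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.progress).to_csv(path, sep="\t", index=False)


def meta_train(model: MultiOmicsSurvivalModel, pool: MultiOmicsDataset,
               config: MetaConfig) -> np.ndarray:
    """Run the full meta-training budget and return the learned initialization."""
    trainer = MetaTrainer(model, pool, config)
    return trainer.run()


def finetune(
    model: MultiOmicsSurvivalModel,
    theta_init: np.ndarray,
    few_shot: MultiOmicsDataset,
    epochs: int,
    lr: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Final learning phase: full-batch gradient descent from theta_init."""
    if few_shot.n_samples < 2:
        raise ValueError("fine-tuning needs at least 2 samples")
    if not (few_shot.events == 1).any():
        raise ValueError("fine-tuning set has zero events: Cox loss has no signal")
    rng = np.random.default_rng(0) if rng is None else rng
    return inner_adapt(model, theta_init, few_shot, lr, epochs, rng)
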