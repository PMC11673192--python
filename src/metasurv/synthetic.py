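"""Synthetic families of related multi-omics survival tasks with known truth.

The generative model matches the structure the survival model assumes:
each patient has latent factors u ~ N(0, I_r) shared by both omics views,

    X(1) = u W1' + noise,   X(2) = u W2' + noise,

and a proportional-hazards event time T ~ Exponential(lambda0 * exp(eta))
with linear predictor eta = w_task . u. Censoring times C are independent
exponentials whose rate is calibrated by bisection so the expected censored
fraction hits a target. A family of tasks ("cancer types") shares the
loadings W1, W2 and a base risk vector w; each task jitters w, so tasks are
related but not identical — the regime meta-learning needs.

Real RNA-seq count distributions, batch effects and pathway structure are
deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import named_rng
from .io_preprocess import MultiOmicsDataset, OmicsMatrix, SurvivalOutcome


@dataclass
class SyntheticConfig:
    """Family-level generative settings.

    Defaults are sized for desk-scale experiments: far fewer features than a
    real gene-expression / miRNA pair, but the same two-view structure.
    ``target_censoring`` defaults to 0.7, a mid-range cohort censoring level
    for cancer registries. ``complementary_views`` restricts each view's
    loadings to a disjoint half of the latent coordinates, so neither view
    alone sees the whole risk signal.
    """

    latent_dim: int = 10
    p1: int = 500
    p2: int = 100
    n_per_task: int = 400
    n_tasks: int = 9  # pool tasks + 1 target
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    risk_scale: float = 1.0  # sd of eta across patients
    task_perturbation_sd: float = 0.2
    baseline_rate: float = 1e-3  # events per day at eta = 0
    target_censoring: float = 0.7
    weibull_shape: float = 1.0  # 1 = exponential event/censoring times
    complementary_views: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.p1, self.p2, self.n_per_task) < 1:
            raise ValueError("dims must be positive")
        if not 0 < self.target_censoring < 1:
            raise ValueError("target_censoring must be in (0, 1)")
        if self.weibull_shape <= 0 or self.baseline_rate <= 0:
            raise ValueError("weibull_shape and baseline_rate must be positive")


@dataclass
class SyntheticTask:
    """A generated cohort plus its ground truth (latents, linear predictor, T, C)."""

    dataset: MultiOmicsDataset
    latents: np.ndarray  # (n, r)
    eta: np.ndarray  # true linear predictor
    true_times: np.ndarray  # T
    censor_times: np.ndarray  # C
    risk_coef: np.ndarray  # the task's jittered w
    source_label: str = ""


def _family_structure(config: SyntheticConfig):
    """Loadings W1, W2 and base risk vector w, drawn once per family."""
    rng = named_rng(config.seed, "family-structure")
    r = config.latent_dim
    W1 = rng.normal(0.0, config.loading_scale, (config.p1, r))
    W2 = rng.normal(0.0, config.loading_scale, (config.p2, r))
    if config.complementary_views:
        half = r // 2
        W1[:, half:] = 0.0
        W2[:, :half] = 0.0
    w = rng.normal(0.0, 1.0, r)
    w *= config.risk_scale / np.linalg.norm(w)  # eta = w.u ~ N(0, risk_scale^2)
    return W1, W2, w


def _draw_times(rate: np.ndarray, shape: float, rng: np.random.Generator) -> np.ndarray:
    """Weibull(shape) times with PH rate parametrisation; shape=1 is exponential."""
    u = rng.random(rate.shape)
    return (-np.log(u) / rate) ** (1.0 / shape)


def calibrate_censoring_rate(
    eta: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    n_sim: int = 20000,
    tol: float = 1e-3,
) -> float:
    """Censoring-time rate whose expected censored fraction hits the target.

    Uses bisection on a simulated censored fraction with common random
    numbers, which stays valid for non-exponential (Weibull) shapes where no
    convenient closed form exists.
    """
    eta_s = rng.choice(eta, size=n_sim, replace=True)
    u_t, u_c = rng.random(n_sim), rng.random(n_sim)
    t = (-np.log(u_t) / (config.baseline_rate * np.exp(eta_s))) ** (1.0 / config.weibull_shape)

    def censored_fraction(rate_c: float) -> float:
        c = (-np.log(u_c) / rate_c) ** (1.0 / config.weibull_shape)
        return float(np.mean(t > c))

    lo, hi = config.baseline_rate * 1e-8, config.baseline_rate * 1e8
    if not censored_fraction(lo) < config.target_censoring < censored_fraction(hi):
        raise ValueError(
            f"censoring target {config.target_censoring} unreachable within rate bracket"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # log-scale bisection: rates span orders of magnitude
        if censored_fraction(mid) < config.target_censoring:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            break
    return float(np.sqrt(lo * hi))


def generate_task(
    config: SyntheticConfig,
    task_index: int,
    rng: np.random.Generator,
    n_samples: int | None = None,
    label: str | None = None,
) -> SyntheticTask:
    """One cohort drawn from the family distribution.

    The family structure (W1, W2, base w) is a deterministic function of the
    config seed; ``rng`` drives everything task-specific (jitter, latents,
    noise, event and censoring times).
    """
    W1, W2, w = _family_structure(config)
    r = config.latent_dim
    n = config.n_per_task if n_samples is None else n_samples
    w_task = w + rng.normal(0.0, config.task_perturbation_sd, r)
    u = rng.normal(0.0, 1.0, (n, r))
    X1 = u @ W1.T + rng.normal(0.0, config.noise_sd, (n, config.p1))
    X2 = u @ W2.T + rng.normal(0.0, config.noise_sd, (n, config.p2))
    eta = u @ w_task
    rate_c = calibrate_censoring_rate(eta, config, rng)
    T = _draw_times(config.baseline_rate * np.exp(eta), config.weibull_shape, rng)
    C = _draw_times(np.full(n, rate_c), config.weibull_shape, rng)
    observed = np.minimum(T, C)
    events = (T <= C).astype(int)
    name = label if label is not None else f"task{task_index}"
    ids = [f"{name}-s{i:05d}" for i in range(n)]
    dataset = MultiOmicsDataset(
        views=[
            OmicsMatrix("gene", ids, [f"g{j}" for j in range(config.p1)], X1),
            OmicsMatrix("mirna", ids, [f"m{j}" for j in range(config.p2)], X2),
        ],
        outcomes=[SurvivalOutcome(s, float(o), int(e)) for s, o, e in zip(ids, observed, events)],
    )
    return SyntheticTask(dataset, u, eta, T, C, w_task, source_label=name)


def generate_family(config: SyntheticConfig) -> tuple[list[SyntheticTask], SyntheticTask]:
    """n_tasks - 1 pool tasks plus one held-out target, sharing family structure."""
    if config.n_tasks < 2:
        raise ValueError("need at least 2 tasks (1 pool + 1 target)")
    tasks = []
    for i in range(config.n_tasks):
        rng = named_rng(config.seed, f"task-{i}")
        is_target = i == config.n_tasks - 1
        tasks.append(generate_task(config, i, rng, label="target" if is_target else f"pool{i}"))
    return tasks[:-1], tasks[-1]


def pool_union(tasks: list[SyntheticTask]) -> MultiOmicsDataset:
    """Concatenate pool task cohorts into one meta-training pool."""
    views = []
    for v in range(len(tasks[0].dataset.views)):
        mats = [t.dataset.views[v] for t in tasks]
        views.append(
            OmicsMatrix(
                mats[0].omics_name,
                [s for m in mats for s in m.sample_ids],
                mats[0].feature_ids,
                np.vstack([m.values for m in mats]),
            )
        )
    outcomes = [o for t in tasks for o in t.dataset.outcomes]
    return MultiOmicsDataset(views, outcomes)


def write_task(task: SyntheticTask, outdir: str | Path) -> None:
    """Write expression TSVs, the survival table and a ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for view in task.dataset.views:
        view.to_tsv(outdir / f"{view.omics_name}_expression.tsv")
    ids = task.dataset.sample_ids
    surv = pd.DataFrame(
        {"sample_id": ids, "time": task.dataset.times, "event": task.dataset.events}
    )
    surv.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    truth = pd.DataFrame({"sample_id": ids, "eta": task.eta,
                          "true_time": task.true_times, "censor_time": task.censor_times})
    for j in range(task.latents.shape[1]):
        truth[f"u{j}"] = task.latents[:, j]
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
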