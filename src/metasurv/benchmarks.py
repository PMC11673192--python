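"""Reference desk-scale experiments on synthetic task families.

These pin one reproducible configuration of the few-shot transfer protocol:
a family of nine related cohorts (eight for meta-training, one held-out
target), two omics views generated from shared latent factors, and the
replicated 10-shot comparison of training schemes. Model and replication
sizes are reduced relative to a full study (16-dim embeddings, 2 highway
layers, 10 draws x 3 repeats) so the whole experiment runs on one CPU in a
few minutes; the protocol itself — stratified task sampling, paired draws,
shared test split — is the full one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import BenchmarkReport, run_benchmark
from .meta import MetaConfig
from .model import HighwayEncoderConfig, ModelConfig
from .schemes import SchemeSpec
from .synthetic import SyntheticConfig, generate_family, pool_union

TRANSFER_SCHEMES = (
    "direct",
    "meta_multi_omics",
    "meta_wo_similarity",
    "meta_single_gene",
    "meta_single_mirna",
)


def reference_model_config(p1: int, p2: int) -> ModelConfig:
    return ModelConfig(
        encoders=[
            HighwayEncoderConfig(p1, n_layers=2, embed_dim=16),
            HighwayEncoderConfig(p2, n_layers=2, embed_dim=16),
        ]
    )


def reference_meta_config(seed: int) -> MetaConfig:
    # alpha/gamma/k/m/task_size sit on the standard search grids
    return MetaConfig(alpha=1e-2, gamma=1e-3, k=5, m=3, task_size=50,
                      meta_iterations=60, finetune_epochs=50, seed=seed)


def few_shot_transfer_benchmark(
    seed: int,
    complementary_views: bool = True,
    n_draws: int = 10,
    n_repeats: int = 3,
    shots: int = 10,
    schemes: tuple[str, ...] = TRANSFER_SCHEMES,
) -> BenchmarkReport:
    """The replicated few-shot comparison on one synthetic family.

    With ``complementary_views`` each omics view loads a disjoint half of the
    latent coordinates, so both views are informative but neither alone sees
    the whole risk signal — the regime where multi-omics integration and the
    cross-view similarity loss have something to contribute.
    """
    syn = SyntheticConfig(complementary_views=complementary_views, seed=seed)
    pool_tasks, target = generate_family(syn)
    pool = pool_union(pool_tasks)
    return run_benchmark(
        pool,
        [target.dataset],
        [SchemeSpec(name) for name in schemes],
        reference_model_config(syn.p1, syn.p2),
        reference_meta_config(seed),
        n_draws=n_draws,
        n_repeats=n_repeats,
        shots=shots,
        test_fraction=0.2,
        seed=seed,
    )


@dataclass
class SimulatorChecks:
    """Calibration diagnostics of the synthetic generator."""

    censored_fraction: float
    censoring_target: float
    null_c_index: float
    t_c_correlation: float


def simulator_calibration_checks(seed: int) -> SimulatorChecks:
    """Monte-Carlo checks of the generator against its own specification."""
    from .evaluation import concordance_index
    from .synthetic import generate_task

    small = dict(latent_dim=4, p1=20, p2=8, n_per_task=200, n_tasks=3)
    cfg = SyntheticConfig(**small, target_censoring=0.75, seed=seed)
    task = generate_task(cfg, 0, np.random.default_rng(seed), n_samples=5000)
    censored = 1.0 - task.dataset.events.mean()

    null_cfg = SyntheticConfig(**small, risk_scale=0.0, task_perturbation_sd=0.0,
                               seed=seed)
    null_task = generate_task(null_cfg, 0, np.random.default_rng(seed + 1),
                              n_samples=2000)
    null_c = concordance_index(np.random.default_rng(seed + 2).normal(size=2000),
                               null_task.dataset.times, null_task.dataset.events)

    ind_task = generate_task(SyntheticConfig(**small, seed=seed), 0,
                             np.random.default_rng(seed + 3), n_samples=10000)
    corr = float(np.corrcoef(ind_task.true_times, ind_task.censor_times)[0, 1])
    return SimulatorChecks(float(censored), 0.75, float(null_c), corr)
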