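import numpy as np
import pytest

from metasurv.io_preprocess import MultiOmicsDataset, OmicsMatrix, SurvivalOutcome
from metasurv.model import HighwayEncoderConfig, ModelConfig, MultiOmicsSurvivalModel
from metasurv.synthetic import SyntheticConfig, generate_family, pool_union


def make_dataset(rng, n=30, p1=10, p2=6, censor_frac=0.4, prefix="s"):
    """Small random aligned two-view dataset for unit tests."""
    ids = [f"{prefix}{i:03d}" for i in range(n)]
    views = [
        OmicsMatrix("gene", ids, [f"g{j}" for j in range(p1)], rng.normal(size=(n, p1))),
        OmicsMatrix("mirna", ids, [f"m{j}" for j in range(p2)], rng.normal(size=(n, p2))),
    ]
    times = rng.exponential(100.0, n) + 1.0
    events = (rng.random(n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[0] = 1
    outcomes = [SurvivalOutcome(s, float(t), int(e)) for s, t, e in zip(ids, times, events)]
    return MultiOmicsDataset(views, outcomes)


def tiny_model(p1=10, p2=6, embed_dim=8, n_layers=2, **kwargs):
    cfg = ModelConfig(
        encoders=[
            HighwayEncoderConfig(p1, n_layers=n_layers, embed_dim=embed_dim),
            HighwayEncoderConfig(p2, n_layers=n_layers, embed_dim=embed_dim),
        ],
        **kwargs,
    )
    return MultiOmicsSurvivalModel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dataset(rng):
    return make_dataset(rng)


@pytest.fixture(scope="session")
def small_family():
    """A small task family shared by meta/scheme tests: 3 pool tasks + target."""
    cfg = SyntheticConfig(
        latent_dim=4, p1=30, p2=12, n_per_task=150, n_tasks=4,
        risk_scale=1.0, noise_sd=1.0, target_censoring=0.6, seed=99,
    )
    pool_tasks, target = generate_family(cfg)
    return pool_union(pool_tasks), target


@pytest.fixture(scope="session")
def small_model():
    return tiny_model(p1=30, p2=12, embed_dim=8, n_layers=2)
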