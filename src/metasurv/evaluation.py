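"""Survival metrics and the replicated few-shot benchmark protocol.

Concordance follows Harrell's definition: a pair (i, j) is comparable iff
O_i < O_j and patient i had the event; it is concordant when the model gives
i the higher risk, with half credit for tied scores. The time-dependent AUC
is the Uno-style cumulative/dynamic estimator: cases are patients with an
observed event by the horizon, controls those still at risk past it, and
both sides are inverse-probability-of-censoring weighted with a Kaplan-Meier
estimate of the censoring distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sksurv.nonparametric import kaplan_meier_estimator

from ._utils import named_rng, round_half_up, spawn_seed
from .io_preprocess import MultiOmicsDataset


@dataclass
class EvaluationResult:
    scheme: str
    replicate: int
    draw: int
    c_index: float
    auc: float
    n_test: int

    def __post_init__(self) -> None:
        if not (0 <= self.c_index <= 1 and (np.isnan(self.auc) or 0 <= self.auc <= 1)):
            raise ValueError("metrics must lie in [0, 1]")


def concordance_index(h, times, events) -> float:
    """Harrell's C: concordant credit over comparable pairs; ties in score 0.5."""
    h = np.asarray(h, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    dt = times[:, None] < times[None, :]
    comparable = dt & (events[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pair (is everything censored or tied?)")
    greater = h[:, None] > h[None, :]
    tied = h[:, None] == h[None, :]
    credit = (comparable & greater).sum() + 0.5 * (comparable & tied).sum()
    return float(credit / n_comp)


def _censoring_survival(times, events):
    """KM estimate of the censoring distribution G(t) = P(C > t)."""
    # censoring 'events' are the complements of the survival events
    t, g = kaplan_meier_estimator((1 - np.asarray(events)).astype(bool), times)
    return t, g


def _step_lookup(step_times, step_vals, query, left_limit=False):
    """Right-continuous step-function evaluation, optionally the left limit."""
    side = "left" if left_limit else "right"
    idx = np.searchsorted(step_times, query, side=side)
    out = np.ones(np.shape(query), dtype=float)
    pos = idx > 0
    out[pos] = step_vals[idx[pos] - 1]
    return out


def time_dependent_auc(h, times, events, horizon: float | None = None) -> float:
    """IPCW cumulative/dynamic AUC at a horizon (default: median observed time)."""
    h = np.asarray(h, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if horizon is None:
        horizon = float(np.median(times))
    if not times.min() <= horizon <= times.max():
        raise ValueError(f"horizon {horizon} outside observed time range")
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    if not cases.any() or not controls.any():
        raise ValueError(f"no cases or no controls at horizon {horizon}")
    kt, kg = _censoring_survival(times, events)
    g_case = _step_lookup(kt, kg, times[cases], left_limit=True)  # G(O_i^-)
    g_ctrl = _step_lookup(kt, kg, np.full(controls.sum(), horizon))
    w_case = 1.0 / np.clip(g_case, 1e-12, None)
    w_ctrl = 1.0 / np.clip(g_ctrl, 1e-12, None)
    hc, hn = h[cases], h[controls]
    greater = hc[:, None] > hn[None, :]
    tied = hc[:, None] == hn[None, :]
    weights = w_case[:, None] * w_ctrl[None, :]
    return float((weights * (greater + 0.5 * tied)).sum() / weights.sum())


def stratified_split(dataset: MultiOmicsDataset, test_fraction: float,
                     rng: np.random.Generator):
    """Train/test split stratified by censoring status."""
    test_idx = []
    for flag in (0, 1):
        idx = np.where(dataset.events == flag)[0]
        n_test = round_half_up(len(idx) * test_fraction)
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(dataset.n_samples), test_idx)
    return dataset.subset(train_idx), dataset.subset(test_idx)


def draw_few_shot(train: MultiOmicsDataset, shots: int, uncensored_fraction: float,
                  rng: np.random.Generator) -> MultiOmicsDataset:
    """Draw the few labelled training samples, stratified by censoring status."""
    from .meta import sample_task

    return sample_task(train, shots, uncensored_fraction, rng).support


@dataclass
class BenchmarkReport:
    """Per-scheme results plus summary statistics and average ranks."""

    results: pd.DataFrame  # columns: target, scheme, replicate, draw, c_index, auc, n_test

    def summary(self) -> pd.DataFrame:
        return (
            self.results.groupby(["target", "scheme"])[["c_index", "auc"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def scheme_means(self, metric: str = "c_index") -> pd.Series:
        return self.results.groupby("scheme")[metric].mean()

    def average_ranks(self, metric: str = "c_index") -> pd.Series:
        """Rank schemes within each target by mean metric (1 = best, ties averaged)."""
        per_target = self.results.groupby(["target", "scheme"])[metric].mean().unstack()
        ranks = per_target.rank(axis=1, ascending=False, method="average")
        return ranks.mean(axis=0)

    def paired_wilcoxon(self, scheme_a: str, scheme_b: str,
                        metric: str = "c_index") -> float:
        """One-sided Wilcoxon p for scheme_a > scheme_b, paired over (target, replicate, draw)."""
        wide = self.results.pivot_table(
            index=["target", "replicate", "draw"], columns="scheme", values=metric)
        a, b = wide[scheme_a].to_numpy(), wide[scheme_b].to_numpy()
        diff = a - b
        if np.allclose(diff, 0):
            return 1.0
        return float(sps.wilcoxon(a, b, alternative="greater").pvalue)

    def to_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_benchmark(
    pool: MultiOmicsDataset,
    targets: list[MultiOmicsDataset],
    schemes: list,
    model_config,
    meta_config,
    n_draws: int = 50,
    n_repeats: int = 20,
    shots: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    horizon: float | None = None,
    target_names: list[str] | None = None,
) -> BenchmarkReport:
    """The replicated few-shot protocol.

    Per target and repeat: re-split train/test stratified by censoring, train
    each scheme's pool-level artifact once (meta-learned or pretrained
    initialization), then for each draw pull ``shots`` stratified training
    samples and give every scheme the identical draw and test split — the
    comparison is paired by construction. Metrics are averaged over draws and
    repeats by the report.
    """
    from .schemes import prepare_pool_artifacts, run_scheme_on_draw

    names = target_names or [f"target{i}" for i in range(len(targets))]
    rows = []
    for tname, target in zip(names, targets):
        for rep in range(n_repeats):
            rng_rep = named_rng(seed, f"benchmark/{tname}/rep{rep}")
            train, test = stratified_split(target, test_fraction, rng_rep)
            artifacts = prepare_pool_artifacts(
                schemes, pool, model_config, meta_config, seed=spawn_seed(rng_rep))
            for draw in range(n_draws):
                few = draw_few_shot(train, shots, meta_config.uncensored_fraction, rng_rep)
                for spec in schemes:
                    res = run_scheme_on_draw(
                        spec, artifacts, pool, few, test, model_config, meta_config,
                        rng=np.random.default_rng(spawn_seed(rng_rep)), horizon=horizon)
                    rows.append({
                        "target": tname, "scheme": spec.name, "replicate": rep,
                        "draw": draw, "c_index": res.c_index, "auc": res.auc,
                        "n_test": res.n_test,
                    })
    return BenchmarkReport(pd.DataFrame(rows))


def plot_shot_curve(report_by_shots: dict[int, BenchmarkReport], scheme: str, path) -> None:
    """C-index of one scheme against training-set size, mean over replicates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shots = sorted(report_by_shots)
    means = [report_by_shots[s].scheme_means().get(scheme, np.nan) for s in shots]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(shots, means, marker="o")
    ax.set_xlabel("training samples")
    ax.set_ylabel("mean C-index")
    ax.set_title(scheme)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
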