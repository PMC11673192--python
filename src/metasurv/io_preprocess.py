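"""Reading, filtering and normalising expression matrices and survival tables.

The preprocessing pipeline mirrors common practice for TCGA-style expression
data: drop features with too many missing values, impute the rest by the
feature median, log-transform, drop near-constant features, and standardise
each feature to zero mean and unit variance. Samples are then aligned across
omics views and the survival table by intersecting sample identifiers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKENS = ("NA", "NaN", "nan", "null", "")


@dataclass
class OmicsMatrix:
    """One omics view: samples x features with optional missing entries (NaN)."""

    omics_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (n_samples, n_features), float64, NaN = missing

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        for label, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {label} ids: {sorted(dupes)}")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    def subset_samples(self, indices: np.ndarray) -> "OmicsMatrix":
        indices = np.asarray(indices)
        return OmicsMatrix(
            self.omics_name,
            [self.sample_ids[i] for i in indices],
            list(self.feature_ids),
            self.values[indices],
        )

    def replace_values(self, values: np.ndarray, feature_ids: list[str] | None = None) -> "OmicsMatrix":
        return OmicsMatrix(
            self.omics_name,
            list(self.sample_ids),
            list(self.feature_ids) if feature_ids is None else feature_ids,
            values,
        )


@dataclass(frozen=True)
class SurvivalOutcome:
    """Observed follow-up for one patient: time in days and event indicator."""

    sample_id: str
    observed_time: float
    event: int

    def __post_init__(self) -> None:
        if not self.observed_time > 0:
            raise ValueError(f"{self.sample_id}: observed_time must be > 0, got {self.observed_time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1, got {self.event}")


@dataclass
class MultiOmicsDataset:
    """Aligned omics views plus survival outcomes, all in one shared sample order."""

    views: list[OmicsMatrix]
    outcomes: list[SurvivalOutcome]

    def __post_init__(self) -> None:
        ids = [o.sample_id for o in self.outcomes]
        for v in self.views:
            if v.sample_ids != ids:
                raise ValueError(f"view '{v.omics_name}' sample order differs from outcomes")

    @property
    def n_samples(self) -> int:
        return len(self.outcomes)

    @property
    def sample_ids(self) -> list[str]:
        return [o.sample_id for o in self.outcomes]

    @property
    def times(self) -> np.ndarray:
        return np.array([o.observed_time for o in self.outcomes], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([o.event for o in self.outcomes], dtype=int)

    def view_values(self) -> list[np.ndarray]:
        return [v.values for v in self.views]

    def view_named(self, name: str) -> OmicsMatrix:
        for v in self.views:
            if v.omics_name == name:
                return v
        raise KeyError(f"no view named '{name}' (have {[v.omics_name for v in self.views]})")

    def subset(self, indices: np.ndarray) -> "MultiOmicsDataset":
        indices = np.asarray(indices)
        return MultiOmicsDataset(
            [v.subset_samples(indices) for v in self.views],
            [self.outcomes[i] for i in indices],
        )


def _duplicates(ids) -> set:
    seen: set = set()
    dup: set = set()
    for x in ids:
        (dup if x in seen else seen).add(x)
    return dup


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    omics_name: str | None = None,
) -> OmicsMatrix:
    """Read a delimited expression matrix into samples x features orientation.

    ``orientation`` names the layout of the *file*: TCGA RNASeq downloads put
    features in rows, one column per sample; ``features_in_rows`` transposes
    on read so the result is always samples x features. Missing tokens
    ("NA", empty cell) become NaN; any other non-numeric cell is an error
    with its location.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation '{orientation}'")
    raw = _read_delimited(path)
    if orientation == "features_in_rows":
        raw = raw.T
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col].to_numpy()):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value '{cell}' at sample '{raw.index[i]}', "
                    f"feature '{col}'"
                ) from None
    name = omics_name if omics_name is not None else Path(path).stem
    return OmicsMatrix(name, list(raw.index), list(raw.columns), values)


def read_survival_table(path: str | Path) -> list[SurvivalOutcome]:
    """Read a survival table with columns sample_id, time, event.

    Rows with non-positive time or an event flag outside {0, 1} are rejected
    with their (1-based, header excluded) row numbers.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    bad_rows = []
    outcomes = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        time, event = float(row.time), row.event
        if not time > 0 or event not in (0, 1):
            bad_rows.append(pos)
            continue
        outcomes.append(SurvivalOutcome(str(row.sample_id), time, int(event)))
    if bad_rows:
        raise ValueError(
            f"{path}: invalid rows (time <= 0 or event not in {{0,1}}) at row(s) {bad_rows}"
        )
    return outcomes


def filter_missing_features(X: OmicsMatrix, max_na_fraction: float = 0.10) -> OmicsMatrix:
    """Drop features whose missing fraction strictly exceeds ``max_na_fraction``."""
    if not 0 <= max_na_fraction < 1:
        raise ValueError("max_na_fraction must be in [0, 1)")
    frac = np.isnan(X.values).mean(axis=0)
    keep = frac <= max_na_fraction
    if not keep.any():
        raise ValueError(f"{X.omics_name}: all features exceed missing fraction {max_na_fraction}")
    return X.replace_values(X.values[:, keep], [f for f, k in zip(X.feature_ids, keep) if k])


def impute_median(X: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing entry by the median of its feature's observed values."""
    fully_missing = np.isnan(X.values).all(axis=0)
    if fully_missing.any():
        bad = [f for f, m in zip(X.feature_ids, fully_missing) if m]
        raise ValueError(f"{X.omics_name}: feature(s) fully missing, filter first: {bad}")
    medians = np.nanmedian(X.values, axis=0)
    values = np.where(np.isnan(X.values), medians[None, :], X.values)
    return X.replace_values(values)


def log_transform(X: OmicsMatrix, pseudocount: float = 1.0, base: float = 2.0) -> OmicsMatrix:
    """log_base(x + pseudocount); expression values must be nonnegative."""
    if np.nanmin(X.values) < 0:
        raise ValueError(f"{X.omics_name}: negative values cannot be log-transformed")
    return X.replace_values(np.log(X.values + pseudocount) / np.log(base))


def remove_low_variance(X: OmicsMatrix, min_variance: float = 1e-8) -> OmicsMatrix:
    """Drop features whose sample variance (ddof=1) falls below ``min_variance``."""
    if np.isnan(X.values).any():
        raise ValueError(f"{X.omics_name}: impute before variance filtering")
    if X.n_samples < 2:
        raise ValueError("variance filter needs at least 2 samples")
    var = X.values.var(axis=0, ddof=1)
    keep = var >= min_variance
    if not keep.any():
        raise ValueError(f"{X.omics_name}: every feature is below variance {min_variance}")
    return X.replace_values(X.values[:, keep], [f for f, k in zip(X.feature_ids, keep) if k])


@dataclass
class StandardizationStats:
    """Per-feature location/scale, fit once (e.g. on a meta-training pool) and reused."""

    mean: np.ndarray
    std: np.ndarray
    convention: str  # 'population' (1/n) or 'sample' (1/(n-1))


def fit_standardization(X: OmicsMatrix, convention: str = "population") -> StandardizationStats:
    if convention not in ("population", "sample"):
        raise ValueError(f"unknown convention '{convention}'")
    ddof = 0 if convention == "population" else 1
    std = X.values.std(axis=0, ddof=ddof)
    if (std == 0).any():
        bad = [f for f, s in zip(X.feature_ids, std) if s == 0]
        raise ValueError(f"{X.omics_name}: zero-variance feature(s): {bad[:5]}")
    return StandardizationStats(X.values.mean(axis=0), std, convention)


def zscore(
    X: OmicsMatrix,
    stats: StandardizationStats | None = None,
    convention: str = "population",
) -> OmicsMatrix:
    """Standardise each feature to zero mean / unit variance.

    Pass ``stats`` fit on a reference cohort to apply its location/scale to new
    data (avoids leaking tiny few-shot statistics); otherwise fit on X itself.
    """
    if stats is None:
        stats = fit_standardization(X, convention)
    return X.replace_values((X.values - stats.mean[None, :]) / stats.std[None, :])


def align_samples(views: list[OmicsMatrix], outcomes: list[SurvivalOutcome]) -> MultiOmicsDataset:
    """Intersect sample ids across all views and the survival table; sort lexicographically."""
    common = set(o.sample_id for o in outcomes)
    for v in views:
        common &= set(v.sample_ids)
    if not common:
        raise ValueError("no sample is present in every view and the survival table")
    order = sorted(common)
    out_by_id = {o.sample_id: o for o in outcomes}
    aligned_views = []
    for v in views:
        idx = {s: i for i, s in enumerate(v.sample_ids)}
        aligned_views.append(v.subset_samples(np.array([idx[s] for s in order])))
    return MultiOmicsDataset(aligned_views, [out_by_id[s] for s in order])


@dataclass
class PreprocessReport:
    """Per-view, per-stage record of feature attrition."""

    stages: dict = field(default_factory=dict)

    def record(self, view: str, stage: str, before: int, after: int) -> None:
        self.stages.setdefault(view, []).append(
            {"stage": stage, "features_before": before, "features_after": after,
             "dropped": before - after}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.stages, indent=2) + "\n")


def preprocess_view(
    X: OmicsMatrix,
    max_na_fraction: float = 0.10,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
    min_variance: float = 1e-8,
    convention: str = "population",
    report: PreprocessReport | None = None,
) -> OmicsMatrix:
    """filter -> impute -> log -> low-variance -> zscore, recording attrition."""
    rep = report if report is not None else PreprocessReport()
    n0 = X.n_features
    X = filter_missing_features(X, max_na_fraction)
    rep.record(X.omics_name, "missing_filter", n0, X.n_features)
    X = impute_median(X)
    X = log_transform(X, pseudocount, log_base)
    n1 = X.n_features
    X = remove_low_variance(X, min_variance)
    rep.record(X.omics_name, "low_variance_filter", n1, X.n_features)
    X = zscore(X, convention=convention)
    return X
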