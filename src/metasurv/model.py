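"""Differentiable multi-omics deep Cox model.

Each omics view is encoded by a highway network (a gated residual MLP:
``out = H(x)*T(x) + G(x)*(1-T(x))`` with nonlinear transform H, affine carry
G and sigmoid gate T) into a shared low-dimensional embedding space. Training
combines two losses on a batch:

* a margin-based hinge similarity loss on cosine similarities that pulls the
  two views of the same patient together and pushes views of different
  patients apart, and
* the negative mean log Cox partial likelihood of a risk head applied to the
  per-patient mean of the view embeddings.

All parameters live in one flat vector so first-order meta-learning can do
plain arithmetic on them; gradients come from reverse-mode autodiff
(autograd), so every function below that touches parameters uses
``autograd.numpy``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.tracer import getval

EPS_NORM = 1e-12  # guard added to embedding norms inside the training loss


@dataclass
class HighwayEncoderConfig:
    """Architecture of one per-omics encoder.

    A linear projection maps the raw feature vector to ``hidden_dim``, then
    ``n_layers`` highway layers operate at that width; if ``hidden_dim``
    differs from ``embed_dim`` a final linear layer maps down.
    The transform gate starts carry-biased (negative ``gate_bias_init``) so
    early training behaves like the identity plus a small perturbation.
    """

    input_dim: int
    n_layers: int = 5
    embed_dim: int = 80
    hidden_dim: int | None = None
    nonlinearity: str = "tanh"
    gate_bias_init: float = -2.0

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.embed_dim < 1 or self.input_dim < 1:
            raise ValueError("dims and n_layers must be positive")
        if self.hidden_dim is None:
            self.hidden_dim = self.embed_dim


@dataclass
class ModelConfig:
    """Full model: one encoder per omics view plus loss settings."""

    encoders: list[HighwayEncoderConfig]
    head_hidden_dim: int | None = None  # None = linear risk head
    margin: float = 0.2
    sim_weight: float = 1.0
    negative_rule: str = "one_random"  # 'one_random' | 'all_pairs' | 'hardest'
    symmetric_similarity: bool = False
    risk_set_rule: str = "geq"  # 'geq' (Breslow) | 'gt' (strict)

    def __post_init__(self) -> None:
        dims = {e.embed_dim for e in self.encoders}
        if len(dims) != 1:
            raise ValueError("all encoders must share embed_dim")
        if self.negative_rule not in ("one_random", "all_pairs", "hardest"):
            raise ValueError(f"unknown negative_rule '{self.negative_rule}'")
        if self.risk_set_rule not in ("geq", "gt"):
            raise ValueError(f"unknown risk_set_rule '{self.risk_set_rule}'")

    @property
    def embed_dim(self) -> int:
        return self.encoders[0].embed_dim

    @property
    def n_views(self) -> int:
        return len(self.encoders)


@dataclass
class LossBreakdown:
    cox: float
    sim: float
    sim_weight: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.cox + self.sim_weight * self.sim


_NONLIN = {"tanh": anp.tanh, "relu": lambda x: anp.maximum(x, 0.0)}


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


class ParameterSpec:
    """Layout of a flat parameter vector: named blocks with shapes and offsets."""

    def __init__(self, entries: list[tuple[str, tuple[int, ...]]]):
        self.entries = entries
        self.offsets = {}
        off = 0
        for name, shape in entries:
            size = int(np.prod(shape))
            self.offsets[name] = (off, off + size, shape)
            off += size
        self.size = off

    def get(self, theta, name):
        lo, hi, shape = self.offsets[name]
        return anp.reshape(theta[lo:hi], shape)

    def pack(self, blocks: dict) -> np.ndarray:
        flat = np.empty(self.size)
        for name, (lo, hi, shape) in self.offsets.items():
            flat[lo:hi] = np.asarray(blocks[name], dtype=float).ravel()
        return flat


def build_parameter_spec(config: ModelConfig) -> ParameterSpec:
    entries: list[tuple[str, tuple[int, ...]]] = []
    for v, enc in enumerate(config.encoders):
        d = enc.hidden_dim
        entries += [(f"enc{v}/proj/W", (enc.input_dim, d)), (f"enc{v}/proj/b", (d,))]
        for l in range(enc.n_layers):
            for part in ("H", "T", "G"):
                entries += [(f"enc{v}/layer{l}/{part}/W", (d, d)),
                            (f"enc{v}/layer{l}/{part}/b", (d,))]
        if d != enc.embed_dim:
            entries += [(f"enc{v}/out/W", (d, enc.embed_dim)), (f"enc{v}/out/b", (enc.embed_dim,))]
    d = config.embed_dim
    if config.head_hidden_dim is not None:
        entries += [("head/hidden/W", (d, config.head_hidden_dim)),
                    ("head/hidden/b", (config.head_hidden_dim,)),
                    ("head/out/W", (config.head_hidden_dim,)), ("head/out/b", ())]
    else:
        entries += [("head/out/W", (d,)), ("head/out/b", ())]
    return ParameterSpec(entries)


def init_parameters(config: ModelConfig, rng: np.random.Generator) -> np.ndarray:
    """Scaled-normal init; carry path starts at the identity with a closed gate."""
    spec = build_parameter_spec(config)
    blocks = {}
    for name, (lo, hi, shape) in spec.offsets.items():
        if name.endswith("/b"):
            if "/T/" in name:
                v = int(name.split("/")[0].removeprefix("enc"))
                blocks[name] = np.full(shape, config.encoders[v].gate_bias_init)
            else:
                blocks[name] = np.zeros(shape)
        elif name.endswith("/W"):
            if "/G/" in name and shape[0] == shape[1]:
                blocks[name] = np.eye(shape[0])
            else:
                fan_in = shape[0] if len(shape) > 1 else shape[0]
                blocks[name] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), shape)
        else:  # scalar bias
            blocks[name] = np.zeros(shape)
    return spec.pack(blocks)


def highway_layer(x, layer_params: dict, nonlinearity: str = "tanh"):
    """One gated layer: ``H(x)*T(x) + G(x)*(1-T(x))``.

    ``layer_params`` maps 'H', 'T', 'G' to (W, b). H is nonlinear, G affine,
    T a sigmoid gate in (0, 1).
    """
    f = _NONLIN[nonlinearity]
    Wh, bh = layer_params["H"]
    Wt, bt = layer_params["T"]
    Wg, bg = layer_params["G"]
    h = f(anp.dot(x, Wh) + bh)
    t = _sigmoid(anp.dot(x, Wt) + bt)
    g = anp.dot(x, Wg) + bg
    return h * t + g * (1.0 - t)


class MultiOmicsSurvivalModel:
    """Bundles a ModelConfig with its parameter layout and loss machinery."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.spec = build_parameter_spec(config)

    @property
    def n_parameters(self) -> int:
        return self.spec.size

    def init_parameters(self, rng: np.random.Generator) -> np.ndarray:
        return init_parameters(self.config, rng)

    def encode(self, theta, X, view: int = 0):
        """Embed one view's samples x features matrix; row i depends only on sample i."""
        enc = self.config.encoders[view]
        X = anp.atleast_2d(X)
        if X.shape[1] != enc.input_dim:
            raise ValueError(f"view {view}: expected {enc.input_dim} features, got {X.shape[1]}")
        g = self.spec.get
        h = anp.dot(X, g(theta, f"enc{view}/proj/W")) + g(theta, f"enc{view}/proj/b")
        for l in range(enc.n_layers):
            params = {p: (g(theta, f"enc{view}/layer{l}/{p}/W"),
                          g(theta, f"enc{view}/layer{l}/{p}/b")) for p in ("H", "T", "G")}
            h = highway_layer(h, params, enc.nonlinearity)
        if enc.hidden_dim != enc.embed_dim:
            h = anp.dot(h, g(theta, f"enc{view}/out/W")) + g(theta, f"enc{view}/out/b")
        return h

    def embed_all(self, theta, views: list):
        return [self.encode(theta, X, v) for v, X in enumerate(views)]

    def risk_from_embedding(self, theta, z):
        g = self.spec.get
        z = anp.atleast_2d(z)
        if self.config.head_hidden_dim is not None:
            h = anp.tanh(anp.dot(z, g(theta, "head/hidden/W")) + g(theta, "head/hidden/b"))
            return anp.dot(h, g(theta, "head/out/W")) + g(theta, "head/out/b")
        return anp.dot(z, g(theta, "head/out/W")) + g(theta, "head/out/b")

    def risk_scores(self, theta, views: list) -> np.ndarray:
        """Log relative hazard per sample; higher = higher predicted risk."""
        Z = self.embed_all(theta, views)
        return np.asarray(self.risk_from_embedding(theta, fuse(*Z) if len(Z) > 1 else Z[0]))

    # -- losses ----------------------------------------------------------

    def sample_negatives(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """One random negative j != i per anchor, for the 'one_random' rule."""
        offsets = rng.integers(1, n, size=n)
        return (np.arange(n) + offsets) % n

    def loss(self, theta, views, times, events, neg_idx=None, rng=None) -> LossBreakdown:
        cox, sim = self._loss_terms(theta, views, times, events, neg_idx, rng)
        return LossBreakdown(float(cox), float(sim), self.config.sim_weight)

    def loss_value_and_grad(self, theta, views, times, events, neg_idx=None, rng=None):
        if self.config.sim_weight != 0 and self.config.n_views > 1 and neg_idx is None:
            if self.config.negative_rule == "one_random":
                if rng is None:
                    raise ValueError("one_random rule needs neg_idx or rng")
                neg_idx = self.sample_negatives(len(times), rng)

        def objective(th):
            cox, sim = self._loss_terms(th, views, times, events, neg_idx, None)
            return cox + self.config.sim_weight * sim

        return value_and_grad(objective)(theta)

    def _loss_terms(self, theta, views, times, events, neg_idx, rng):
        Z = self.embed_all(theta, views)
        fused = fuse(*Z) if len(Z) > 1 else Z[0]
        h = self.risk_from_embedding(theta, fused)
        cox = cox_partial_likelihood_loss(h, times, events, self.config.risk_set_rule)
        if len(Z) > 1 and self.config.sim_weight != 0:
            sim = similarity_loss(
                Z[0], Z[1], self.config.margin, self.config.negative_rule,
                rng=rng, neg_idx=neg_idx, symmetric=self.config.symmetric_similarity,
            )
        else:
            sim = 0.0
        return cox, sim


def fuse(z1, z2):
    """Fused patient embedding: elementwise mean of the per-view embeddings."""
    return 0.5 * (z1 + z2)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two vectors; errors on zero-norm input."""
    a, b = anp.asarray(a, dtype=float), anp.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vector")
    return anp.dot(a, b) / (na * nb)


def similarity_loss(Z1, Z2, margin: float, negative_rule: str = "one_random",
                    rng: np.random.Generator | None = None, neg_idx=None,
                    symmetric: bool = False):
    """Margin hinge on cross-view cosine similarities, averaged over anchors.

    Anchor i's positive is its own second-view embedding; negatives j != i are
    chosen by ``negative_rule``: one random j (seeded), the mean over all j,
    or the hardest (most similar) j. Zero exactly when every same-patient
    similarity beats every selected cross-patient similarity by >= margin.
    """
    n = Z1.shape[0]
    if n < 2:
        raise ValueError("similarity loss needs at least 2 samples")
    S = _cosine_matrix(Z1, Z2)
    loss = _hinge_from_matrix(S, margin, negative_rule, rng, neg_idx, n)
    if symmetric:
        loss = 0.5 * (loss + _hinge_from_matrix(_cosine_matrix(Z2, Z1), margin,
                                                negative_rule, rng, neg_idx, n))
    return loss


def _cosine_matrix(Z1, Z2):
    n1 = anp.sqrt(anp.sum(Z1 * Z1, axis=1)) + EPS_NORM
    n2 = anp.sqrt(anp.sum(Z2 * Z2, axis=1)) + EPS_NORM
    return anp.dot(Z1 / n1[:, None], (Z2 / n2[:, None]).T)


def _hinge_from_matrix(S, margin, rule, rng, neg_idx, n):
    pos = anp.diag(S)
    if rule == "one_random":
        if neg_idx is None:
            if rng is None:
                raise ValueError("one_random rule needs an rng or precomputed neg_idx")
            offsets = rng.integers(1, n, size=n)
            neg_idx = (np.arange(n) + offsets) % n
        neg = S[anp.arange(n), neg_idx]
        return anp.mean(anp.maximum(0.0, margin - (pos - neg)))
    off_diag = ~np.eye(n, dtype=bool)
    hinges = anp.maximum(0.0, margin - (pos[:, None] - S))
    if rule == "all_pairs":
        return anp.sum(hinges * off_diag) / (n * (n - 1))
    if rule == "hardest":
        neg = anp.max(anp.where(off_diag, S, -anp.inf), axis=1)
        return anp.mean(anp.maximum(0.0, margin - (pos - neg)))
    raise ValueError(f"unknown negative_rule '{rule}'")


def risk_score(z, weights, bias: float = 0.0) -> float:
    """Linear risk head on one embedding: w.z + b."""
    return float(np.dot(np.asarray(z, float), np.asarray(weights, float)) + bias)


def cox_partial_likelihood_loss(h, times, events, risk_set_rule: str = "geq"):
    """Negative mean log Cox partial likelihood.

    For each event i the risk set is {j : O_j >= O_i} under 'geq' (Breslow
    convention, always nonempty since it contains i) or {j : O_j > O_i} under
    the strict 'gt' rule, which raises if any event's risk set is empty.
    The log-sum-exp is stabilised by max subtraction. All-censored input has
    no likelihood contribution and returns 0 with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a nonempty 1-d array")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    n = len(times)
    h = anp.reshape(h, (n,))
    event_mask = events == 1
    if not event_mask.any():
        warnings.warn("all samples censored: Cox loss is 0 with no gradient signal")
        return 0.0 * anp.sum(h)
    ev_times = times[event_mask]
    if risk_set_rule == "geq":
        R = times[None, :] >= ev_times[:, None]
    elif risk_set_rule == "gt":
        R = times[None, :] > ev_times[:, None]
        empty = ~R.any(axis=1)
        if empty.any():
            bad = np.where(event_mask)[0][empty]
            raise ValueError(
                f"strict risk-set rule leaves event(s) at index {bad.tolist()} "
                "with an empty risk set; use rule 'geq'"
            )
    else:
        raise ValueError(f"unknown risk_set_rule '{risk_set_rule}'")
    h_ev = h[np.where(event_mask)[0]]
    # constant max shift per risk set: lse(h) = a + log sum exp(h - a) holds
    # exactly for any constant a, so treating a as data keeps gradients exact
    h_const = np.where(R, getval(h)[None, :], -np.inf)
    a = h_const.max(axis=1)
    expd = anp.exp(anp.where(R, h[None, :] - a[:, None], -np.inf))
    lse = a + anp.log(anp.sum(expd, axis=1))
    return -anp.sum(h_ev - lse) / n


def total_loss(model: MultiOmicsSurvivalModel, theta, views, times, events,
               neg_idx=None, rng=None) -> LossBreakdown:
    """Convenience wrapper: LossBreakdown of Cox + weighted similarity terms."""
    return model.loss(theta, views, times, events, neg_idx=neg_idx, rng=rng)
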