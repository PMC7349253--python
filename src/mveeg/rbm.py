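"""Stacked restricted Boltzmann machine pretraining.

Greedy layer-wise training of the X-500-500-2500-d feedforward stack by
CD-1 contrastive divergence.  The first three hidden layers are Bernoulli
(sigmoid means), the top layer is linear-Gaussian so the latent code is
real-valued and stable.  Visible units of every RBM are treated as
real-valued probabilities in [0, 1] (the multi-view features are min-max
scaled before entering the stack).

Training hyperparameters follow the published schedule: sigmoid layers use
learning rate 0.007, L2 weight-cost 0.005, 70 epochs, momentum 0.5 for the
first ten epochs then 0.7; the linear layer uses 0.0002 / 0.003 / 80 epochs
with momentum 0.6 then 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RBMParams",
    "LayerSchedule",
    "PretrainSchedule",
    "DeepNet",
    "sigmoid",
    "rbm_energy",
    "hidden_prob",
    "visible_prob",
    "cd_step",
    "train_rbm",
    "train_rbm_stack",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBMParams:
    """Weights and biases of one RBM: ``W`` is visible x hidden, ``b`` the
    visible biases, ``c`` the hidden biases."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray
    hidden_kind: str = "bernoulli"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.W.shape != (self.b.size, self.c.size):
            raise ValueError("W must be (n_visible, n_hidden)")
        if self.hidden_kind not in ("bernoulli", "linear"):
            raise ValueError(f"unknown hidden_kind {self.hidden_kind!r}")
        for arr in (self.W, self.b, self.c):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite RBM parameters")


@dataclass(frozen=True)
class LayerSchedule:
    """CD training schedule for one RBM layer."""

    learning_rate: float
    weight_cost: float
    n_iterations: int
    momentum_initial: float
    momentum_later: float
    momentum_switch_epoch: int = 10
    batch_size: int = 100

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.n_iterations < 1:
            raise ValueError("learning rate must be > 0 and iterations >= 1")

    def momentum_at(self, epoch: int) -> float:
        """Momentum for a 1-based epoch index."""
        return (self.momentum_initial if epoch <= self.momentum_switch_epoch
                else self.momentum_later)


@dataclass(frozen=True)
class PretrainSchedule:
    """Per-kind layer schedules for the whole stack."""

    sigmoid: LayerSchedule = LayerSchedule(0.007, 0.005, 70, 0.5, 0.7)
    linear: LayerSchedule = LayerSchedule(0.0002, 0.003, 80, 0.6, 0.8)

    def scaled(self, n_iterations: int) -> "PretrainSchedule":
        """Same rates with a reduced epoch count (for small fixtures)."""
        return PretrainSchedule(
            sigmoid=replace(self.sigmoid, n_iterations=n_iterations),
            linear=replace(self.linear, n_iterations=n_iterations),
        )


@dataclass
class DeepNet:
    """Deterministic feedforward network assembled from a trained RBM stack.

    ``layers`` is an ordered list of ``(W, bias, activation)`` with
    activation ``"sigmoid"`` or ``"linear"``; ``W`` maps inputs (rows) to
    units (columns).
    """

    layers: list[tuple[np.ndarray, np.ndarray, str]]
    meta: dict = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return self.layers[0][0].shape[0]

    @property
    def output_dim(self) -> int:
        return self.layers[-1][0].shape[1]

    def forward(self, X: np.ndarray, return_activations: bool = False):
        """Forward pass on ``(n, input_dim)`` data using hidden means."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected (n, {self.input_dim}) input, got {X.shape}"
            )
        activations = [X]
        a = X
        for W, bias, kind in self.layers:
            z = a @ W + bias
            a = sigmoid(z) if kind == "sigmoid" else z
            activations.append(a)
        return activations if return_activations else a

    def copy(self) -> "DeepNet":
        return DeepNet(
            layers=[(W.copy(), b.copy(), kind) for W, b, kind in self.layers],
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

def rbm_energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """Joint energy E(v, h) = -v.W.h - b.v - c.h."""
    v = np.asarray(v, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if v.shape != params.b.shape or h.shape != params.c.shape:
        raise ValueError("v/h shapes do not match the RBM parameters")
    return float(-(v @ params.W @ h) - params.b @ v - params.c @ h)


def hidden_prob(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v) = sigmoid(c_j + sum_i W_ij v_i); for linear hidden
    units this returns the Gaussian mean ``c + v W`` instead."""
    single = np.asarray(v).ndim == 1
    v2 = np.atleast_2d(np.asarray(v, dtype=np.float64))
    if v2.shape[1] != params.b.size:
        raise ValueError("v length does not match the visible layer size")
    pre = v2 @ params.W + params.c
    out = pre if params.hidden_kind == "linear" else sigmoid(pre)
    return out[0] if single else out


def visible_prob(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(v_i = 1 | h) = sigmoid(b_i + sum_j W_ij h_j)."""
    h2 = np.atleast_2d(np.asarray(h, dtype=np.float64))
    if h2.shape[1] != params.c.size:
        raise ValueError("h length does not match the hidden layer size")
    out = sigmoid(h2 @ params.W.T + params.b)
    return out[0] if np.asarray(h).ndim == 1 else out


# ---------------------------------------------------------------------------
# contrastive divergence
# ---------------------------------------------------------------------------

def _hidden_data_phase(v: np.ndarray, params: RBMParams, rng: np.random.Generator):
    """Hidden response to data: sampled binaries for Bernoulli units,
    mean + unit-variance Gaussian noise for linear units."""
    if params.hidden_kind == "linear":
        mean = v @ params.W + params.c
        return mean + rng.standard_normal(mean.shape)
    prob = sigmoid(v @ params.W + params.c)
    return (rng.random(prob.shape) < prob).astype(np.float64)


def cd_step(
    batch: np.ndarray,
    params: RBMParams,
    lr: float,
    weight_cost: float,
    momentum: float,
    velocity: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[RBMParams, dict[str, np.ndarray], float]:
    """One CD-1 update on a mini-batch (rows in [0, 1] for Bernoulli
    visibles).  Hidden units are sampled in the data phase and taken as
    means in the reconstruction phase; updates use momentum on a persistent
    velocity and L2 weight-cost on ``W``. Returns the mean squared
    reconstruction error of the batch."""
    v0 = np.asarray(batch, dtype=np.float64)
    n = v0.shape[0]
    h0 = _hidden_data_phase(v0, params, rng)
    v1 = sigmoid(h0 @ params.W.T + params.b)
    h1 = hidden_prob(v1, params)

    grad_W = (v0.T @ h0 - v1.T @ h1) / n
    grad_b = (v0 - v1).mean(axis=0)
    grad_c = (h0 - h1).mean(axis=0)

    velocity["W"] = momentum * velocity["W"] + lr * (grad_W - weight_cost * params.W)
    velocity["b"] = momentum * velocity["b"] + lr * grad_b
    velocity["c"] = momentum * velocity["c"] + lr * grad_c
    params.W += velocity["W"]
    params.b += velocity["b"]
    params.c += velocity["c"]
    for arr in (params.W, params.b, params.c):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                "non-finite RBM update; reduce the learning rate or rescale inputs"
            )
    err = float(((v0 - v1) ** 2).mean())
    return params, velocity, err


def init_rbm(
    n_visible: int,
    n_hidden: int,
    hidden_kind: str,
    rng: np.random.Generator,
    weight_scale: float = 0.01,
) -> RBMParams:
    """Small Gaussian weight init N(0, weight_scale^2), zero biases."""
    return RBMParams(
        W=rng.normal(0.0, weight_scale, size=(n_visible, n_hidden)),
        b=np.zeros(n_visible),
        c=np.zeros(n_hidden),
        hidden_kind=hidden_kind,
    )


def train_rbm(
    data: np.ndarray,
    n_hidden: int,
    hidden_kind: str,
    schedule: LayerSchedule,
    rng: np.random.Generator,
    weight_scale: float = 0.01,
) -> tuple[RBMParams, np.ndarray]:
    """Train one RBM by CD-1 over mini-batches; returns the parameters and
    the per-epoch mean reconstruction-error curve."""
    data = np.asarray(data, dtype=np.float64)
    params = init_rbm(data.shape[1], n_hidden, hidden_kind, rng, weight_scale)
    velocity = {"W": np.zeros_like(params.W), "b": np.zeros_like(params.b),
                "c": np.zeros_like(params.c)}
    n = data.shape[0]
    bs = min(schedule.batch_size, n)
    curve = np.empty(schedule.n_iterations)
    for epoch in range(1, schedule.n_iterations + 1):
        momentum = schedule.momentum_at(epoch)
        order = rng.permutation(n)
        errs = []
        for start in range(0, n - bs + 1, bs):
            batch = data[order[start:start + bs]]
            params, velocity, err = cd_step(
                batch, params, schedule.learning_rate, schedule.weight_cost,
                momentum, velocity, rng,
            )
            errs.append(err)
        curve[epoch - 1] = float(np.mean(errs))
    return params, curve


def train_rbm_stack(
    features: np.ndarray,
    widths: list[int] = (500, 500, 2500, 60),
    schedule: PretrainSchedule | None = None,
    seed: int = 0,
    weight_meaning: str = "weight_cost",
) -> DeepNet:
    """Greedy layer-wise pretraining of the full stack.

    ``features`` must already be scaled to [0, 1]. Layer 1 is trained on the
    features, each later layer on the previous layer's hidden means; all but
    the last layer are Bernoulli, the last is linear. Returns the
    deterministic feedforward net. ``weight_meaning`` selects how the
    published per-layer "weight" constant is applied: as an L2 weight-cost
    (default) or as the initial weight scale.
    """
    if schedule is None:
        schedule = PretrainSchedule()
    features = np.asarray(features, dtype=np.float64)
    if features.min() < -1e-9 or features.max() > 1 + 1e-9:
        raise ValueError("features must be min-max scaled to [0, 1]")
    if len(widths) < 1:
        raise ValueError("need at least one layer width")
    rng = np.random.default_rng(seed)
    layers = []
    data = features
    curves = []
    for li, width in enumerate(widths):
        is_top = li == len(widths) - 1
        kind = "linear" if is_top else "bernoulli"
        layer_sched = schedule.linear if is_top else schedule.sigmoid
        if weight_meaning == "weight_cost":
            wc, scale = layer_sched.weight_cost, 0.01
        elif weight_meaning == "init_scale":
            wc, scale = 0.0, layer_sched.weight_cost
        else:
            raise ValueError(f"unknown weight_meaning {weight_meaning!r}")
        sched = replace(layer_sched, weight_cost=wc)
        params, curve = train_rbm(data, width, kind, sched, rng, weight_scale=scale)
        curves.append(curve)
        layers.append((params.W.copy(), params.c.copy(),
                       "linear" if is_top else "sigmoid"))
        data = hidden_prob(data, params)
        if kind == "bernoulli":
            data = np.asarray(data, dtype=np.float64)
    return DeepNet(layers=layers, meta={
        "widths": list(widths),
        "seed": seed,
        "reconstruction_curves": [c.tolist() for c in curves],
    })
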