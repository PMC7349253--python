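"""Parametric t-SNE fine-tuning of the pretrained deep network.

The pretrained stack maps multi-view features X to a d-dimensional latent
code Y = f(X | W).  Fine-tuning matches, per mini-batch, the
perplexity-calibrated Gaussian joint probabilities P of the inputs to the
Student-t joint probabilities Q of the latent codes,

    q_ij = (1 + ||y_i - y_j||^2 / alpha)^(-(alpha+1)/2) / Z,

minimising C = KL(P || Q) by conjugate-gradient backpropagation through
the network.  The heavy-tailed Student-t kernel in latent space is what
counteracts the crowding problem of plain SNE.

The latent gradient implemented here is the exact derivative of KL(P||Q)
of the kernel above,

    dC/dy_i = (2a+2)/a * sum_j (p_ij - q_ij) (y_i - y_j)
              * (1 + ||y_i - y_j||^2 / a)^(-1),

which reduces to the familiar 4*sum (p-q)(y_i-y_j)/(1+d^2) at alpha = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as spo
from scipy.spatial.distance import squareform, pdist

from .rbm import DeepNet, sigmoid

__all__ = [
    "TSNEConfig",
    "PairwiseDistribution",
    "calibrate_sigmas",
    "joint_p",
    "joint_q",
    "kl_cost",
    "latent_gradient",
    "cost_gradient",
    "finetune",
    "embed",
]

_EPS = 1e-12  # floor on probabilities inside logs and ratios


@dataclass(frozen=True)
class TSNEConfig:
    """Fine-tuning hyperparameters.

    alpha is the Student-t degrees of freedom (default 32), d the latent
    dimension (default 60), perplexity the target effective neighbour count
    (default 25).  Data is split once into fixed batches of ``batch_size``;
    each of the ``n_iterations`` epochs runs ``cg_steps_per_batch``
    conjugate-gradient steps on every batch.
    """

    alpha: float = 32.0
    d: int = 60
    perplexity: float = 25.0
    batch_size: int = 100
    n_iterations: int = 50
    cg_steps_per_batch: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 1 < self.perplexity < self.batch_size:
            raise ValueError("perplexity must satisfy 1 < perplexity < batch_size")
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass
class PairwiseDistribution:
    """Symmetric joint-probability matrix with zero diagonal, summing to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.values, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("pairwise distribution must be square")
        if np.any(P < 0) or np.any(np.diag(P) != 0):
            raise ValueError("probabilities must be >= 0 with a zero diagonal")
        if abs(P.sum() - 1.0) > 1e-9:
            raise ValueError("joint probabilities must sum to 1")
        if np.max(np.abs(P - P.T)) > 1e-12:
            raise ValueError("joint probabilities must be symmetric")
        self.values = P


# ---------------------------------------------------------------------------
# high-dimensional side: perplexity-calibrated Gaussian conditionals
# ---------------------------------------------------------------------------

def _row_entropy(p_row: np.ndarray) -> float:
    """Shannon entropy (bits) of one conditional row."""
    p = p_row[p_row > 0]
    return float(-(p * np.log2(p)).sum())


def calibrate_sigmas(
    X_batch: np.ndarray,
    perplexity: float = 25.0,
    tol: float = 1e-5,
    max_bisect: int = 50,
    sigma_bounds: tuple[float, float] = (1e-20, 1e20),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point Gaussian bandwidth calibration.

    For each point i, bisection (in log sigma over ``sigma_bounds``) finds
    sigma_i such that the conditional P_i over j != i has
    ``2**H(P_i) == perplexity`` within ``tol``.  Returns ``(sigmas,
    conditionals)`` with each conditional row summing to 1.  If the target
    is unreachable (e.g. mutually equidistant points, where perplexity is
    pinned at B-1) a warning is issued and the closest sigma kept.
    """
    X = np.asarray(X_batch, dtype=np.float64)
    B = X.shape[0]
    if B < 2:
        raise ValueError("need at least 2 points to calibrate")
    D2 = squareform(pdist(X, "sqeuclidean"))
    sigmas = np.empty(B)
    cond = np.zeros((B, B))
    log_lo0, log_hi0 = np.log(sigma_bounds[0]), np.log(sigma_bounds[1])
    target = np.log2(perplexity)

    for i in range(B):
        d2 = np.delete(D2[i], i)

        def row_for(log_sigma: float) -> np.ndarray:
            e = -d2 / (2.0 * np.exp(2.0 * log_sigma))
            e -= e.max()
            p = np.exp(e)
            return p / p.sum()

        lo, hi = log_lo0, log_hi0
        best_ls, best_gap = None, np.inf
        for _ in range(max_bisect):
            mid = 0.5 * (lo + hi)
            h = _row_entropy(row_for(mid))
            gap = 2.0**h - perplexity
            if abs(gap) < best_gap:
                best_gap, best_ls = abs(gap), mid
            if abs(gap) < tol:
                break
            if h > target:  # too many neighbours -> shrink sigma
                hi = mid
            else:
                lo = mid
        else:
            if best_gap >= tol:
                warnings.warn(
                    f"perplexity calibration did not converge for point {i} "
                    f"(closest gap {best_gap:.3g})", RuntimeWarning, stacklevel=2)
            mid = best_ls
        sigmas[i] = np.exp(mid)
        row = row_for(mid)
        cond[i, np.arange(B) != i] = row
    return sigmas, cond


def joint_p(conditionals: np.ndarray) -> PairwiseDistribution:
    """Symmetrise row-normalised conditionals: p_ij = (p_j|i + p_i|j) / 2B."""
    C = np.asarray(conditionals, dtype=np.float64)
    B = C.shape[0]
    P = (C + C.T) / (2.0 * B)
    np.fill_diagonal(P, 0.0)
    return PairwiseDistribution(P)


# ---------------------------------------------------------------------------
# latent side: Student-t joints, cost and gradient
# ---------------------------------------------------------------------------

def _t_kernel(Y: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised Student-t kernel W and its base (1 + d^2/alpha)."""
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite latent coordinates")
    D2 = squareform(pdist(np.asarray(Y, dtype=np.float64), "sqeuclidean"))
    base = 1.0 + D2 / alpha
    W = base ** (-(alpha + 1.0) / 2.0)
    np.fill_diagonal(W, 0.0)
    return W, base


def joint_q(Y_batch: np.ndarray, alpha: float) -> PairwiseDistribution:
    """Latent joint probabilities q_ij of the Student-t kernel."""
    W, _ = _t_kernel(Y_batch, alpha)
    return PairwiseDistribution(W / W.sum())


def kl_cost(P: PairwiseDistribution, Q: PairwiseDistribution) -> float:
    """C = KL(P || Q) = sum_{i != j} p_ij log(p_ij / q_ij), with zero-p
    terms contributing 0 and q floored at 1e-12."""
    p = P.values
    q = np.maximum(Q.values, _EPS)
    if p.shape != q.shape:
        raise ValueError("P and Q shapes differ")
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / q[mask])).sum())


def latent_gradient(P: PairwiseDistribution, Y: np.ndarray, alpha: float) -> np.ndarray:
    """Exact dC/dY for C = KL(P||Q) with the Student-t latent kernel."""
    Y = np.asarray(Y, dtype=np.float64)
    W, base = _t_kernel(Y, alpha)
    Q = W / W.sum()
    M = (P.values - Q) / base
    np.fill_diagonal(M, 0.0)
    coef = (2.0 * alpha + 2.0) / alpha
    return coef * (M.sum(axis=1)[:, None] * Y - M @ Y)


def _net_backprop(
    net: DeepNet, activations: list[np.ndarray], grad_out: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Chain dC/d(output) back through sigmoid/linear layers; returns
    per-layer (dC/dW, dC/dbias)."""
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(net.layers)
    delta = grad_out
    for li in range(len(net.layers) - 1, -1, -1):
        W, _, kind = net.layers[li]
        if kind == "sigmoid":
            a = activations[li + 1]
            delta = delta * a * (1.0 - a)
        grads[li] = (activations[li].T @ delta, delta.sum(axis=0))
        if li > 0:
            delta = delta @ W.T
    return grads


def cost_gradient(
    P: PairwiseDistribution,
    X_batch: np.ndarray,
    net: DeepNet,
    alpha: float,
) -> tuple[float, list[tuple[np.ndarray, np.ndarray]]]:
    """KL cost of the batch and its gradient w.r.t. every weight and bias,
    obtained by backpropagating the latent gradient through the network."""
    activations = net.forward(X_batch, return_activations=True)
    Y = activations[-1]
    grad_y = latent_gradient(P, Y, alpha)
    if not np.all(np.isfinite(grad_y)):
        raise FloatingPointError("non-finite latent gradient")
    cost = kl_cost(P, joint_q(Y, alpha))
    return cost, _net_backprop(net, activations, grad_y)


# ---------------------------------------------------------------------------
# conjugate-gradient fine-tuning
# ---------------------------------------------------------------------------

def _flatten(net: DeepNet) -> np.ndarray:
    return np.concatenate([np.r_[W.ravel(), b] for W, b, _ in net.layers])


def _unflatten(theta: np.ndarray, net: DeepNet) -> None:
    """Write a flat parameter vector back into ``net`` (in place)."""
    pos = 0
    for li, (W, b, kind) in enumerate(net.layers):
        nw, nb = W.size, b.size
        net.layers[li] = (
            theta[pos:pos + nw].reshape(W.shape).copy(),
            theta[pos + nw:pos + nw + nb].copy(),
            kind,
        )
        pos += nw + nb


def _batch_objective(theta, net, X, P, alpha):
    _unflatten(theta, net)
    cost, grads = cost_gradient(P, X, net, alpha)
    flat_grad = np.concatenate([np.r_[gW.ravel(), gb] for gW, gb in grads])
    return cost, flat_grad


def finetune(
    net: DeepNet,
    features: np.ndarray,
    cfg: TSNEConfig,
) -> tuple[DeepNet, list[dict]]:
    """Fine-tune a pretrained net by batched conjugate-gradient descent on
    KL(P||Q).

    Trials are shuffled once by ``cfg.seed`` into fixed batches of
    ``cfg.batch_size`` (a trailing partial batch is dropped); P is
    calibrated once per batch, then every epoch runs
    ``cfg.cg_steps_per_batch`` Polak-Ribiere conjugate-gradient steps per
    batch.  Returns the tuned net and a cost trace of dicts with keys
    ``iteration``, ``batch``, ``kl``.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.shape[1] != net.input_dim:
        raise ValueError("feature dimension does not match the net input")
    out = net.copy()
    if cfg.n_iterations == 0:
        return out, []
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(X.shape[0])
    n_batches = X.shape[0] // cfg.batch_size
    if n_batches == 0:
        raise ValueError(
            f"need at least one full batch of {cfg.batch_size} "
            f"(perplexity {cfg.perplexity} requires batch > perplexity)"
        )
    batches = [order[k * cfg.batch_size:(k + 1) * cfg.batch_size]
               for k in range(n_batches)]
    # P depends only on the inputs, so calibrate once per fixed batch
    Ps = []
    for idx in batches:
        _, cond = calibrate_sigmas(X[idx], cfg.perplexity)
        Ps.append(joint_p(cond))

    trace: list[dict] = []
    for it in range(1, cfg.n_iterations + 1):
        for bi, idx in enumerate(batches):
            theta0 = _flatten(out)
            res = spo.minimize(
                _batch_objective, theta0, args=(out, X[idx], Ps[bi], cfg.alpha),
                jac=True, method="CG",
                options={"maxiter": cfg.cg_steps_per_batch, "gtol": 0.0},
            )
            _unflatten(res.x, out)
            trace.append({"iteration": it, "batch": bi, "kl": float(res.fun)})
    out.meta = dict(out.meta)
    out.meta["finetune"] = {
        "alpha": cfg.alpha, "perplexity": cfg.perplexity,
        "n_iterations": cfg.n_iterations, "batch_size": cfg.batch_size,
        "seed": cfg.seed,
    }
    return out, trace


def embed(net: DeepNet, features: np.ndarray) -> np.ndarray:
    """Deterministic latent embedding: a plain forward pass, no sampling."""
    return net.forward(np.asarray(features, dtype=np.float64))
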