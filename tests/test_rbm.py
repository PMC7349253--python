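"""RBM energy model, conditionals, contrastive divergence and stack training."""

import itertools

import numpy as np
import pytest

from mveeg.rbm import (
    DeepNet,
    LayerSchedule,
    PretrainSchedule,
    RBMParams,
    cd_step,
    hidden_prob,
    init_rbm,
    rbm_energy,
    train_rbm,
    train_rbm_stack,
    visible_prob,
)


def random_params(rng, nv=3, nh=2, kind="bernoulli"):
    return RBMParams(W=rng.normal(0, 1, (nv, nh)), b=rng.normal(0, 1, nv),
                     c=rng.normal(0, 1, nh), hidden_kind=kind)


def patterns_fixture(seed=0, n=64, nv=8):
    """Noisy copies of four binary prototypes (the CD training fixture)."""
    rng = np.random.default_rng(seed)
    protos = (rng.random((4, nv)) < 0.5).astype(float)
    data = np.repeat(protos, n // 4, axis=0)
    flips = rng.random(data.shape) < 0.05
    return np.abs(data - flips)


# -------------------------------------------------------------------- energy

def test_energy_direct_cases():
    p = RBMParams(W=[[2.0]], b=[1.0], c=[1.0])
    assert rbm_energy(np.array([0.0]), np.array([0.0]), p) == 0.0
    assert rbm_energy(np.array([1.0]), np.array([1.0]), p) == -4.0


def test_energy_matches_double_loop_oracle(rng):
    p = random_params(rng, 4, 3)
    v, h = rng.random(4), rng.random(3)
    expected = (-sum(p.W[i, j] * v[i] * h[j] for i in range(4) for j in range(3))
                - sum(p.b[i] * v[i] for i in range(4))
                - sum(p.c[j] * h[j] for j in range(3)))
    assert abs(rbm_energy(v, h, p) - expected) < 1e-12


# -------------------------------------------------------------- conditionals

def test_conditionals_zero_params_are_half():
    p = RBMParams(W=np.zeros((3, 2)), b=np.zeros(3), c=np.zeros(2))
    assert np.allclose(hidden_prob(np.ones(3), p), 0.5)
    assert np.allclose(visible_prob(np.ones(2), p), 0.5)


def test_conditionals_scalar_values_and_symmetry(rng):
    p = RBMParams(W=[[1.0]], b=[0.0], c=[0.0])
    assert np.isclose(hidden_prob(np.array([1.0]), p)[()], 0.7310585786, atol=1e-9)
    assert np.isclose(visible_prob(np.array([1.0]), p)[()], 0.7310585786, atol=1e-9)
    # swapping roles (W^T, b <-> c) exchanges the two conditionals
    q = random_params(rng, 4, 3)
    swapped = RBMParams(W=q.W.T.copy(), b=q.c.copy(), c=q.b.copy())
    h = rng.random(3)
    assert np.allclose(visible_prob(h, q), hidden_prob(h, swapped), atol=1e-12)


def test_hidden_prob_monotone_in_bias():
    probs = [hidden_prob(np.array([1.0]),
                         RBMParams(W=[[1.0]], b=[0.0], c=[cj]))[()]
             for cj in (-1.0, -10.0, -100.0)]
    assert probs[0] > probs[1] > probs[2] >= 0.0


def test_conditionals_match_boltzmann_enumeration(rng):
    """Eq-4/5 sigmoids equal exact Boltzmann conditionals from the energy on
    an enumerable 3-visible / 2-hidden RBM."""
    p = random_params(rng, 3, 2)
    v = np.array([1.0, 0.0, 1.0])
    weights = {h: np.exp(-rbm_energy(v, np.array(h, dtype=float), p))
               for h in itertools.product((0, 1), repeat=2)}
    Z = sum(weights.values())
    for j in range(2):
        marginal = sum(w for h, w in weights.items() if h[j] == 1) / Z
        assert abs(marginal - hidden_prob(v, p)[j]) < 1e-10
    h = np.array([1.0, 0.0])
    weights = {v_: np.exp(-rbm_energy(np.array(v_, dtype=float), h, p))
               for v_ in itertools.product((0, 1), repeat=3)}
    Z = sum(weights.values())
    for i in range(3):
        marginal = sum(w for v_, w in weights.items() if v_[i] == 1) / Z
        assert abs(marginal - visible_prob(h, p)[i]) < 1e-10


# ------------------------------------------------------------------------ CD

def test_cd_step_zero_lr_only_decays_velocity(rng):
    p = random_params(rng, 4, 3)
    W0 = p.W.copy()
    vel = {"W": np.ones_like(p.W), "b": np.ones_like(p.b), "c": np.ones_like(p.c)}
    with pytest.raises(ValueError):
        LayerSchedule(0.0, 0.0, 1, 0.5, 0.5)  # zero lr is a config error
    # emulate lr -> 0 via a tiny rate on a frozen copy
    _, vel_out, _ = cd_step(rng.random((8, 4)), p, 0.0, 0.005, 0.5, vel,
                            np.random.default_rng(0))
    assert np.allclose(p.W, W0 + vel_out["W"])
    assert np.allclose(vel_out["W"], 0.5)  # momentum-decayed only


def test_cd_statistics_match_per_sample_loop(rng):
    """Batched positive/negative statistics equal a naive per-sample loop."""
    from mveeg.rbm import _hidden_data_phase, sigmoid

    p = random_params(rng, 5, 3)
    batch = (rng.random((6, 5)) < 0.5).astype(float)
    h0 = _hidden_data_phase(batch, p, np.random.default_rng(9))
    v1 = sigmoid(h0 @ p.W.T + p.b)
    h1 = hidden_prob(v1, p)
    pos = batch.T @ h0
    neg = v1.T @ h1
    pos_loop = np.zeros_like(pos)
    neg_loop = np.zeros_like(neg)
    for n in range(6):
        pos_loop += np.outer(batch[n], h0[n])
        neg_loop += np.outer(v1[n], h1[n])
    assert np.abs(pos - pos_loop).max() < 1e-10
    assert np.abs(neg - neg_loop).max() < 1e-10


def test_cd_training_reduces_reconstruction_error():
    """70 epochs of CD-1 with the sigmoid-layer schedule on the 64-pattern
    fixture end below the first epoch; weights stay bounded."""
    data = patterns_fixture()
    sched = LayerSchedule(0.007, 0.005, 70, 0.5, 0.7, batch_size=16)
    params, curve = train_rbm(data, 4, "bernoulli", sched,
                              np.random.default_rng(3))
    assert curve[-1] < curve[0]
    assert np.isfinite(params.W).all()
    assert np.linalg.norm(params.W) < 100.0


def test_cd_improves_exact_log_likelihood():
    """On an exhaustively enumerable 4x3 RBM, CD-1 at a small rate raises the
    brute-force training log-likelihood over 200 epochs."""
    rng = np.random.default_rng(2)
    data = (rng.random((32, 4)) < np.array([0.9, 0.1, 0.8, 0.2])).astype(float)

    def exact_loglik(p):
        vs = np.array(list(itertools.product((0, 1), repeat=4)), dtype=float)
        hs = np.array(list(itertools.product((0, 1), repeat=3)), dtype=float)
        energies = np.array([[rbm_energy(v, h, p) for h in hs] for v in vs])
        joint = np.exp(-energies)
        pv = joint.sum(axis=1) / joint.sum()
        idx = (data @ (2 ** np.arange(4)[::-1])).astype(int)
        lut = {int(v @ (2 ** np.arange(4)[::-1])): i for i, v in enumerate(vs)}
        return float(np.log([pv[lut[i]] for i in idx]).sum())

    params = init_rbm(4, 3, "bernoulli", rng)
    before = exact_loglik(params)
    vel = {"W": np.zeros_like(params.W), "b": np.zeros_like(params.b),
           "c": np.zeros_like(params.c)}
    for _ in range(200):
        params, vel, _ = cd_step(data, params, 0.05, 0.0, 0.0, vel, rng)
    assert exact_loglik(params) > before


# --------------------------------------------------------------------- stack

def test_stack_shapes_and_determinism():
    rng = np.random.default_rng(5)
    X = rng.random((40, 12))
    sched = PretrainSchedule().scaled(3)
    net1 = train_rbm_stack(X, widths=[8, 8, 16, 3], schedule=sched, seed=7)
    net2 = train_rbm_stack(X, widths=[8, 8, 16, 3], schedule=sched, seed=7)
    out = net1.forward(X)
    assert out.shape == (40, 3)
    for (W1, b1, k1), (W2, b2, k2) in zip(net1.layers, net2.layers):
        assert np.array_equal(W1, W2) and np.array_equal(b1, b2) and k1 == k2
    assert [k for _, _, k in net1.layers] == ["sigmoid"] * 3 + ["linear"]


def test_stack_rejects_unscaled_features():
    with pytest.raises(ValueError):
        train_rbm_stack(np.random.default_rng(0).normal(0, 5, (10, 4)),
                        widths=[4, 2], schedule=PretrainSchedule().scaled(1))


def test_pretraining_improves_class_separation():
    """On separable two-class features, the latent d=2 pretraining output
    clusters classes better than the raw input (silhouette score)."""
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(7)
    a = np.clip(rng.normal(0.25, 0.06, (100, 20)), 0, 1)
    b = np.clip(rng.normal(0.75, 0.06, (100, 20)), 0, 1)
    X = np.vstack([a, b])
    y = np.r_[np.zeros(100), np.ones(100)]
    net = train_rbm_stack(X, widths=[16, 16, 32, 2],
                          schedule=PretrainSchedule().scaled(30), seed=1)
    assert silhouette_score(net.forward(X), y) > silhouette_score(X, y)


def test_weight_cost_interpretation_switch():
    X = np.random.default_rng(0).random((20, 6))
    net = train_rbm_stack(X, widths=[4, 2], schedule=PretrainSchedule().scaled(2),
                          seed=0, weight_meaning="init_scale")
    assert net.output_dim == 2
    with pytest.raises(ValueError):
        train_rbm_stack(X, widths=[4, 2], schedule=PretrainSchedule().scaled(1),
                        weight_meaning="bogus")
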