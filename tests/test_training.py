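"""Loss exactness, masking laws, and the training loop contract."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from mmdx.autodiff import Tensor
from mmdx.backbone import ModelConfig
from mmdx.schema import UNKNOWN
from mmdx.synthdata import SyntheticConfig, simulate_cohort
from mmdx.training import (Checkpoint, LossConfig, TrainConfig, compute_alpha,
                           focal_loss, label_loss_mask, l2_penalty, predict,
                           ranking_loss, sample_feature_mask, total_loss,
                           train_model)

N_LABELS = 13


def focal_brute(p, y, m, alpha, gamma):
    """Direct double-sum evaluation of the focal loss equation."""
    n = p.shape[0]
    tot = 0.0
    for k in range(n):
        for i in range(N_LABELS):
            if not m[k, i]:
                continue
            if y[k, i] == 1:
                tot += -alpha[i] * (1 - p[k, i]) ** gamma * math.log(p[k, i])
            else:
                tot += -(1 - alpha[i]) * p[k, i] ** gamma * math.log(1 - p[k, i])
    return tot / n


def ranking_brute(p, y, m, eps):
    """Direct triple-sum evaluation of the pairwise hinge equation."""
    n = p.shape[0]
    tot = 0.0
    for k in range(n):
        for i in range(N_LABELS):
            for j in range(i + 1, N_LABELS):
                if m[k, i] and m[k, j]:
                    tot += max(0.0, (p[k, i] - p[k, j]) * (y[k, j] - y[k, i]) + eps)
    return tot / n


def _single_label_instance(y, p, mask_label=0):
    labels = np.full((1, N_LABELS), UNKNOWN)
    labels[0, mask_label] = y
    probs = np.full((1, N_LABELS), p)
    return probs, labels, label_loss_mask(labels)


def test_compute_alpha_from_stated_formula():
    labels = np.array([[1], [1], [0], [0], [UNKNOWN]]) @ np.ones((1, N_LABELS), dtype=int)
    labels = labels.astype(int)
    a = compute_alpha(labels)
    assert np.allclose(a, 0.25)  # f = 0.5 -> (1 - 0.5)^2
    all_neg = np.zeros((4, N_LABELS), dtype=int)
    assert np.allclose(compute_alpha(all_neg), 1.0)  # f = 0 -> 1
    empty = np.full((3, N_LABELS), UNKNOWN)
    with pytest.raises(ValueError):
        compute_alpha(empty)


def test_focal_loss_hand_oracle():
    cfg = LossConfig(alpha=[0.75] * N_LABELS, gamma=2.0)
    probs, labels, m = _single_label_instance(1, 0.5)
    expected = 0.75 * 0.25 * (-math.log(0.5))  # 0.129953...
    assert focal_loss(probs, labels, m, cfg) == pytest.approx(expected, abs=1e-12)
    cfg2 = LossConfig(alpha=[0.25] * N_LABELS, gamma=2.0)
    probs, labels, m = _single_label_instance(0, 0.5)
    expected = (1 - 0.25) * 0.25 * (-math.log(0.5))
    assert focal_loss(probs, labels, m, cfg2) == pytest.approx(expected, abs=1e-12)


def test_focal_loss_perfect_prediction_vanishes():
    cfg = LossConfig(alpha=[0.5] * N_LABELS)
    labels = np.ones((2, N_LABELS), dtype=int)
    probs = np.full((2, N_LABELS), 1.0 - 1e-9)
    assert focal_loss(probs, labels, label_loss_mask(labels), cfg) < 1e-12


def test_ranking_loss_hand_oracle():
    cfg = LossConfig(epsilon=0.25)
    labels = np.full((1, N_LABELS), UNKNOWN)
    labels[0, 0], labels[0, 1] = 1, 0
    probs = np.full((1, N_LABELS), 0.5)
    probs[0, 0], probs[0, 1] = 0.9, 0.2  # margin satisfied
    assert ranking_loss(probs, labels, label_loss_mask(labels), cfg) == pytest.approx(0.0)
    probs[0, 0], probs[0, 1] = 0.3, 0.4  # violated: 0.1 + 0.25
    assert ranking_loss(probs, labels, label_loss_mask(labels), cfg) == pytest.approx(0.35)
    labels[0, 1] = 1  # equal-label pair contributes exactly epsilon
    assert ranking_loss(probs, labels, label_loss_mask(labels), cfg) == pytest.approx(0.25)


def test_losses_match_brute_force_on_random_instances():
    rng = np.random.default_rng(12)
    cfg = LossConfig(alpha=rng.uniform(0, 1, N_LABELS).tolist())
    for _ in range(50):
        n = int(rng.integers(1, 6))
        p = rng.uniform(0.01, 0.99, size=(n, N_LABELS))
        y = rng.integers(0, 2, size=(n, N_LABELS))
        y[rng.random((n, N_LABELS)) < 0.3] = UNKNOWN
        m = label_loss_mask(y)
        assert focal_loss(p, y, m, cfg) == pytest.approx(
            focal_brute(p, y, m, cfg.alpha, cfg.gamma), abs=1e-8)
        assert ranking_loss(p, y, m, cfg) == pytest.approx(
            ranking_brute(p, y, m, cfg.epsilon), abs=1e-8)


def test_total_loss_is_component_sum():
    rng = np.random.default_rng(3)
    cfg = LossConfig(alpha=[0.5] * N_LABELS)
    p = rng.uniform(0.05, 0.95, size=(4, N_LABELS))
    y = rng.integers(0, 2, size=(4, N_LABELS))
    m = label_loss_mask(y)
    w = {"layer.weight": Tensor(rng.normal(size=(3, 3)), requires_grad=True),
         "layer.bias": Tensor(rng.normal(size=3), requires_grad=True),
         "norm.gain": Tensor(rng.normal(size=3), requires_grad=True)}
    got = total_loss(p, y, m, w, cfg)
    # biases and norm parameters are excluded from the L2 scope
    expected = (focal_loss(p, y, m, cfg) + cfg.lam * ranking_loss(p, y, m, cfg)
                + cfg.beta * float((w["layer.weight"].data ** 2).sum()))
    assert got == pytest.approx(expected, abs=1e-8)
    cfg0 = LossConfig(alpha=[0.5] * N_LABELS, lam=0.0, beta=0.0)
    assert total_loss(p, y, m, w, cfg0) == pytest.approx(focal_loss(p, y, m, cfg0))


def test_masked_label_terms_carry_no_gradient():
    """Finite differences: perturbing a masked entry's logit leaves the loss
    unchanged; unmasked entries do move it."""
    rng = np.random.default_rng(7)
    cfg = LossConfig(alpha=[0.5] * N_LABELS)
    logits = rng.normal(size=(3, N_LABELS))
    y = rng.integers(0, 2, size=(3, N_LABELS))
    y[rng.random((3, N_LABELS)) < 0.4] = UNKNOWN
    m = label_loss_mask(y)

    def loss_at(z):
        t = Tensor(z, requires_grad=True)
        return total_loss(t.sigmoid(), y, m, None, cfg).item()

    base = loss_at(logits)
    eps = 1e-4
    for k in range(3):
        for i in range(N_LABELS):
            z = logits.copy()
            z[k, i] += eps
            delta = loss_at(z) - base
            if not m[k, i]:
                assert delta == 0.0
    # autodiff agrees: gradient exactly zero at masked positions
    t = Tensor(logits, requires_grad=True)
    total_loss(t.sigmoid(), y, m, None, cfg).backward()
    assert np.all(t.grad[~m] == 0.0)
    assert np.any(t.grad[m] != 0.0)


def test_equal_label_pairs_are_gradient_free():
    rng = np.random.default_rng(8)
    cfg = LossConfig(alpha=[0.5] * N_LABELS)
    logits = rng.normal(size=(2, N_LABELS))
    y = np.ones((2, N_LABELS), dtype=int)  # all pairs equal-label
    m = label_loss_mask(y)
    t = Tensor(logits, requires_grad=True)
    rl = ranking_loss(t.sigmoid(), y, m, cfg)
    # value is the constant: (13 choose 2) pairs * epsilon * 2 rows / N=2
    assert rl.item() == pytest.approx(78 * cfg.epsilon)
    rl.backward()
    assert np.all(t.grad == 0.0)


def test_feature_mask_sampler_laws():
    rng = np.random.default_rng(9)
    assert sample_feature_mask(["only"], rng) == set()
    with pytest.raises(ValueError):
        sample_feature_mask([], rng)
    # kept-count uniform on {1..4}: chi-squared goodness of fit
    s = ["a", "b", "c", "d"]
    kept = np.array([4 - len(sample_feature_mask(s, rng)) for _ in range(20000)])
    counts = np.bincount(kept, minlength=5)[1:]
    chi2 = ((counts - 5000.0) ** 2 / 5000.0).sum()
    assert sps.chi2.sf(chi2, df=3) > 0.001
    # masked features are always a subset of the observed set
    for _ in range(100):
        drop = sample_feature_mask(s, rng)
        assert drop <= set(s)


@pytest.fixture(scope="module")
def tiny_training_run():
    cfg = SyntheticConfig(n_subjects=160, seed=21)
    coh = simulate_cohort(cfg)
    mc = ModelConfig(d_model=16, n_layers=1, n_heads=2, dropout_rate=0.1)
    lc = LossConfig(batch_size=32)
    tc = TrainConfig(epochs=5, first_restart=5, seed=5)
    ckpt = train_model(coh.records[:120], coh.records[120:], coh.catalog, mc, lc, tc)
    return coh, mc, lc, tc, ckpt


def test_training_descends_on_separable_cohort(tiny_training_run):
    _, _, _, _, ckpt = tiny_training_run
    losses = [e["train_loss"] for e in ckpt.log]
    assert losses[-1] < losses[0]


def test_training_is_reproducible(tiny_training_run):
    coh, mc, lc, tc, ckpt = tiny_training_run
    again = train_model(coh.records[:120], coh.records[120:], coh.catalog, mc, lc, tc)
    assert [e["train_loss"] for e in again.log] == [e["train_loss"] for e in ckpt.log]
    assert [e["val_score"] for e in again.log] == [e["val_score"] for e in ckpt.log]


def test_epoch_best_selection_is_argmax(tiny_training_run):
    _, _, _, _, ckpt = tiny_training_run
    vals = [e["val_score"] for e in ckpt.log]
    assert ckpt.best_epoch == int(np.argmax(vals))


def test_checkpoint_round_trip(tmp_path, tiny_training_run):
    coh, _, _, _, ckpt = tiny_training_run
    path = tmp_path / "model.npz"
    ckpt.save(path)
    back = Checkpoint.load(path)
    test_recs = coh.records[:10]
    assert np.array_equal(predict(ckpt, test_recs).logits,
                          predict(back, test_recs).logits)
    assert back.catalog.names == ckpt.catalog.names
    assert back.best_epoch == ckpt.best_epoch


def test_disjoint_split_enforced(tiny_training_run):
    coh, mc, lc, tc, _ = tiny_training_run
    with pytest.raises(ValueError, match="disjoint"):
        train_model(coh.records[:50], coh.records[:10], coh.catalog, mc, lc, tc)


def test_cosine_warm_restart_schedule():
    from mmdx.optim import CosineWarmRestarts

    s = CosineWarmRestarts(1.0, first_restart=64, period_multiplier=2)
    assert s.lr_at(0) == pytest.approx(1.0)
    assert s.lr_at(32) == pytest.approx(0.5)
    assert s.lr_at(64) == pytest.approx(1.0)   # first restart
    assert s.lr_at(128) == pytest.approx(0.5)  # halfway through the doubled period
    assert s.lr_at(192) == pytest.approx(1.0)  # second restart at 64 + 128
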