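"""Dual-stream segmentation and the distance-aware CPS loss algebra."""

import numpy as np
import pytest

from facps import dacps
from facps.alignment import build_nets
from facps.dacps import (cross_entropy_loss, dacps_loss, dual_predict,
                         ensemble_average, kl_map, kl_pseudo_distance, one_hot,
                         pseudo_label, soft_dice_loss, supervised_dice_loss)
from facps.nn import Tensor

LOG2 = float(np.log(2.0))


def random_probmap(rng, shape=(2, 4, 6, 6)):
    p = rng.uniform(0.05, 1.0, size=shape).astype(np.float32)
    return Tensor(p / p.sum(axis=1, keepdims=True))


# -- dual prediction ---------------------------------------------------------

@pytest.fixture(scope="module")
def nets():
    return build_nets(feat_channels=8, n_classes=3, seed=0)


def test_dual_predict_probability_contracts(nets, rng):
    x = Tensor(rng.uniform(-1, 1, size=(2, 1, 32, 32)).astype(np.float32))
    xt = Tensor(rng.uniform(-1, 1, size=(2, 1, 32, 32)).astype(np.float32))
    maps = dual_predict(nets, x, xt)
    for p in maps:
        total = p.data.sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-5)
        assert p.data.min() >= 0.0


def test_dual_predict_identity_cases(nets, rng):
    x = Tensor(rng.uniform(-1, 1, size=(1, 1, 32, 32)).astype(np.float32))
    p_o1, p_c1, p_o2, p_c2 = dual_predict(nets, x, x)
    assert np.array_equal(p_o1.data, p_c1.data)       # same input, same stream
    assert not np.array_equal(p_o1.data, p_o2.data)   # different init

    # with theta1 = theta2 forced equal the streams coincide exactly
    nets2 = build_nets(feat_channels=8, n_classes=3, seed=3)
    nets2.seg2.load_state_dict(nets2.seg1.state_dict())
    q_o1, _, q_o2, _ = dual_predict(nets2, x, x)
    assert np.array_equal(q_o1.data, q_o2.data)


def test_dual_predict_rejects_shared_registry(nets, rng):
    class FakeBundle:
        encoder, seg1 = nets.encoder, nets.seg1
        seg2 = nets.seg1
    x = Tensor(rng.uniform(-1, 1, size=(1, 1, 32, 32)).astype(np.float32))
    with pytest.raises(ValueError, match="share"):
        dual_predict(FakeBundle, x, x)


# -- ensemble ----------------------------------------------------------------

def test_ensemble_average_properties(rng):
    p = random_probmap(rng)
    assert np.array_equal(ensemble_average(p, p).data, p.data)
    a = Tensor(np.array([[[[1.0]], [[0.0]]]], dtype=np.float32))
    b = Tensor(np.array([[[[0.0]], [[1.0]]]], dtype=np.float32))
    np.testing.assert_allclose(ensemble_average(a, b).data.ravel(), [0.5, 0.5])
    q = random_probmap(rng)
    np.testing.assert_allclose(ensemble_average(p, q).data.sum(axis=1), 1.0,
                               atol=1e-5)
    with pytest.raises(ValueError, match="shape"):
        ensemble_average(p, Tensor(np.zeros((1, 2, 3, 3), dtype=np.float32)))


# -- KL pseudo-distance ------------------------------------------------------

def test_kl_zero_on_identical_maps(rng):
    p = random_probmap(rng)
    assert kl_pseudo_distance(p, p).item() == pytest.approx(0.0, abs=1e-7)


def test_kl_single_pixel_closed_form():
    pc = Tensor(np.array([1.0, 0.0], dtype=np.float32).reshape(1, 2, 1, 1))
    po = Tensor(np.array([0.5, 0.5], dtype=np.float32).reshape(1, 2, 1, 1))
    assert kl_pseudo_distance(pc, po).item() == pytest.approx(LOG2, abs=1e-5)


def test_kl_matches_per_pixel_double_loop(rng):
    pc = random_probmap(rng, (1, 3, 4, 4))
    po = random_probmap(rng, (1, 3, 4, 4))
    eps = 1e-8
    expect = 0.0
    for i in range(4):
        for j in range(4):
            for c in range(3):
                a = max(float(pc.data[0, c, i, j]), eps)
                b = max(float(po.data[0, c, i, j]), eps)
                expect += a * np.log(a / b)
    expect /= 16
    assert kl_pseudo_distance(pc, po).item() == pytest.approx(expect, abs=1e-6)
    assert kl_pseudo_distance(pc, po).item() >= 0.0


# -- pseudo-labels -----------------------------------------------------------

def test_pseudo_label_onehot_and_tie_break():
    p = np.array([[0.4, 0.4, 0.2]], dtype=np.float32).reshape(1, 3, 1, 1)
    lab = pseudo_label(Tensor(p))
    assert lab.sum(axis=1).max() == 1.0
    assert lab[0, 0, 0, 0] == 1.0   # tie resolved toward the lowest class


def test_pseudo_label_carries_no_gradient(rng):
    raw = rng.uniform(0.05, 1.0, size=(2, 4, 6, 6)).astype(np.float32)
    p = Tensor(raw / raw.sum(axis=1, keepdims=True), requires_grad=True)
    lab = pseudo_label(p)
    assert isinstance(lab, np.ndarray)   # a constant w.r.t. autodiff
    loss = cross_entropy_loss(p, lab)
    loss.backward()
    assert p.grad is not None


# -- dacps loss --------------------------------------------------------------

def test_dacps_reduces_to_plain_cps_at_zero_distance(rng):
    p1 = random_probmap(rng)
    p2 = random_probmap(rng)
    got = dacps_loss(p1, p2, 0.0, 0.0).item()
    expect = (cross_entropy_loss(p2, pseudo_label(p1)).item()
              + cross_entropy_loss(p1, pseudo_label(p2)).item())
    assert got == pytest.approx(expect, abs=1e-6)


def test_dacps_consensus_limit_is_zero(rng):
    onehot = np.zeros((1, 3, 4, 4), dtype=np.float32)
    onehot[:, 1] = 1.0
    p = Tensor(onehot)
    assert dacps_loss(p, p, kl_pseudo_distance(p, p),
                      kl_pseudo_distance(p, p)).item() == pytest.approx(0.0, abs=1e-4)


def test_dacps_scalar_evaluation_at_log2(rng):
    """d1 = d2 = log 2 with fixed CE terms c gives 0.5c + log2 + 0.5c + log2."""
    p1 = random_probmap(rng)
    p2 = random_probmap(rng)
    c21 = cross_entropy_loss(p2, pseudo_label(p1)).item()
    c12 = cross_entropy_loss(p1, pseudo_label(p2)).item()
    got = dacps_loss(p1, p2, LOG2, LOG2).item()
    assert got == pytest.approx(0.5 * c21 + LOG2 + 0.5 * c12 + LOG2, abs=1e-5)


def test_dacps_symmetric_under_stream_swap(rng):
    p1 = random_probmap(rng)
    p2 = random_probmap(rng)
    v1 = kl_map(p1, p2).detach()
    v2 = kl_map(p2, p1).detach()
    a = dacps_loss(p1, p2, v1.mean(), v2.mean(), v1=v1, v2=v2).item()
    b = dacps_loss(p2, p1, v2.mean(), v1.mean(), v1=v2, v2=v1).item()
    assert a == pytest.approx(b, abs=1e-6)


def test_exponential_weight_strictly_decreases_in_distance():
    d = np.linspace(0.0, 5.0, 20)
    w = np.exp(-d)
    assert np.all(np.diff(w) < 0)


def test_dacps_rejects_unknown_exponent_source(rng):
    p = random_probmap(rng)
    with pytest.raises(ValueError, match="exponent_source"):
        dacps_loss(p, p, 0.0, 0.0, exponent_source="entropy")


# -- dice losses -------------------------------------------------------------

def test_supervised_dice_perfect_and_disjoint():
    y = np.zeros((1, 4, 4), dtype=np.int64)
    y[0, :2] = 1
    perfect = Tensor(one_hot(y, 2))
    assert soft_dice_loss(perfect, one_hot(y, 2)).item() == pytest.approx(0.0, abs=1e-4)
    assert supervised_dice_loss(perfect, perfect, y, 2).item() == pytest.approx(
        0.0, abs=1e-4)
    flipped = Tensor(one_hot(1 - y, 2))
    assert soft_dice_loss(flipped, one_hot(y, 2)).item() == pytest.approx(1.0, abs=1e-4)


def test_soft_dice_matches_brute_force_on_hand_mask(rng):
    y = np.array([[[0, 1, 1, 0], [0, 1, 0, 0], [2, 2, 0, 0], [2, 0, 0, 1]]],
                 dtype=np.int64)
    p = rng.uniform(0.05, 1.0, size=(1, 3, 4, 4)).astype(np.float32)
    p /= p.sum(axis=1, keepdims=True)
    g = one_hot(y, 3)
    sm = 1e-5
    dices = []
    for c in (1, 2):
        inter = sum(float(p[0, c, i, j]) * float(g[0, c, i, j])
                    for i in range(4) for j in range(4))
        tot = (sum(float(p[0, c, i, j]) for i in range(4) for j in range(4))
               + sum(float(g[0, c, i, j]) for i in range(4) for j in range(4)))
        dices.append((2 * inter + sm) / (tot + sm))
    expect = 1.0 - float(np.mean(dices))
    assert soft_dice_loss(Tensor(p), g, sm).item() == pytest.approx(expect, abs=1e-6)


def test_supervised_dice_requires_labels(rng):
    p = random_probmap(rng)
    with pytest.raises(ValueError, match="labels"):
        supervised_dice_loss(p, p, None, 4)
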