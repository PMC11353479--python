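"""Alignment sub-network: attention algebra, GAN/reconstruction losses,
parameter topology."""

import numpy as np
import pytest

from facps import alignment, nn
from facps.alignment import (adversarial_value, build_nets, discriminator_loss,
                             generator_adversarial_loss, generator_loss,
                             reconstruction_l1)
from facps.nn import SelfAttention2d, Tensor

LOG2 = float(np.log(2.0))


@pytest.fixture(scope="module")
def nets():
    return build_nets(feat_channels=8, n_classes=3, use_attention=True, seed=0)


# -- self-attention ----------------------------------------------------------

def test_attention_zero_gate_is_bitexact_identity(rng):
    att = SelfAttention2d(4, rng=rng)
    assert float(att.gate.data) == 0.0
    f = Tensor(rng.normal(size=(2, 4, 5, 5)).astype(np.float32))
    out = att(f)
    assert np.array_equal(out.data, f.data)


def test_attention_rows_sum_to_one(rng):
    att = SelfAttention2d(6, rng=rng)
    f = Tensor(rng.normal(size=(3, 6, 4, 4)).astype(np.float32))
    a = att.attention_map(f).data
    np.testing.assert_allclose(a.sum(axis=2), 1.0, atol=1e-5)


def test_attention_map_equals_gram_softmax_oracle(rng):
    """With identity 1x1 query/key kernels on a 2x2 grid the attention map
    is the row-softmaxed Gram matrix of the feature columns."""
    c = 3
    att = SelfAttention2d(c, rng=rng)
    eye = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1)
    for conv in (att.c1, att.c2, att.c3):
        conv.w.data = eye.copy()
        conv.b.data = np.zeros(c, dtype=np.float32)
    f = rng.normal(size=(1, c, 2, 2)).astype(np.float32)
    a = att.attention_map(Tensor(f)).data[0]

    flat = f[0].reshape(c, 4)
    expect = np.zeros((4, 4))
    for i in range(4):
        logits = np.array([sum(flat[ch, i] * flat[ch, j] for ch in range(c))
                           for j in range(4)])
        e = np.exp(logits - logits.max())
        expect[i] = e / e.sum()
    np.testing.assert_allclose(a, expect, atol=1e-5)


# -- encoder / translate -----------------------------------------------------

def test_encoder_deterministic_and_stride_contract(nets, rng):
    x = Tensor(rng.uniform(-1, 1, size=(1, 1, 32, 32)).astype(np.float32))
    f1 = nets.encoder(x).data
    f2 = nets.encoder(x).data
    assert np.array_equal(f1, f2)
    assert f1.shape[2:] == (32 // alignment.ENCODER_STRIDE,) * 2


def test_encoder_rejects_incompatible_size(nets, rng):
    with pytest.raises(ValueError, match="stride"):
        nets.encoder(Tensor(rng.normal(size=(1, 1, 30, 30)).astype(np.float32)))


def test_translate_shape_range_and_domain_tag(nets, rng):
    x = Tensor(rng.uniform(-1, 1, size=(2, 1, 32, 32)).astype(np.float32))
    for dom in ("source", "target"):
        y = nets.translate(x, dom)
        assert y.shape == x.shape
        assert y.data.min() >= -1.0 and y.data.max() <= 1.0
    with pytest.raises(ValueError, match="domain"):
        nets.translate(x, "both")


def test_unknown_backbone_rejected():
    with pytest.raises(ValueError, match="backbone"):
        alignment.Encoder(backbone="deeplab-resnet50")


# -- parameter topology ------------------------------------------------------

def test_domain_components_share_no_parameters(nets):
    for a, b in ((nets.g_s, nets.g_t), (nets.d_s, nets.d_t),
                 (nets.seg1, nets.seg2)):
        ids_a = {id(p) for p in a.parameters().values()}
        ids_b = {id(p) for p in b.parameters().values()}
        assert not ids_a & ids_b


def test_shared_encoder_identical_in_both_directions(nets):
    assert nets.modules()["encoder"] is nets.encoder  # single registry


def test_bundle_rejects_shared_streams():
    n = build_nets(feat_channels=8, n_classes=3, seed=1)
    with pytest.raises(ValueError, match="share"):
        alignment.NetBundle(n.encoder, n.g_s, n.g_t, n.d_s, n.d_t,
                            n.seg1, n.seg1)


# -- adversarial losses ------------------------------------------------------

def test_perfect_discriminator_reaches_loss_floor():
    real = Tensor(np.ones((2, 1, 4, 4), dtype=np.float32))
    fake = Tensor(np.zeros((2, 1, 4, 4), dtype=np.float32))
    assert discriminator_loss(real, fake).item() == pytest.approx(0.0, abs=1e-5)


def test_chance_discriminator_closed_form():
    half = Tensor(np.full((3, 1, 4, 4), 0.5, dtype=np.float32))
    # negative-log loss at D=0.5 is 2*log2; the stated objective value is
    # log(1/2) + log(1/2) = -2*log2
    assert discriminator_loss(half, half).item() == pytest.approx(2 * LOG2, abs=1e-5)
    assert adversarial_value(half.data, half.data) == pytest.approx(-2 * LOG2, abs=1e-5)
    assert generator_adversarial_loss(half).item() == pytest.approx(LOG2, abs=1e-5)


def test_discriminator_step_sends_no_gradient_to_generators(nets, rng):
    """Freezing contract: fakes are detached, so the discriminator loss has
    exactly zero gradient w.r.t. encoder/decoder parameters."""
    x = Tensor(rng.uniform(-1, 1, size=(2, 1, 32, 32)).astype(np.float32))
    with nn.no_grad():
        fake = nets.translate(x, "target")
    loss = discriminator_loss(nets.d_t(x), nets.d_t(Tensor(fake.data)))
    for mod in (nets.encoder, nets.g_s, nets.g_t):
        mod.zero_grad()
    loss.backward()
    for mod in (nets.encoder, nets.g_s, nets.g_t):
        assert all(p.grad is None for p in mod.parameters().values())
    assert any(p.grad is not None for p in nets.d_t.parameters().values())


def test_adversarial_losses_bundle_contract(nets, rng):
    x_s = Tensor(rng.uniform(-1, 1, size=(2, 1, 32, 32)).astype(np.float32))
    x_t = Tensor(rng.uniform(-1, 1, size=(2, 1, 32, 32)).astype(np.float32))
    out = alignment.adversarial_losses(nets, x_s, x_t)
    # stated-form value is the negated discriminator loss
    assert out["adv_value_t"] == pytest.approx(-out["d_loss_t"].item(), abs=1e-5)
    assert out["g_adv_t"].item() >= 0.0 and out["d_loss_s"].item() >= 0.0
    with pytest.raises(ValueError, match="batch"):
        alignment.adversarial_losses(
            nets, Tensor(np.zeros((0, 1, 32, 32), dtype=np.float32)), x_t)


def test_reconstruction_losses_with_identity_stubs(rng):
    class Identity:
        def __call__(self, x):
            return x

    class Stub:
        encoder = Identity()
        g_s = Identity()
        g_t = Identity()

    x = Tensor(rng.uniform(-1, 1, size=(1, 1, 8, 8)).astype(np.float32))
    recon_t, recon_s = alignment.reconstruction_losses(Stub(), x, x)
    assert recon_t.item() == 0.0 and recon_s.item() == 0.0


# -- reconstruction ----------------------------------------------------------

def test_reconstruction_identity_and_offset(rng):
    x = Tensor(rng.uniform(-1, 1, size=(2, 1, 8, 8)).astype(np.float32))
    assert reconstruction_l1(x, x).item() == 0.0
    shifted = Tensor(x.data + 0.1)
    assert reconstruction_l1(shifted, x).item() == pytest.approx(0.1, abs=1e-6)


def test_reconstruction_matches_per_pixel_loop(rng):
    a = rng.uniform(-1, 1, size=(2, 1, 6, 6)).astype(np.float32)
    b = rng.uniform(-1, 1, size=(2, 1, 6, 6)).astype(np.float32)
    expect = float(np.mean([abs(float(x) - float(y))
                            for x, y in zip(a.ravel(), b.ravel())]))
    assert reconstruction_l1(Tensor(a), Tensor(b)).item() == pytest.approx(
        expect, abs=1e-6)


# -- generator loss ----------------------------------------------------------

def test_generator_loss_weighting():
    assert generator_loss(2.0, 10.0) == pytest.approx(2.2)          # printed weights
    assert generator_loss(2.0, 10.0, lambda_adv=0.0) == pytest.approx(2.0)
    base = generator_loss(1.0, 1.0, lambda_recon=1.0, lambda_adv=0.02)
    double = generator_loss(1.0, 1.0, lambda_recon=2.0, lambda_adv=0.02)
    assert double - base == pytest.approx(1.0)
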