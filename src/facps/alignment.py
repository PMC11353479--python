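"""Cross-modality feature-alignment sub-network and its losses.

One encoder ``E`` is shared by every path (translation in both directions
and segmentation), which is what forces it toward domain-invariant
features.  Two domain-specific decoders ``G_s``/``G_t`` map the latent
grid back to image space (tanh output, matching the [-1, 1] input range)
and two discriminators ``D_s``/``D_t`` judge realness per patch.  The
decoders share an architecture but never parameters, likewise the
discriminators.  A self-attention block with a zero-initialised learnable
gate sits on the encoder's last convolutional layer, so a fresh encoder
is exactly attention-free.

Losses: the adversarial objective is the standard minimax log form,
trained as binary cross-entropy with the non-saturating generator
variant; reconstruction is mean absolute error of re-decoding an image
into its own domain; the per-domain generator loss combines the two as
``lambda_recon * L_recon + lambda_adv * L_adv`` with defaults 1.0 / 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Conv2d, InstanceNorm2d, SelfAttention2d, Tensor

__all__ = [
    "Encoder",
    "Decoder",
    "Discriminator",
    "NetBundle",
    "build_nets",
    "discriminator_loss",
    "generator_adversarial_loss",
    "adversarial_value",
    "adversarial_losses",
    "reconstruction_l1",
    "reconstruction_losses",
    "generator_loss",
    "ENCODER_STRIDE",
]

ENCODER_STRIDE = 4
_LOG_EPS = 1e-7


class ResidualBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, pad=1, rng=rng)
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, pad=1, rng=rng)
        self.norm2 = InstanceNorm2d(channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = nn.relu(self.norm1(self.conv1(x)))
        return nn.relu(self.norm2(self.conv2(h)) + x)


class Encoder(Module):
    """Shared encoder; downsamples by ENCODER_STRIDE, optional attention on
    the final layer.  ``backbone='small'`` is the CPU desk default;
    ``'resnet_small'`` adds residual blocks for a deeper variant."""

    def __init__(self, feat_channels: int = 16, use_attention: bool = False,
                 backbone: str = "small", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if backbone not in ("small", "resnet_small"):
            raise ValueError(f"unknown backbone {backbone!r}")
        c = feat_channels
        self.conv1 = Conv2d(1, c // 2, 3, stride=2, pad=1, rng=rng)
        self.norm1 = InstanceNorm2d(c // 2)
        self.conv2 = Conv2d(c // 2, c, 3, stride=2, pad=1, rng=rng)
        self.norm2 = InstanceNorm2d(c)
        self.blocks = (
            [ResidualBlock(c, rng), ResidualBlock(c, rng)]
            if backbone == "resnet_small" else []
        )
        self.conv3 = Conv2d(c, c, 3, pad=1, rng=rng)
        self.norm3 = InstanceNorm2d(c)
        self.attention = SelfAttention2d(c, rng=rng) if use_attention else None
        self.feat_channels = c

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % ENCODER_STRIDE or w % ENCODER_STRIDE:
            raise ValueError(
                f"input size {h}x{w} not divisible by encoder stride {ENCODER_STRIDE}"
            )
        f = nn.relu(self.norm1(self.conv1(x)))
        f = nn.relu(self.norm2(self.conv2(f)))
        for blk in self.blocks:
            f = blk(f)
        f = nn.relu(self.norm3(self.conv3(f)))
        if self.attention is not None:
            f = self.attention(f)
        return f


class Decoder(Module):
    """Domain-specific decoder: residual refinement + two upsampling stages,
    tanh output bounded to [-1, 1]."""

    def __init__(self, feat_channels: int = 16, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        c = feat_channels
        self.block = ResidualBlock(c, rng)
        self.up1 = Conv2d(c, c // 2, 3, pad=1, rng=rng)
        self.norm1 = InstanceNorm2d(c // 2)
        self.out = Conv2d(c // 2, 1, 3, pad=1, rng=rng)

    def __call__(self, f: Tensor) -> Tensor:
        h = self.block(f)
        h = nn.relu(self.norm1(self.up1(nn.upsample_nearest(h, 2))))
        return nn.tanh(self.out(nn.upsample_nearest(h, 2)))


class Discriminator(Module):
    """Four conv layers emitting a patch map of realness probabilities."""

    def __init__(self, base: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.conv1 = Conv2d(1, base, 3, stride=2, pad=1, rng=rng)
        self.conv2 = Conv2d(base, base * 2, 3, stride=2, pad=1, rng=rng)
        self.norm2 = InstanceNorm2d(base * 2)
        self.conv3 = Conv2d(base * 2, base * 2, 3, stride=2, pad=1, rng=rng)
        self.norm3 = InstanceNorm2d(base * 2)
        self.conv4 = Conv2d(base * 2, 1, 3, pad=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = nn.leaky_relu(self.conv1(x))
        h = nn.leaky_relu(self.norm2(self.conv2(h)))
        h = nn.leaky_relu(self.norm3(self.conv3(h)))
        return nn.sigmoid(self.conv4(h))


@dataclass
class NetBundle:
    """The seven parameterised components; seg heads are owned by the
    dual-stream segmentation module but registered here so the optimizer
    grouping (and parameter-disjointness checks) can see everything."""

    encoder: Encoder
    g_s: Decoder
    g_t: Decoder
    d_s: Discriminator
    d_t: Discriminator
    seg1: Module
    seg2: Module

    def __post_init__(self):
        for a, b, what in (
            (self.g_s, self.g_t, "G_s/G_t"),
            (self.d_s, self.d_t, "D_s/D_t"),
            (self.seg1, self.seg2, "S(theta1)/S(theta2)"),
        ):
            ids_a = {id(p) for p in a.parameters().values()}
            ids_b = {id(p) for p in b.parameters().values()}
            if ids_a & ids_b:
                raise ValueError(f"{what} must not share parameters")

    def translate(self, x: Tensor, to_domain: str) -> Tensor:
        if to_domain == "target":
            return self.g_t(self.encoder(x))
        if to_domain == "source":
            return self.g_s(self.encoder(x))
        raise ValueError(f"unknown domain tag {to_domain!r}")

    def modules(self) -> dict[str, Module]:
        return {
            "encoder": self.encoder, "g_s": self.g_s, "g_t": self.g_t,
            "d_s": self.d_s, "d_t": self.d_t, "seg1": self.seg1, "seg2": self.seg2,
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, mod in self.modules().items():
            for k, v in mod.state_dict().items():
                out[f"{name}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, mod in self.modules().items():
            prefix = name + "."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            mod.load_state_dict(sub)


def build_nets(feat_channels: int = 16, n_classes: int = 5,
               use_attention: bool = False, backbone: str = "small",
               seed: int = 0) -> NetBundle:
    """Construct all components with independent per-component init streams
    (the two seg heads share a structure but differ by initialisation)."""
    from .dacps import SegHead  # local import to avoid a module cycle

    streams = [np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                            spawn_key=(7, i)))
               for i in range(7)]
    return NetBundle(
        encoder=Encoder(feat_channels, use_attention, backbone, rng=streams[0]),
        g_s=Decoder(feat_channels, rng=streams[1]),
        g_t=Decoder(feat_channels, rng=streams[2]),
        d_s=Discriminator(rng=streams[3]),
        d_t=Discriminator(rng=streams[4]),
        seg1=SegHead(feat_channels, n_classes, rng=streams[5]),
        seg2=SegHead(feat_channels, n_classes, rng=streams[6]),
    )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _safe_log(p: Tensor) -> Tensor:
    return p.clamp(_LOG_EPS, 1.0 - _LOG_EPS).log()


def discriminator_loss(p_real: Tensor, p_fake: Tensor) -> Tensor:
    """Negative-log discriminator objective; 0 is the perfect-D limit.

    Minimising this maximises E[log D(real)] + E[log(1 - D(fake))].
    """
    return -(_safe_log(p_real).mean() + _safe_log(1.0 - p_fake).mean())


def generator_adversarial_loss(p_fake: Tensor) -> Tensor:
    """Non-saturating generator objective, -E[log D(fake)]."""
    return -_safe_log(p_fake).mean()


def adversarial_value(p_real: np.ndarray, p_fake: np.ndarray) -> float:
    """The adversarial objective in its stated form,
    E[log D(real)] + E[log(1 - D(fake))], for reporting."""
    pr = np.clip(p_real, _LOG_EPS, 1 - _LOG_EPS)
    pf = np.clip(p_fake, _LOG_EPS, 1 - _LOG_EPS)
    return float(np.log(pr).mean() + np.log(1.0 - pf).mean())


def reconstruction_l1(x_hat: Tensor, x: Tensor) -> Tensor:
    """Mean absolute error between a re-decoded image and the original."""
    return (x_hat - x).abs().mean()


def adversarial_losses(nets: "NetBundle", x_s: Tensor, x_t: Tensor) -> dict:
    """All adversarial terms for one batch of both domains.

    Discriminator losses are computed on detached translations (no
    gradient reaches the generators); the generator-side losses use fresh
    translations with the discriminators frozen by contract.  Returns the
    negative-log discriminator losses, the non-saturating generator
    losses, and the stated-form objective values ``adv_value_*``.
    """
    if x_s.shape[0] == 0 or x_t.shape[0] == 0:
        raise ValueError("a batch from each domain is required")
    with nn.no_grad():
        x_st = nets.translate(x_s, "target")
        x_ts = nets.translate(x_t, "source")
    p_real_t, p_fake_t = nets.d_t(x_t), nets.d_t(Tensor(x_st.data))
    p_real_s, p_fake_s = nets.d_s(x_s), nets.d_s(Tensor(x_ts.data))
    return {
        "d_loss_t": discriminator_loss(p_real_t, p_fake_t),
        "d_loss_s": discriminator_loss(p_real_s, p_fake_s),
        "g_adv_t": generator_adversarial_loss(nets.d_t(nets.translate(x_s, "target"))),
        "g_adv_s": generator_adversarial_loss(nets.d_s(nets.translate(x_t, "source"))),
        "adv_value_t": adversarial_value(p_real_t.data, p_fake_t.data),
        "adv_value_s": adversarial_value(p_real_s.data, p_fake_s.data),
    }


def reconstruction_losses(nets: "NetBundle", x_s: Tensor, x_t: Tensor
                          ) -> tuple[Tensor, Tensor]:
    """Same-domain reconstruction pair:
    ``(E||G_t(E(x_t)) - x_t||_1, E||G_s(E(x_s)) - x_s||_1)``."""
    recon_t = reconstruction_l1(nets.g_t(nets.encoder(x_t)), x_t)
    recon_s = reconstruction_l1(nets.g_s(nets.encoder(x_s)), x_s)
    return recon_t, recon_s


def generator_loss(recon: Tensor | float, adv: Tensor | float,
                   lambda_recon: float = 1.0, lambda_adv: float = 0.02):
    """Per-domain generator loss: lambda_recon*L_recon + lambda_adv*L_adv."""
    return recon * lambda_recon + adv * lambda_adv
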