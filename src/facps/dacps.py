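"""Dual-stream segmentation and the distance-aware cross-pseudo-supervision loss.

Two segmentation heads with one structure but independent initialisation
sit on the shared encoder.  For an image pair (original, its cross-domain
translation) each head predicts both, the per-head predictions are
ensemble-averaged, and each head's hard pseudo-label (argmax, no
gradient) supervises the *other* head's average prediction through a
cross-entropy term.  The KL "pseudo-distance" between a head's
prediction on the translated image and on the original quantifies how
unreliable that head's pseudo-labels are; the cross-entropy term is
down-weighted by exp(-d) (a detached scalar) and d itself is added as a
consistency regulariser.  With d = 0 the loss reduces exactly to plain
cross-pseudo-supervision, which is also the code path used for the
CPS-only ablation (exponent forced to zero, +d terms dropped).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Conv2d, Module, Tensor

__all__ = [
    "SegHead",
    "one_hot",
    "dual_predict",
    "ensemble_average",
    "kl_map",
    "kl_pseudo_distance",
    "pseudo_label",
    "cross_entropy_map",
    "cross_entropy_loss",
    "dacps_loss",
    "soft_dice_loss",
    "supervised_dice_loss",
]

_CE_EPS = 1e-7


class SegHead(Module):
    """Segmentation head over encoder features: one hidden conv, a 1x1
    classifier, bilinear upsampling back to image resolution, channel
    softmax.  Output is a valid probability map (B, C, H, W)."""

    def __init__(self, feat_channels: int, n_classes: int, upsample: int = 4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        c = feat_channels
        self.conv = Conv2d(c, c, 3, pad=1, rng=rng)
        self.classify = Conv2d(c, n_classes, 1, rng=rng)
        self.upsample = upsample
        self.n_classes = n_classes

    def __call__(self, f: Tensor) -> Tensor:
        h = nn.relu(self.conv(f))
        logits = self.classify(h)
        logits = nn.upsample_bilinear(logits, logits.shape[2] * self.upsample)
        return nn.softmax_channel(logits, axis=1)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(B, H, W) integer labels -> (B, C, H, W) float32 one-hot."""
    labels = np.asarray(labels)
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def dual_predict(nets, x_orig: Tensor, x_translated: Tensor):
    """Predictions of both streams on an image and its translation:
    ``p_o_i = S(theta_i)(E(x_orig))``, ``p_c_i = S(theta_i)(E(x_translated))``."""
    ids1 = {id(p) for p in nets.seg1.parameters().values()}
    ids2 = {id(p) for p in nets.seg2.parameters().values()}
    if ids1 & ids2:
        raise ValueError("the two segmentation streams must not share parameters")
    f_o = nets.encoder(x_orig)
    f_c = nets.encoder(x_translated)
    return nets.seg1(f_o), nets.seg1(f_c), nets.seg2(f_o), nets.seg2(f_c)


def ensemble_average(p_o: Tensor, p_c: Tensor) -> Tensor:
    """Midpoint of two probability maps (stays on the simplex)."""
    if p_o.shape != p_c.shape:
        raise ValueError(f"shape mismatch: {p_o.shape} vs {p_c.shape}")
    return (p_o + p_c) * 0.5


def kl_map(p_c: Tensor, p_o: Tensor, eps: float = 1e-8) -> Tensor:
    """Per-pixel KL divergence KL(p_c || p_o): the class-wise sum of
    p_c*log(p_c/p_o) at every pixel, shape (B, H, W).  Probabilities are
    clamped to [eps, 1] before the logs, so zeros are safe."""
    pc = p_c.clamp(eps, 1.0)
    po = p_o.clamp(eps, 1.0)
    return (pc * (pc.log() - po.log())).sum(axis=1)


def kl_pseudo_distance(p_c: Tensor, p_o: Tensor, eps: float = 1e-8) -> Tensor:
    """Batch-mean KL pseudo-distance: ``kl_map`` averaged over pixels and
    batch; 0 iff the two probability maps agree (within clamping)."""
    return kl_map(p_c, p_o, eps).mean()


def pseudo_label(p_avg: Tensor | np.ndarray) -> np.ndarray:
    """Hard one-hot pseudo-label by per-pixel argmax (ties -> lowest class
    index).  Returns a plain array: no gradient flows through this path."""
    probs = p_avg.data if isinstance(p_avg, Tensor) else np.asarray(p_avg)
    idx = probs.argmax(axis=1)
    return one_hot(idx, probs.shape[1])


def cross_entropy_map(p: Tensor, target_onehot: np.ndarray) -> Tensor:
    """Per-pixel cross-entropy (B, H, W) of a probability map against a
    one-hot target."""
    logp = p.clamp(_CE_EPS, 1.0).log()
    return -(logp * Tensor(target_onehot)).sum(axis=1)


def cross_entropy_loss(p: Tensor, target_onehot: np.ndarray) -> Tensor:
    """Pixel-mean cross-entropy of a probability map against a one-hot target."""
    return cross_entropy_map(p, target_onehot).mean()


def dacps_loss(
    p_avg1: Tensor,
    p_avg2: Tensor,
    d1: Tensor | float,
    d2: Tensor | float,
    v1: Tensor | None = None,
    v2: Tensor | None = None,
    exponent_source: str = "distance",
    include_distance: bool = True,
) -> Tensor:
    """Distance-aware cross-pseudo-supervision for one direction.

    ``E[exp(-v1) * CE(p_avg2, P1)] + d1 + E[exp(-v2) * CE(p_avg1, P2)] + d2``
    where P_i = one-hot(argmax p_avg_i) carries no gradient.  The exponent
    ``v_i`` is the per-pixel KL pseudo-distance map (pass ``v1``/``v2``);
    when omitted it falls back to the scalar ``d_i``, which is also the
    batch mean of the map.  The exponential weight is detached either way,
    so only its value — not its gradient — modulates the supervision.
    With ``v_i = d_i = 0`` the loss is exactly plain cross-pseudo-
    supervision; ``exponent_source='zero'`` with
    ``include_distance=False`` is that ablation's code path.
    """
    if exponent_source not in ("distance", "zero"):
        raise ValueError(f"unknown exponent_source {exponent_source!r}")
    p1 = pseudo_label(p_avg1)
    p2 = pseudo_label(p_avg2)
    ce_21 = cross_entropy_map(p_avg2, p1)   # P1 supervises stream 2
    ce_12 = cross_entropy_map(p_avg1, p2)   # P2 supervises stream 1

    def _weight(v, d) -> np.ndarray | float:
        if exponent_source == "zero":
            return 1.0
        arg = v if v is not None else d
        val = arg.data if isinstance(arg, Tensor) else np.asarray(arg)
        return np.exp(-val).astype(np.float32)  # detached

    loss = (ce_21 * _weight(v1, d1)).mean() + (ce_12 * _weight(v2, d2)).mean()
    if include_distance:
        d1_t = d1 if isinstance(d1, Tensor) else Tensor(np.float32(d1))
        d2_t = d2 if isinstance(d2, Tensor) else Tensor(np.float32(d2))
        loss = loss + d1_t + d2_t
    return loss


def soft_dice_loss(p: Tensor, target_onehot: np.ndarray, smooth: float = 1e-5) -> Tensor:
    """1 - mean soft Dice over foreground classes (class 0 excluded).

    Per class and batch item: (2*sum(p*g) + smooth) / (sum(p) + sum(g) + smooth)
    with the sums over pixels.
    """
    g = Tensor(target_onehot)
    inter = (p * g).sum(axis=(2, 3))
    denom = p.sum(axis=(2, 3)) + g.sum(axis=(2, 3))
    dice = (inter * 2.0 + smooth) / (denom + smooth)     # (B, C)
    b, c = dice.shape
    if c < 2:
        raise ValueError("soft Dice needs at least one foreground class")
    fg = np.ones((1, c), dtype=np.float32)
    fg[0, 0] = 0.0
    mean_fg = (dice * Tensor(fg)).sum() * (1.0 / (b * (c - 1)))
    return 1.0 - mean_fg


def supervised_dice_loss(p_o1: Tensor, p_o2: Tensor, y: np.ndarray,
                         n_classes: int, smooth: float = 1e-5) -> Tensor:
    """Supervised source-domain loss: the sum of both streams' Dice losses
    against the gold labels ``y`` (B, H, W)."""
    if y is None:
        raise ValueError("supervised_dice_loss called on a batch without labels")
    g = one_hot(y, n_classes)
    return soft_dice_loss(p_o1, g, smooth) + soft_dice_loss(p_o2, g, smooth)
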