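"""Training orchestration: update schedule, total loss, ablation arms,
checkpointing and ensemble inference.

Each training iteration runs up to four sequential updates:

1. discriminator step for ``D_t`` and ``D_s`` on detached translations;
2. update ``E`` and ``G_t`` by minimising the target generator loss;
3. update ``E``, ``G_s`` and both seg streams by minimising the source
   generator loss plus the supervised Dice loss (on the source image
   and, from the FA arm up, on its target-style translation);
4. update the seg streams (and ``E``, configurable) by minimising the
   weighted cross-pseudo-supervision losses on (x_s, x_{s->t}) and
   (x_t, x_{t->s}).

Optimizer grouping: seg streams and decoders train at 1e-3, the shared
encoder and the discriminators at 2e-4, all with Adam (GAN components
use beta1=0.5, segmentation beta1=0.9).

The ablation ladder (SegOnly, FA, FA+CPS, FA+DACPS, FACPS) selects
nested loss sets; FACPS additionally enables the encoder's
self-attention block.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import alignment, dacps, metrics_eval, nn
from .alignment import NetBundle, build_nets
from .io_prep import ImageGrid, LabelMap, augment_pair
from .nn import Adam, Parameter, Tensor
from .phantom import DomainSample, PhantomConfig, PhantomDataset, generate_dataset

__all__ = [
    "TrainConfig",
    "LossBundle",
    "TrainingDiverged",
    "ARM_LADDER",
    "arm_losses",
    "total_loss",
    "Trainer",
    "train_iteration",
    "fit",
    "infer",
    "evaluate_target_dice",
    "run_ablation",
    "desk_benchmark_config",
    "save_checkpoint",
    "load_checkpoint",
]

ARM_LADDER = ("SegOnly", "FA", "FA+CPS", "FA+DACPS", "FACPS")


def arm_losses(arm: str) -> frozenset[str]:
    """Active loss/module set per ablation arm; sets are nested along the
    ladder (distance awareness and self-attention are additive upgrades of
    the cross-supervision path)."""
    if arm not in ARM_LADDER:
        raise ValueError(f"unknown ablation arm {arm!r}; choose from {ARM_LADDER}")
    active = {"l_s"}
    if arm != "SegOnly":
        active |= {"l_st", "l_gen_s", "l_gen_t"}
    if arm in ("FA+CPS", "FA+DACPS", "FACPS"):
        active |= {"l_cross"}
    if arm in ("FA+DACPS", "FACPS"):
        active |= {"distance_aware"}
    if arm == "FACPS":
        active |= {"self_attention"}
    return frozenset(active)


@dataclass(frozen=True)
class TrainConfig:
    """All hyperparameters; defaults follow the published configuration."""

    # loss weights
    lambda_recon: float = 1.0
    lambda_adv: float = 0.02
    lambda_gen_t: float = 1.0
    lambda_gen_s: float = 1.0
    lambda_s: float = 1.0
    lambda_st: float = 2.0
    lambda_ts: float = 2.0
    # optimisation
    lr_seg_and_decoders: float = 1e-3
    lr_encoder_and_discriminators: float = 2e-4
    betas_gan: tuple[float, float] = (0.5, 0.999)
    betas_seg: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 4
    iterations: int = 2000
    # model
    image_size: int = 64
    n_classes: int = 5
    feat_channels: int = 16
    backbone: str = "small"
    use_imagenet_init: bool = False
    lambda_att_init: float = 0.0
    # schedule / arms
    ablation_arm: str = "FACPS"
    seeds: tuple[int, ...] = (0, 1, 2)
    update_encoder_in_dacps: bool = True
    # loss numerics
    dice_smooth: float = 1e-5
    kl_eps: float = 1e-8
    exponent_source: str = "distance"
    # warm-up schedule for the cross-pseudo-supervision step: the step-4
    # loss is scaled by a ramp rising linearly from 0 to 1 between these
    # two fractions of total iterations, so pseudo-labels only start to
    # teach once the supervised path and the translators have matured
    # (guards against early degenerate consensus)
    cps_rampup: tuple[float, float] = (0.4, 0.7)
    # augmentation
    augment: bool = True
    rotation_deg: float = 15.0
    crop_scale: tuple[float, float] = (0.85, 1.0)

    def __post_init__(self):
        for name in ("lambda_recon", "lambda_adv", "lambda_gen_t", "lambda_gen_s",
                     "lambda_s", "lambda_st", "lambda_ts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lr_seg_and_decoders < 0 or self.lr_encoder_and_discriminators < 0:
            raise ValueError("learning rates must be >= 0 (0 freezes training)")
        arm_losses(self.ablation_arm)  # validates the arm name
        if self.use_imagenet_init:
            raise ValueError(
                "use_imagenet_init requires pretrained weights, which this "
                "build does not ship; set it to False"
            )

    @property
    def active_losses(self) -> frozenset[str]:
        return arm_losses(self.ablation_arm)


@dataclass
class LossBundle:
    """Scalar loss values of one iteration (None where inactive)."""

    l_gen_t: float | None = None
    l_gen_s: float | None = None
    l_s: float | None = None
    l_st: float | None = None
    l_dacps_st: float | None = None
    l_dacps_ts: float | None = None
    l_recon_t: float | None = None
    l_recon_s: float | None = None
    l_cycle_t: float | None = None
    l_cycle_s: float | None = None
    l_adv_t: float | None = None
    l_adv_s: float | None = None
    l_disc: float | None = None
    d1_st: float | None = None
    d2_st: float | None = None
    lambda_att: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, batch_ids: Sequence[str] = ()):
        super().__init__(message + (f" (batch ids: {list(batch_ids)})" if batch_ids else ""))
        self.batch_ids = list(batch_ids)


def total_loss(parts: Mapping[str, float] | LossBundle, cfg: TrainConfig) -> float:
    """Overall objective: lambda_gen_t*L_gen_t + lambda_gen_s*L_gen_s +
    lambda_s*L_s + lambda_st*L_dacps(s->t) + lambda_ts*L_dacps(t->s).

    The supervised part folds the translated-image Dice term (``l_st``,
    arms >= FA) into ``l_s``.  Missing constituents required by the
    configured arm raise.
    """
    p = parts.as_dict() if isinstance(parts, LossBundle) else dict(parts)
    active = cfg.active_losses

    def need(key):
        v = p.get(key)
        if v is None:
            raise ValueError(f"arm {cfg.ablation_arm!r} needs loss part {key!r}")
        return float(v)

    out = cfg.lambda_s * need("l_s")
    if "l_st" in active:
        out += cfg.lambda_s * need("l_st")
    if "l_gen_t" in active:
        out += cfg.lambda_gen_t * need("l_gen_t")
    if "l_gen_s" in active:
        out += cfg.lambda_gen_s * need("l_gen_s")
    if "l_cross" in active:
        out += cfg.lambda_st * need("l_dacps_st")
        out += cfg.lambda_ts * need("l_dacps_ts")
    return out


# ---------------------------------------------------------------------------
# trainer
# ---------------------------------------------------------------------------

class Trainer:
    """Holds nets + optimizer for one seed and executes the update schedule."""

    def __init__(self, cfg: TrainConfig, seed: int = 0, nets: NetBundle | None = None):
        self.cfg = cfg
        self.seed = seed
        self.nets = nets or build_nets(
            feat_channels=cfg.feat_channels,
            n_classes=cfg.n_classes,
            use_attention="self_attention" in cfg.active_losses,
            backbone=cfg.backbone,
            seed=seed,
        )
        att = self.nets.encoder.attention
        if att is not None:
            att.gate.data = np.asarray(cfg.lambda_att_init, dtype=np.float32)
        self.param_groups = self._make_groups()
        self.opt = Adam([(params, lr, betas) for params, lr, betas
                         in self.param_groups.values()])

    def _params(self, *modules) -> list[Parameter]:
        out = []
        for m in modules:
            out.extend(m.parameters().values())
        return out

    def _make_groups(self):
        n = self.nets
        cfg = self.cfg
        return {
            "decoders": (self._params(n.g_s, n.g_t),
                         cfg.lr_seg_and_decoders, cfg.betas_gan),
            "seg_streams": (self._params(n.seg1, n.seg2),
                            cfg.lr_seg_and_decoders, cfg.betas_seg),
            "encoder": (self._params(n.encoder),
                        cfg.lr_encoder_and_discriminators, cfg.betas_gan),
            "discriminators": (self._params(n.d_s, n.d_t),
                               cfg.lr_encoder_and_discriminators, cfg.betas_gan),
        }

    def group_lr(self, name: str) -> float:
        return self.param_groups[name][1]

    def _zero(self):
        self.opt.zero_grad()

    def _step(self, *modules):
        self.opt.step(self._params(*modules))

    # -- the four-step iteration ---------------------------------------------
    def train_iteration(self, xs: np.ndarray, ys: np.ndarray, xt: np.ndarray,
                        batch_ids: Sequence[str] = (),
                        cps_ramp: float = 1.0) -> LossBundle:
        """One iteration on a source batch (B,H,W images + labels) and a
        target batch (images only).  ``cps_ramp`` in [0, 1] scales the
        cross-pseudo-supervision step.  Returns the scalar losses."""
        cfg, n = self.cfg, self.nets
        active = cfg.active_losses
        gan = "l_gen_t" in active
        out = LossBundle()
        b = xs.shape[0]
        xs_t = Tensor(xs[:, None])
        xt_t = Tensor(xt[:, None])
        both = np.concatenate([xs[:, None], xt[:, None]])

        def _translate_pair() -> tuple[np.ndarray, np.ndarray]:
            """Detached x_{s->t}, x_{t->s} with current parameters."""
            with nn.no_grad():
                f = n.encoder(Tensor(both))
                x_st = n.g_t(nn.slice_rows(f, 0, b)).data
                x_ts = n.g_s(nn.slice_rows(f, b, 2 * b)).data
            return x_st, x_ts

        if gan:
            # (1) discriminators on detached translations
            x_st, x_ts = _translate_pair()
            self._zero()
            pt = n.d_t(Tensor(np.concatenate([xt[:, None], x_st])))
            ps = n.d_s(Tensor(np.concatenate([xs[:, None], x_ts])))
            d_loss = (
                alignment.discriminator_loss(nn.slice_rows(pt, 0, b),
                                             nn.slice_rows(pt, b, 2 * b))
                + alignment.discriminator_loss(nn.slice_rows(ps, 0, b),
                                               nn.slice_rows(ps, b, 2 * b)))
            d_loss.backward()
            self._step(n.d_s, n.d_t)
            out.l_disc = d_loss.item()

            # (2) target generator path: update E, G_t.  Besides the
            # same-domain reconstruction, the generated source-like fake is
            # reverse-transformed and must reconstruct the original target
            # image (cycle path; G_s contributes but is not stepped here).
            self._zero()
            f = n.encoder(Tensor(both))
            fs = nn.slice_rows(f, 0, b)
            ft = nn.slice_rows(f, b, 2 * b)
            f_cyc = n.encoder(n.g_s(ft))
            dec = n.g_t(nn.concat_rows([ft, f_cyc, fs]))
            recon_t = alignment.reconstruction_l1(nn.slice_rows(dec, 0, b), xt_t)
            cycle_t = alignment.reconstruction_l1(nn.slice_rows(dec, b, 2 * b), xt_t)
            adv_t = alignment.generator_adversarial_loss(
                n.d_t(nn.slice_rows(dec, 2 * b, 3 * b)))
            gen_t = alignment.generator_loss(recon_t + cycle_t, adv_t,
                                             cfg.lambda_recon, cfg.lambda_adv)
            gen_t.backward()
            self._step(n.encoder, n.g_t)
            out.l_recon_t, out.l_adv_t = recon_t.item(), adv_t.item()
            out.l_cycle_t = cycle_t.item()
            out.l_gen_t = gen_t.item()

        # (3) source generator path + supervised segmentation (one stacked
        # encoder/decoder/head call feeds every step-3 term)
        self._zero()
        step3_mods = [n.encoder, n.seg1, n.seg2]
        if gan:
            f = n.encoder(Tensor(both))
            fs = nn.slice_rows(f, 0, b)
            ft = nn.slice_rows(f, b, 2 * b)
            x_st_g = n.g_t(fs)           # in-graph for the cycle; G_t frozen
            f2 = n.encoder(nn.concat_rows([Tensor(x_st_g.data), x_st_g]))
            f_st = nn.slice_rows(f2, 0, b)      # detached x_{s->t} for L_st
            f_cyc = nn.slice_rows(f2, b, 2 * b)
            dec = n.g_s(nn.concat_rows([fs, f_cyc, ft]))
            recon_s = alignment.reconstruction_l1(nn.slice_rows(dec, 0, b), xs_t)
            cycle_s = alignment.reconstruction_l1(nn.slice_rows(dec, b, 2 * b), xs_t)
            adv_s = alignment.generator_adversarial_loss(
                n.d_s(nn.slice_rows(dec, 2 * b, 3 * b)))
            gen_s = alignment.generator_loss(recon_s + cycle_s, adv_s,
                                             cfg.lambda_recon, cfg.lambda_adv)
            head_in = nn.concat_rows([fs, f_st])
        else:
            fs = n.encoder(xs_t)
            head_in = fs
        h1 = n.seg1(head_in)
        h2 = n.seg2(head_in)
        p_o1, p_o2 = nn.slice_rows(h1, 0, b), nn.slice_rows(h2, 0, b)
        l_s = dacps.supervised_dice_loss(p_o1, p_o2, ys, cfg.n_classes,
                                         cfg.dice_smooth)
        loss3 = l_s * cfg.lambda_s
        out.l_s = l_s.item()
        if gan:
            out.l_recon_s, out.l_adv_s = recon_s.item(), adv_s.item()
            out.l_cycle_s = cycle_s.item()
            out.l_gen_s = gen_s.item()
            loss3 = loss3 + gen_s * cfg.lambda_gen_s
            step3_mods.append(n.g_s)
        if "l_st" in active:
            p_c1 = nn.slice_rows(h1, b, 2 * b)
            p_c2 = nn.slice_rows(h2, b, 2 * b)
            l_st = dacps.supervised_dice_loss(p_c1, p_c2, ys, cfg.n_classes,
                                              cfg.dice_smooth)
            out.l_st = l_st.item()
            loss3 = loss3 + l_st * cfg.lambda_s
        loss3.backward()
        self._step(*step3_mods)

        # (4) cross-pseudo-supervision on both directions, one stacked pass:
        # rows [x_s | x_{s->t} | x_t | x_{t->s}]
        if "l_cross" in active and cps_ramp > 0.0:
            distance = "distance_aware" in active
            x_st, x_ts = _translate_pair()
            self._zero()
            f4 = n.encoder(Tensor(np.concatenate([xs[:, None], x_st,
                                                  xt[:, None], x_ts])))
            q1 = n.seg1(f4)
            q2 = n.seg2(f4)
            parts = []
            for base in (0, 2 * b):   # s->t then t->s
                po1 = nn.slice_rows(q1, base, base + b)
                pc1 = nn.slice_rows(q1, base + b, base + 2 * b)
                po2 = nn.slice_rows(q2, base, base + b)
                pc2 = nn.slice_rows(q2, base + b, base + 2 * b)
                pavg1 = dacps.ensemble_average(po1, pc1)
                pavg2 = dacps.ensemble_average(po2, pc2)
                # the pseudo-distance enters the loss value and the e^{-v}
                # weights but carries no gradient (see methods note)
                v1 = dacps.kl_map(pc1, po1, cfg.kl_eps).detach()
                v2 = dacps.kl_map(pc2, po2, cfg.kl_eps).detach()
                d1, d2 = v1.mean(), v2.mean()
                parts.append((
                    dacps.dacps_loss(
                        pavg1, pavg2, d1, d2, v1=v1, v2=v2,
                        exponent_source=(cfg.exponent_source if distance else "zero"),
                        include_distance=distance),
                    d1.item(), d2.item(),
                ))
            (l_dacps_st, d1_st, d2_st), (l_dacps_ts, _, _) = parts
            loss4 = (l_dacps_st * cfg.lambda_st
                     + l_dacps_ts * cfg.lambda_ts) * cps_ramp
            loss4.backward()
            step4 = [n.seg1, n.seg2]
            if cfg.update_encoder_in_dacps:
                step4.append(n.encoder)
            self._step(*step4)
            out.l_dacps_st = l_dacps_st.item()
            out.l_dacps_ts = l_dacps_ts.item()
            out.d1_st, out.d2_st = d1_st, d2_st
        elif "l_cross" in active:
            # before the warm-up ramp opens, the step is skipped entirely
            out.l_dacps_st = out.l_dacps_ts = 0.0

        att = n.encoder.attention
        out.lambda_att = float(att.gate.data) if att is not None else 0.0
        out.total = total_loss(out, cfg)
        if not np.isfinite(out.total):
            raise TrainingDiverged(
                f"non-finite loss at arm {cfg.ablation_arm}", batch_ids)
        return out


# ---------------------------------------------------------------------------
# fit / infer
# ---------------------------------------------------------------------------

@dataclass
class SeedRunResult:
    seed: int
    nets: NetBundle
    log: list[dict]
    recon_initial: dict[str, float] = field(default_factory=dict)
    recon_final: dict[str, float] = field(default_factory=dict)
    checkpoint_path: Path | None = None


@dataclass
class FitResult:
    cfg: TrainConfig
    runs: list[SeedRunResult]


def _probe_recon(trainer: Trainer, xs: np.ndarray, xt: np.ndarray) -> dict[str, float]:
    n = trainer.nets
    vals = {}
    with nn.no_grad():
        for tag, x in (("s", xs), ("t", xt)):
            img = Tensor(x[:, None])
            dec = n.g_s if tag == "s" else n.g_t
            vals[tag] = alignment.reconstruction_l1(dec(n.encoder(img)),
                                                    img).item()
    return vals


def _sample_batch(samples: list[DomainSample], idx: np.ndarray, cfg: TrainConfig,
                  rng: np.random.Generator, labeled: bool):
    imgs, lbls, ids = [], [], []
    for i in idx:
        s = samples[int(i)]
        img, lbl = s.image, s.label
        if cfg.augment:
            img, lbl = augment_pair(img, lbl, rng, cfg.rotation_deg, cfg.crop_scale)
        imgs.append(img.values)
        ids.append(s.id)
        if labeled:
            lbls.append(lbl.values)
    x = np.stack(imgs).astype(np.float32)
    y = np.stack(lbls).astype(np.int64) if labeled else None
    return x, y, ids


def fit(cfg: TrainConfig, dataset: PhantomDataset | None = None,
        out_dir: str | Path | None = None,
        phantom_cfg: PhantomConfig | None = None) -> FitResult:
    """Train one model per seed; returns nets, per-iteration logs, and the
    probe reconstruction losses at initialisation and after training."""
    if dataset is None:
        dataset = generate_dataset(phantom_cfg or PhantomConfig(
            image_size=cfg.image_size, n_classes=cfg.n_classes))
    if not dataset.train_source or not dataset.train_target:
        raise ValueError("empty training dataset")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    probe_xs = np.stack([s.image.values for s in dataset.train_source[:4]])
    probe_xt = np.stack([s.image.values for s in dataset.train_target[:4]])

    runs = []
    for seed in cfg.seeds:
        t0 = time.time()
        trainer = Trainer(cfg, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(13,)))
        recon0 = _probe_recon(trainer, probe_xs, probe_xt)
        log: list[dict] = []
        n_src, n_tgt = len(dataset.train_source), len(dataset.train_target)
        for it in range(cfg.iterations):
            idx_s = rng.integers(0, n_src, size=cfg.batch_size)
            idx_t = rng.integers(0, n_tgt, size=cfg.batch_size)
            xs, ys, ids_s = _sample_batch(dataset.train_source, idx_s, cfg, rng,
                                          labeled=True)
            xt, _, ids_t = _sample_batch(dataset.train_target, idx_t, cfg, rng,
                                         labeled=False)
            lo, hi = cfg.cps_rampup
            frac = it / max(cfg.iterations - 1, 1)
            ramp = float(np.clip((frac - lo) / max(hi - lo, 1e-9), 0.0, 1.0))
            bundle = trainer.train_iteration(xs, ys, xt, batch_ids=ids_s + ids_t,
                                             cps_ramp=ramp)
            row = {"iteration": it, "seed": seed, **bundle.as_dict()}
            log.append(row)
        recon1 = _probe_recon(trainer, probe_xs, probe_xt)
        result = SeedRunResult(seed=seed, nets=trainer.nets, log=log,
                               recon_initial=recon0, recon_final=recon1)
        if out is not None:
            log_path = out / f"train_log_seed{seed}.jsonl"
            with log_path.open("w") as fh:
                for row in log:
                    fh.write(json.dumps(row) + "\n")
            ckpt = out / f"checkpoint_seed{seed}.npz"
            save_checkpoint(ckpt, trainer.nets, cfg, extra={
                "seed": seed, "wall_clock_s": time.time() - t0,
                "recon_initial": recon0, "recon_final": recon1,
            })
            result.checkpoint_path = ckpt
        runs.append(result)
    return FitResult(cfg=cfg, runs=runs)


def infer(images: Sequence[ImageGrid], nets: NetBundle,
          stream: str = "ensemble") -> list[LabelMap]:
    """Ensemble inference: argmax of (S1(E(x)) + S2(E(x)))/2.  No
    translation step is involved.  ``stream`` in {'ensemble','1','2'}."""
    out = []
    with nn.no_grad():
        for img in images:
            x = Tensor(img.values[None, None])
            f = nets.encoder(x)
            if stream == "1":
                p = nets.seg1(f)
            elif stream == "2":
                p = nets.seg2(f)
            else:
                p = dacps.ensemble_average(nets.seg1(f), nets.seg2(f))
            pred = p.data[0].argmax(axis=0).astype(np.int64)
            out.append(LabelMap(pred, spacing=img.spacing))
    return out


def evaluate_target_dice(nets: NetBundle, samples: Sequence[DomainSample],
                         n_classes: int) -> float:
    """Mean foreground Dice (%) of ensemble predictions over samples."""
    preds = infer([s.image for s in samples], nets)
    scores = []
    for s, pred in zip(samples, preds):
        for cls in range(1, n_classes):
            if (s.label.values == cls).any() or (pred.values == cls).any():
                scores.append(metrics_eval.dice(pred, s.label, cls))
    return 100.0 * float(np.mean(scores)) if scores else float("nan")


def run_ablation(base_cfg: TrainConfig, dataset: PhantomDataset,
                 arms: Sequence[str] = ARM_LADDER,
                 out_dir: str | Path | None = None):
    """Train every arm with every seed and tabulate mean target Dice.

    Returns (per-run DataFrame, {arm: FitResult}).
    """
    import pandas as pd

    rows, fits = [], {}
    for arm in arms:
        cfg = replace(base_cfg, ablation_arm=arm)
        sub = Path(out_dir) / arm.replace("+", "_") if out_dir else None
        fr = fit(cfg, dataset=dataset, out_dir=sub)
        fits[arm] = fr
        for run in fr.runs:
            rows.append({
                "arm": arm, "seed": run.seed,
                "target_dice": evaluate_target_dice(
                    run.nets, dataset.test_target, cfg.n_classes),
                "source_dice": evaluate_target_dice(
                    run.nets, dataset.test_source, cfg.n_classes),
            })
    df = pd.DataFrame(rows)
    if out_dir:
        df.to_csv(Path(out_dir) / "ablation.csv", index=False)
    return df, fits


def desk_benchmark_config() -> tuple[PhantomConfig, TrainConfig]:
    """The 64 px desk benchmark: 100 paired training anatomies (200 slices),
    20 test anatomies, batch 2, 700 iterations, 3 seeds."""
    return PhantomConfig(), replace(TrainConfig(), batch_size=2, iterations=700)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, nets: NetBundle, cfg: TrainConfig,
                    extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(cfg).items()},
            "extra": extra or {}}
    np.savez(path, __meta__=json.dumps(meta), **nets.state_dict())


def load_checkpoint(path: str | Path) -> tuple[NetBundle, TrainConfig, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    raw = meta["config"]
    raw = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()}
    cfg = TrainConfig(**raw)
    nets = build_nets(feat_channels=cfg.feat_channels, n_classes=cfg.n_classes,
                      use_attention="self_attention" in cfg.active_losses,
                      backbone=cfg.backbone, seed=0)
    nets.load_state_dict(state)
    return nets, cfg, meta["extra"]
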