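"""Trainer: total-loss algebra, arm ladder structure, update isolation,
determinism, checkpoints, inference."""

from dataclasses import replace

import numpy as np
import pytest

from facps import trainer as tr
from facps.phantom import PhantomConfig, generate_dataset
from facps.trainer import (ARM_LADDER, LossBundle, TrainConfig, Trainer,
                           TrainingDiverged, arm_losses, desk_benchmark_config,
                           evaluate_target_dice, fit, infer, load_checkpoint,
                           total_loss)


@pytest.fixture(scope="module")
def ds():
    return generate_dataset(PhantomConfig(image_size=32, n_classes=3,
                                          n_train=6, n_test=2, seed=11))


def small_cfg(**over):
    base = dict(image_size=32, n_classes=3, feat_channels=8, batch_size=2,
                iterations=4, seeds=(0,), cps_rampup=(0.0, 0.25))
    base.update(over)
    return TrainConfig(**base)


def batch_from(ds, b=2):
    xs = np.stack([s.image.values for s in ds.train_source[:b]])
    ys = np.stack([s.label.values for s in ds.train_source[:b]])
    xt = np.stack([s.image.values for s in ds.train_target[:b]])
    return xs, ys, xt


# -- total loss --------------------------------------------------------------

def test_total_loss_with_unit_parts_is_seven():
    cfg = TrainConfig()
    parts = dict(l_s=0.5, l_st=0.5, l_gen_t=1.0, l_gen_s=1.0,
                 l_dacps_st=1.0, l_dacps_ts=1.0)
    # supervised part sums to 1: 1*1 + 1*1 + 1*1 + 2*1 + 2*1 = 7
    assert total_loss(parts, cfg) == 7.0


def test_total_loss_respects_ablation_arm():
    cfg = replace(TrainConfig(), ablation_arm="FA")
    parts = dict(l_s=1.0, l_st=0.0, l_gen_t=2.0, l_gen_s=3.0)
    assert total_loss(parts, cfg) == pytest.approx(1.0 + 2.0 + 3.0)
    with pytest.raises(ValueError, match="needs loss part"):
        total_loss(dict(l_s=1.0), cfg)


def test_total_loss_zero_lambdas_vanish():
    cfg = replace(TrainConfig(), lambda_gen_t=0, lambda_gen_s=0, lambda_s=0,
                  lambda_st=0, lambda_ts=0)
    parts = dict(l_s=5.0, l_st=5.0, l_gen_t=5.0, l_gen_s=5.0,
                 l_dacps_st=5.0, l_dacps_ts=5.0)
    assert total_loss(parts, cfg) == 0.0


# -- arms --------------------------------------------------------------------

def test_arm_ladder_is_nested():
    sets = [arm_losses(a) for a in ARM_LADDER]
    for prev, nxt in zip(sets, sets[1:]):
        assert prev < nxt


def test_invalid_arm_and_config_validation():
    with pytest.raises(ValueError, match="arm"):
        TrainConfig(ablation_arm="CPSOnly")
    with pytest.raises(ValueError):
        TrainConfig(lambda_s=-1.0)
    with pytest.raises(ValueError):
        TrainConfig(lr_seg_and_decoders=-1e-3)
    with pytest.raises(ValueError, match="pretrained"):
        TrainConfig(use_imagenet_init=True)


# -- optimizer grouping ------------------------------------------------------

def test_optimizer_groups_match_published_learning_rates():
    t = Trainer(small_cfg(), seed=0)
    assert t.group_lr("seg_streams") == pytest.approx(1e-3)
    assert t.group_lr("decoders") == pytest.approx(1e-3)
    assert t.group_lr("encoder") == pytest.approx(2e-4)
    assert t.group_lr("discriminators") == pytest.approx(2e-4)
    grouped = {id(p) for params, _, _ in t.param_groups.values() for p in params}
    every = {id(p) for m in t.nets.modules().values()
             for p in m.parameters().values()}
    assert grouped == every


# -- update isolation --------------------------------------------------------

def test_zero_learning_rates_freeze_all_parameters(ds):
    cfg = small_cfg(lr_seg_and_decoders=0.0, lr_encoder_and_discriminators=0.0,
                    ablation_arm="FACPS", augment=False)
    t = Trainer(cfg, seed=0)
    before = t.nets.state_dict()
    t.train_iteration(*batch_from(ds))
    after = t.nets.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_segonly_touches_only_encoder_and_streams(ds):
    cfg = small_cfg(ablation_arm="SegOnly", augment=False)
    t = Trainer(cfg, seed=0)
    before = t.nets.state_dict()
    out = t.train_iteration(*batch_from(ds))
    after = t.nets.state_dict()
    changed = {k for k in before if not np.array_equal(before[k], after[k])}
    assert changed
    assert all(k.split(".")[0] in ("encoder", "seg1", "seg2") for k in changed)
    assert out.l_gen_t is None and out.l_dacps_st is None


def test_full_arm_iteration_reports_every_loss(ds):
    cfg = small_cfg(ablation_arm="FACPS", augment=False,
                    cps_rampup=(0.0, 0.0))
    t = Trainer(cfg, seed=0)
    out = t.train_iteration(*batch_from(ds), cps_ramp=1.0)
    for key in ("l_s", "l_st", "l_gen_t", "l_gen_s", "l_dacps_st",
                "l_dacps_ts", "l_recon_s", "l_recon_t", "l_disc"):
        assert getattr(out, key) is not None
    assert out.total == pytest.approx(total_loss(out, cfg))
    assert out.d1_st >= 0.0 and out.d2_st >= 0.0


def test_nan_batch_aborts_with_diagnostic(ds):
    cfg = small_cfg(ablation_arm="SegOnly", augment=False)
    t = Trainer(cfg, seed=0)
    xs, ys, xt = batch_from(ds)
    xs = xs.copy()
    xs[0, 0, 0] = np.nan
    with pytest.raises(TrainingDiverged, match="bad_batch"):
        t.train_iteration(xs, ys, xt, batch_ids=["bad_batch"])


# -- fit ---------------------------------------------------------------------

def test_fit_writes_one_checkpoint_and_log_per_seed(tmp_path, ds):
    cfg = small_cfg(seeds=(0, 1, 2), iterations=2, ablation_arm="SegOnly")
    result = fit(cfg, dataset=ds, out_dir=tmp_path)
    assert len(result.runs) == 3
    for seed in (0, 1, 2):
        assert (tmp_path / f"checkpoint_seed{seed}.npz").exists()
        assert (tmp_path / f"train_log_seed{seed}.jsonl").exists()
    # attention gate starts at zero and is logged
    assert result.runs[0].log[0]["lambda_att"] == 0.0


def test_fit_rejects_empty_dataset():
    empty = generate_dataset(PhantomConfig(image_size=32, n_train=1, n_test=1))
    empty.train_source = []
    with pytest.raises(ValueError, match="empty"):
        fit(small_cfg(), dataset=empty)


def test_training_is_deterministic_under_fixed_seed(ds):
    cfg = small_cfg(ablation_arm="FA", iterations=3)
    logs = []
    for _ in range(2):
        result = fit(cfg, dataset=ds)
        logs.append([row["total"] for row in result.runs[0].log])
    assert logs[0] == logs[1]


# -- inference ---------------------------------------------------------------

def test_infer_deterministic_and_checkpoint_roundtrip(tmp_path, ds):
    cfg = small_cfg(ablation_arm="SegOnly", iterations=3)
    result = fit(cfg, dataset=ds, out_dir=tmp_path)
    nets = result.runs[0].nets
    images = [s.image for s in ds.test_target]
    m1 = infer(images, nets)
    m2 = infer(images, nets)
    assert all(np.array_equal(a.values, b.values) for a, b in zip(m1, m2))

    nets2, cfg2, extra = load_checkpoint(tmp_path / "checkpoint_seed0.npz")
    assert cfg2.ablation_arm == "SegOnly"
    assert extra["seed"] == 0
    m3 = infer(images, nets2)
    assert all(np.array_equal(a.values, b.values) for a, b in zip(m1, m3))

    d = evaluate_target_dice(nets, ds.test_target, cfg.n_classes)
    assert 0.0 <= d <= 100.0


def test_stream_consensus_and_disagreement(ds):
    cfg = small_cfg(ablation_arm="SegOnly", iterations=2)
    nets = fit(cfg, dataset=ds).runs[0].nets
    img = ds.test_target[0].image
    ens = infer([img], nets)[0].values
    s1 = infer([img], nets, stream="1")[0].values
    s2 = infer([img], nets, stream="2")[0].values
    agree = s1 == s2
    # wherever the streams agree the ensemble must follow them
    assert np.array_equal(ens[agree], s1[agree])


def test_desk_benchmark_config_shape():
    pcfg, tcfg = desk_benchmark_config()
    assert pcfg.image_size == tcfg.image_size == 64
    assert tcfg.batch_size == 2 and len(tcfg.seeds) == 3


def test_loss_bundle_dict_roundtrip():
    b = LossBundle(l_s=1.0, total=1.0)
    d = b.as_dict()
    assert d["l_s"] == 1.0 and "l_dacps_st" in d
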