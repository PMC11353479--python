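# Methods

`facps` implements an unsupervised domain-adaptation (UDA) framework for
cross-modality medical image segmentation: a labeled source modality and
an unlabeled target modality showing the same kind of anatomy are bridged
by (i) a bidirectional feature-alignment sub-network built around one
shared encoder, and (ii) a dual-stream segmentation sub-network trained
with a distance-aware cross-pseudo-supervision loss.  The package runs
end-to-end on synthetic two-modality phantoms, so every mechanism can be
exercised and tested on a laptop-class CPU without external data.

## Model

**Feature alignment.**  A single encoder `E` maps any 2-D slice
(preprocessed to `[-1, 1]`) to a latent feature grid.  Two
domain-specific decoders `G_s`, `G_t` (same architecture, disjoint
parameters) render latents as source- or target-style images (tanh
output); two patch discriminators `D_s`, `D_t` judge realness.  The
losses per domain are

- adversarial: `L_adv^t = E[log D_t(x_t)] + E[log(1 - D_t(G_t(E(x_s))))]`
  (symmetrically for the source side), trained as binary cross-entropy
  with the non-saturating generator variant;
- reconstruction: `L_recon^t = E ||G_t(E(x_t)) - x_t||_1` (and the
  source analogue) — re-decoding an image into its own domain;
- combined: `L_gen^d = lambda_recon * L_recon^d + lambda_adv * L_adv^d`
  with `lambda_recon = 1.0`, `lambda_adv = 0.02`.

In addition to the same-domain reconstructions the trainer enforces the
cycle form of consistency: the generated fake is reverse-transformed and
must reproduce the original input (`G_s(E(G_t(E(x_s)))) ~ x_s` in the
source step, `G_t(E(G_s(E(x_t)))) ~ x_t` in the target step), each
weighted by `lambda_recon`.  With auto-encoding alone the source decoder
is never trained on target-derived latents, and we found it unusable on
them (its renderings of real target images carried essentially no
anatomy); the cycle terms close that hole.

**Self-attention.**  A non-local attention block sits on the encoder's
last convolutional layer: 1x1 convolutions produce query/key/value/output
maps, `A = softmax(C1(f)^T C2(f))` is the row-stochastic attention map
over the N = H*W positions, `f_att = C4(A C3(f))`, and the output is
`lambda_att * f_att + f` with the scalar gate `lambda_att` learnable and
initialised to 0 — a fresh encoder is exactly attention-free, and the
model opens the attention path only as far as it helps.

**Dual-stream segmentation.**  Two segmentation heads `S(theta_1)`,
`S(theta_2)` with one structure but independent initialisation sit on the
shared encoder.  For an image pair (original `x`, cross-domain
translation `x'`), each head predicts both views
(`p_o_i = S(theta_i)(E(x))`, `p_c_i = S(theta_i)(E(x'))`), and the
per-head ensemble is the midpoint `p_avg_i = (p_o_i + p_c_i)/2`.  Each
head's hard pseudo-label `P_i = onehot(argmax p_avg_i)` (gradient-free;
argmax ties resolve to the lowest class index) supervises the *other*
head:

```
L_dacps = E[ e^{-v_1} CE(p_avg_2, P_1) ] + d_1
        + E[ e^{-v_2} CE(p_avg_1, P_2) ] + d_2
```

where `v_i` is the per-pixel KL pseudo-distance
`sum_c p_c_i log(p_c_i / p_o_i)` between a head's translated-view and
original-view predictions, and `d_i = E[v_i]` is its batch mean.  A pixel
whose two views disagree is deemed unreliable and its cross-entropy is
down-weighted by `e^{-v_i}`; with `v = d = 0` the loss reduces exactly to
plain cross-pseudo-supervision (CPS), which is also the code path used
for the CPS-only ablation arm.  The loss is applied in both directions:
on `(x_s, x_{s->t})` and on `(x_t, x_{t->s})`, with no ground truth in
either.

The supervised part is a soft Dice loss over foreground classes on the
source predictions, `L_s = L_Dice(p_o1, y_s) + L_Dice(p_o2, y_s)`
(smoothing 1e-5), plus — from the FA arm upward — the same Dice loss on
the predictions for the translated source image `x_{s->t}`, whose labels
are known because translation preserves the pixel grid.

**Total objective.**

```
L = lambda_gen_t L_gen^t + lambda_gen_s L_gen^s + lambda_s L_s
  + lambda_st L_dacps^{s->t} + lambda_ts L_dacps^{t->s}
```

with defaults `lambda_gen_t = lambda_gen_s = lambda_s = 1.0`,
`lambda_st = lambda_ts = 2.0`.

## Update schedule and optimisation

Each iteration runs up to four sequential Adam updates:

1. `D_t`, `D_s` on detached translations (one discriminator step per
   iteration);
2. `E`, `G_t` minimising `L_gen^t` (+ the target cycle term);
3. `E`, `G_s`, `S(theta)` minimising `L_gen^s + L_s (+ L_st)`;
4. `S(theta)` (and `E`, switchable via `update_encoder_in_dacps`,
   default on) minimising `lambda_st L_dacps^{s->t} + lambda_ts
   L_dacps^{t->s}`.

Learning rates follow the published configuration: 1e-3 for the
segmentation streams and decoders, 2e-4 for the shared encoder and the
discriminators; Adam betas are (0.5, 0.999) for GAN components and
(0.9, 0.999) for segmentation.  Default batch size is 4 (the desk
benchmark uses 2).

Three numerical choices matter in practice and are deliberate:

- **Pseudo-distance gradients.**  The `e^{-v}` weights and the `+d`
  regularisers enter the loss as *detached* quantities: they modulate and
  report the supervision but carry no gradient.  Letting the KL term
  backpropagate drags the reliable original-view prediction toward the
  unreliable translated-view one; in our runs that variant cut source
  Dice from ~83% to ~24%.
- **Warm-up ramp for step 4.**  The cross-pseudo-supervision loss is
  scaled by a ramp rising linearly from 0 to 1 between 40% and 70% of
  total iterations.  Without it, hard pseudo-labels at initialisation
  lock both streams onto the majority class within a few dozen
  iterations at desk batch sizes; opening the ramp only once the
  translators have matured is what lets the cross-supervised arms
  improve on plain feature alignment at this scale.
- **Per-pixel weighting.**  `v_i` is a per-pixel map, not one scalar per
  batch: a scalar weight is ~1 early in training (the two views, both
  near-uniform, have tiny KL) and cannot mute the individual unreliable
  pixels that cause the damage.

## Architecture (desk backbone)

The default backbone is a deliberately small CNN (the `backbone`
config also offers a deeper residual variant, `resnet_small`): encoder
= two stride-2 3x3 convs + one stride-1 conv (16 feature channels,
total stride 4), instance-normalised; decoders = residual block + two
nearest-upsample+conv stages; discriminators = four 3x3 convs emitting a
patch realness map; seg heads = conv + 1x1 classifier + bilinear
upsampling + channel softmax.  Instance normalisation is used throughout
the translation components, as is standard in this family of
image-translation networks; it removes per-image global intensity
statistics — precisely the cue that separates the two phantom modalities
— and without it the shared encoder fails to align them at all.
Pretrained-backbone initialisation is not shipped
(`use_imagenet_init=True` raises).

All networks, losses and the optimiser run on a compact numpy
reverse-mode autodiff engine (`facps.nn`) written for this package:
float32, single-threaded, deterministic under fixed seeds, with conv2d
via im2col/BLAS (a compiled kernel covers thin output layers) — small
enough to audit, fast enough for the desk benchmark.

## Synthetic phantom benchmark

`PhantomConfig()` defines the study conditions: 64x64 slices, 5 classes
(background + four organ-like structures), 100 paired training
anatomies (hence 200 training slices across the two modalities, with
target labels withheld), 20 test anatomies, seed 0.  Each anatomy is a
set of random ellipses; each foreground class clusters around its own
quadrant anchor, mimicking organs that occupy distinct body regions.
Per-class intensities are drawn from narrow Gaussians (mean = the class
base level, sd 0.02), the image is shaded by a low-frequency
multiplicative bias field (amplitude 0.15) and corrupted by additive
Gaussian noise, then normalised like any other slice.  The source
transfer uses increasing base intensities and noise sd 0.05; the target
transfer inverts the intensity ranking, applies gamma 1.8 and doubles
the noise.  The inversion is the domain gap: a segmenter trained on
source alone collapses on target (few-percent Dice), while the
intensity ordering of the anatomy is perfectly recoverable in principle.

What the phantoms do *not* model: imaging physics (beam hardening,
k-space artefacts), 3-D context, anatomical shape priors, class
imbalance beyond background dominance, or inter-patient appearance
variation.  Passing the benchmark therefore demonstrates that the
losses, update schedule and adaptation mechanics behave as designed —
not that the method reaches any particular accuracy on real CT/MR data.

## Desk benchmark problem sizes

`desk_benchmark_config()` trains every ablation arm for 700 iterations
at batch 2 with three model initialisations — sizes chosen so the whole
5-arm x 3-seed ladder runs on one CPU core in roughly a quarter of an
hour.  The ablation arms are nested as in the ablation-study design:
SegOnly (supervised Dice only), FA (+ translated-image supervision and
both generator losses), FA+CPS (+ plain cross-pseudo-supervision),
FA+DACPS (distance-aware weighting and regularisers), FACPS
(+ self-attention).

## Evaluation

Dice is `2|P n G| / (|P| + |G|)` per class (1.0 when both masks are
empty, 0.0 when exactly one is).  Surfaces are 8-connectivity border
pixels (mask minus its erosion); ASD is the mean of the two directed
mean nearest-surface distances, HD the maximum of the two directed
maxima (HD95 behind a flag), both scaled by pixel spacing.  A class
absent from either mask yields a *missing* surface metric (excluded from
averages and logged), never a silent zero.  Experiment tables report
mean ± population std across seeds, per class and averaged.

## Known limitations

- The desk-scale GAN reaches moderate translation fidelity within the
  benchmark's iteration budget; target-domain Dice is far below the
  supervised ceiling, and the margins between the cross-supervised arms
  are small relative to seed noise.
- The per-slice z-score choice (statistics per slice, not per volume)
  and the ASD aggregation (per-case metric, unweighted mean over cases)
  are conventions the evaluation fixes explicitly; other choices exist.
- `L_dacps` uses hard argmax pseudo-labels without confidence
  thresholding or class balancing, by design.
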