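"""Synthetic two-modality phantom datasets for domain-adaptation benchmarks.

Each phantom is a multi-class "anatomy" of random ellipses (background is
class 0) rendered twice: once with a source-modality intensity transfer
function and once with a target-modality transfer that, by default,
inverts the intensity ranking of the classes, applies a gamma curve and
doubles the noise.  A segmenter trained on the source modality alone
therefore collapses on the target modality, which is exactly the domain
gap an adaptation method has to close.  Both renderings of one latent
anatomy share the same label map, and target-domain training samples
carry no label.

Randomness is counter-split from one root seed: sample ``i`` always sees
the same stream no matter how many samples are generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .io_prep import ImageGrid, LabelMap, preprocess_slice, write_slice

__all__ = [
    "TransferParams",
    "PhantomConfig",
    "DomainSample",
    "PhantomDataset",
    "render_label_map",
    "render_modality",
    "generate_dataset",
    "save_dataset",
]


@dataclass(frozen=True)
class TransferParams:
    """Piecewise-monotone intensity transfer: per-class base intensity on
    [0, 1], optional global inversion, gamma exponent, and the std of the
    narrow per-sample Gaussian the class intensity is drawn from (so the
    per-class value is a distribution mean, not a constant)."""

    class_bases: tuple[float, ...]
    invert: bool = False
    gamma: float = 1.0
    intensity_jitter: float = 0.02

    def class_levels(self, rng: np.random.Generator) -> np.ndarray:
        levels = np.asarray(self.class_bases, dtype=np.float64)
        if self.intensity_jitter > 0:
            levels = levels + rng.normal(0.0, self.intensity_jitter, size=levels.shape)
        levels = np.clip(levels, 0.0, 1.0)
        if self.invert:
            levels = 1.0 - levels
        return np.clip(levels, 1e-6, 1.0) ** self.gamma


def _default_bases(n_classes: int) -> tuple[float, ...]:
    # background dark, foreground classes spread over the bright range
    if n_classes < 2:
        raise ValueError("need at least background + one foreground class")
    fg = np.linspace(0.35, 0.9, n_classes - 1)
    return tuple([0.12] + list(fg))


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for the two-modality phantom benchmark."""

    image_size: int = 64
    n_classes: int = 5
    shapes_per_class: tuple[int, int] = (1, 2)
    source_transfer: TransferParams | None = None
    target_transfer: TransferParams | None = None
    noise_sigma_source: float = 0.05
    noise_sigma_target: float = 0.10
    bias_field_amplitude: float = 0.15
    n_train: int = 100
    n_test: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.noise_sigma_source < 0 or self.noise_sigma_target < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.source_transfer is None:
            object.__setattr__(
                self, "source_transfer",
                TransferParams(class_bases=_default_bases(self.n_classes)),
            )
        if self.target_transfer is None:
            object.__setattr__(
                self, "target_transfer",
                TransferParams(class_bases=_default_bases(self.n_classes),
                               invert=True, gamma=1.8),
            )
        for tp in (self.source_transfer, self.target_transfer):
            if len(tp.class_bases) != self.n_classes:
                raise ValueError("transfer class_bases must have one entry per class")


@dataclass
class DomainSample:
    """One slice from one modality; target training samples have label=None."""

    image: ImageGrid
    label: LabelMap | None
    domain: str
    id: str


@dataclass
class PhantomDataset:
    train_source: list[DomainSample]
    train_target: list[DomainSample]
    test_source: list[DomainSample]
    test_target: list[DomainSample]
    # evaluation-only ground truth for the unlabeled target training slices
    hidden_train_target_labels: dict[str, LabelMap] = field(default_factory=dict)
    config: PhantomConfig | None = None


def _rng_for(cfg: PhantomConfig, role: int, index: int) -> np.random.Generator:
    """Counter-split stream: stable per (role, index) regardless of counts."""
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(role, index))
    return np.random.default_rng(ss)


# quadrant anchors: organ-like layouts keep different structures in
# different image regions (classes still overwrite in index order if
# shapes happen to collide)
_ANCHORS = np.array([[0.32, 0.32], [0.32, 0.68], [0.68, 0.32], [0.68, 0.68]])


def render_label_map(cfg: PhantomConfig, rng: np.random.Generator) -> LabelMap:
    """Random-ellipse anatomy; each class's shapes cluster around a
    class-specific anchor (mimicking organs occupying distinct regions);
    classes are drawn in index order so later classes overwrite earlier
    ones where shapes overlap."""
    n = cfg.image_size
    lab = np.zeros((n, n), dtype=np.int64)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    lo, hi = cfg.shapes_per_class
    for cls in range(1, cfg.n_classes):
        n_shapes = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
        anchor = _ANCHORS[(cls - 1) % len(_ANCHORS)]
        for _ in range(n_shapes):
            cy, cx = (anchor + rng.uniform(-0.08, 0.08, size=2)) * n
            ay, ax = rng.uniform(0.09, 0.18, size=2) * n
            theta = rng.uniform(0.0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (yy - cy) * ct + (xx - cx) * st
            v = -(yy - cy) * st + (xx - cx) * ct
            lab[(u / ay) ** 2 + (v / ax) ** 2 <= 1.0] = cls
    return LabelMap(lab)


def _bias_field(n: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency multiplicative shading in [1-a, 1+a]."""
    if amplitude <= 0:
        return np.ones((n, n))
    coarse = rng.normal(0.0, 1.0, size=(4, 4))
    fld = resize(coarse, (n, n), order=3, mode="edge", anti_aliasing=False)
    span = np.abs(fld).max()
    if span > 0:
        fld = fld / span
    return 1.0 + amplitude * fld


def render_modality(
    label: LabelMap,
    transfer: TransferParams,
    noise_sigma: float,
    rng: np.random.Generator,
    bias_field_amplitude: float = 0.0,
    normalize: bool = True,
) -> ImageGrid:
    """Render one modality of a label map.

    image = bias_field * transfer(class levels) + Gaussian noise, then the
    standard slice normalisation (z-score + [-1, 1] map) unless
    ``normalize=False`` (useful for inspecting the raw transfer output).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    levels = transfer.class_levels(rng)
    if label.values.max() >= len(levels):
        raise ValueError("transfer has fewer class levels than label classes")
    img = levels[label.values]
    img = img * _bias_field(label.values.shape[0], bias_field_amplitude, rng)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    grid = ImageGrid(img.astype(np.float32))
    if normalize:
        grid = preprocess_slice(grid, out_size=label.values.shape[0])
    return grid


def _make_pair(cfg: PhantomConfig, role: int, index: int, prefix: str):
    rng = _rng_for(cfg, role, index)
    label = render_label_map(cfg, rng)
    src = render_modality(label, cfg.source_transfer, cfg.noise_sigma_source,
                          rng, cfg.bias_field_amplitude)
    tgt = render_modality(label, cfg.target_transfer, cfg.noise_sigma_target,
                          rng, cfg.bias_field_amplitude)
    sid = f"{prefix}{index:04d}"
    return sid, label, src, tgt


def generate_dataset(cfg: PhantomConfig) -> PhantomDataset:
    """Generate train/test splits with disjoint latent anatomies.

    Source and target training sets are paired (same anatomy, two
    modalities); the target training labels are withheld from the sample
    objects and kept only in ``hidden_train_target_labels``.
    """
    if cfg.n_train <= 0 or cfg.n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    ds = PhantomDataset([], [], [], [], {}, cfg)
    for i in range(cfg.n_train):
        sid, label, src, tgt = _make_pair(cfg, 0, i, "train")
        ds.train_source.append(DomainSample(src, label, "source", f"{sid}_src"))
        ds.train_target.append(DomainSample(tgt, None, "target", f"{sid}_tgt"))
        ds.hidden_train_target_labels[f"{sid}_tgt"] = label
    for i in range(cfg.n_test):
        sid, label, src, tgt = _make_pair(cfg, 1, i, "test")
        ds.test_source.append(DomainSample(src, label, "source", f"{sid}_src"))
        ds.test_target.append(DomainSample(tgt, label, "target", f"{sid}_tgt"))
    return ds


def save_dataset(ds: PhantomDataset, out_dir: str | Path, fmt: str = "png") -> Path:
    """Write images/masks plus a JSON manifest; returns the manifest path."""
    if fmt not in ("png", "nii.gz"):
        raise ValueError("fmt must be 'png' or 'nii.gz'")
    out = Path(out_dir)
    entries = []
    splits = [
        ("train_source", ds.train_source),
        ("train_target", ds.train_target),
        ("test_source", ds.test_source),
        ("test_target", ds.test_target),
    ]
    for split, samples in splits:
        for s in samples:
            img_path = out / split / f"{s.id}_img.{fmt}"
            write_slice(img_path, s.image)
            entry = {
                "id": s.id,
                "split": split,
                "domain": s.domain,
                "image": str(img_path.relative_to(out)),
                "label": None,
                "seed": ds.config.seed if ds.config else None,
            }
            if s.label is not None:
                lbl_path = out / split / f"{s.id}_mask.{fmt}"
                write_slice(lbl_path, s.label)
                entry["label"] = str(lbl_path.relative_to(out))
            entries.append(entry)
    manifest = out / "manifest.json"
    manifest.parent.mkdir(parents=True, exist_ok=True)
    manifest.write_text(json.dumps(entries, indent=1))
    return manifest


def desk_config(**overrides) -> PhantomConfig:
    """The default desk-scale benchmark conditions (64 px, 5 classes,
    100 paired training anatomies, 20 test anatomies)."""
    return replace(PhantomConfig(), **overrides) if overrides else PhantomConfig()
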