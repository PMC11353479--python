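"""Image/mask I/O and the slice preprocessing + augmentation pipeline.

Images are single-channel 2-D slices.  Preprocessing resamples to a square
working size, z-scores the intensities and affinely maps them to [-1, 1]
(the input range the translation decoders' tanh output matches).
Augmentation applies one shared geometric transform (small rotation +
random crop) to an image and its label map, with bilinear interpolation
for the image and nearest-neighbour for the label.

Supported formats: PNG (8-bit) and NIfTI (.nii / .nii.gz, spacing kept).
Coordinates are row-major, origin top-left, 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

log = logging.getLogger("facps")

__all__ = [
    "ImageGrid",
    "LabelMap",
    "read_slice",
    "write_slice",
    "preprocess_slice",
    "augment_pair",
]


@dataclass
class ImageGrid:
    """A single-channel 2-D intensity field with optional physical spacing."""

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError(f"ImageGrid expects a 2-D array, got {self.values.shape}")


@dataclass
class LabelMap:
    """Per-pixel integer class map; class 0 is background."""

    values: np.ndarray
    class_names: list[str] = field(default_factory=list)
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"LabelMap expects a 2-D array, got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("LabelMap values must be integers")
            arr = arr.astype(np.int64)
        if arr.min() < 0:
            raise ValueError("LabelMap values must be non-negative")
        self.values = arr.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return int(self.values.max()) + 1


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_slice(path: str | Path, kind: str = "image") -> ImageGrid | LabelMap:
    """Read a 2-D slice; ``kind`` selects image (float) vs mask (integer)."""
    path = Path(path)
    if kind not in ("image", "mask"):
        raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single 2-D slice, got {data.shape}")
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1]))
    else:
        data = np.asarray(iio.imread(path)).astype(np.float64)
        if data.ndim == 3:  # collapse RGB(A) written by other tools
            data = data[..., 0]
        spacing = (1.0, 1.0)
    if kind == "mask":
        if not np.all(data == np.round(data)):
            raise ValueError(f"{path}: mask contains non-integer values")
        return LabelMap(data.astype(np.int64), spacing=spacing)
    return ImageGrid(data.astype(np.float32), spacing=spacing)


def write_slice(path: str | Path, grid: ImageGrid | LabelMap) -> None:
    """Write a slice; PNG images are rescaled from [-1, 1] to 8-bit."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    is_mask = isinstance(grid, LabelMap)
    if _is_nifti(path):
        data = grid.values.astype(np.int16 if is_mask else np.float32)
        affine = np.diag([grid.spacing[0], grid.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(data[..., None], affine), str(path))
        return
    if is_mask:
        if grid.values.max() > 255:
            raise ValueError("PNG masks support at most 256 classes")
        iio.imwrite(path, grid.values.astype(np.uint8))
    else:
        v = grid.values.astype(np.float64)
        v = np.clip((v + 1.0) * 127.5, 0, 255)  # [-1,1] -> 8-bit
        iio.imwrite(path, np.round(v).astype(np.uint8))


def preprocess_slice(img: ImageGrid, out_size: int) -> ImageGrid:
    """Resample to ``out_size`` square, z-score, then map min/max to [-1, 1].

    A constant-intensity slice has no contrast to normalise; it is mapped to
    the all-zero grid (with a warning) so batched pipelines never abort.
    """
    v = img.values.astype(np.float64)
    if v.shape != (out_size, out_size):
        v = resize(v, (out_size, out_size), order=1, mode="edge",
                   anti_aliasing=v.shape[0] > out_size, preserve_range=True)
    std = v.std()
    if std == 0:
        log.warning("preprocess_slice: constant slice mapped to zeros")
        return ImageGrid(np.zeros((out_size, out_size), dtype=np.float32),
                         spacing=img.spacing)
    v = (v - v.mean()) / std
    lo, hi = v.min(), v.max()
    v = 2.0 * (v - lo) / (hi - lo) - 1.0
    return ImageGrid(v.astype(np.float32), spacing=img.spacing)


def _rotate_crop(arr: np.ndarray, angle: float, box: tuple[int, int, int, int],
                 order: int) -> np.ndarray:
    """Rotate about the centre then crop ``box`` and resize back."""
    h, w = arr.shape
    out = arr
    if angle != 0.0:
        out = ndi.rotate(out.astype(np.float64), angle, reshape=False,
                         order=order, mode="nearest")
    r0, c0, bh, bw = box
    if (r0, c0, bh, bw) != (0, 0, h, w):
        out = out[r0:r0 + bh, c0:c0 + bw]
        out = resize(out.astype(np.float64), (h, w), order=order, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out


def augment_pair(
    img: ImageGrid,
    lbl: LabelMap | None,
    rng: np.random.Generator,
    rotation_deg: float = 15.0,
    crop_scale: tuple[float, float] = (0.85, 1.0),
) -> tuple[ImageGrid, LabelMap | None]:
    """Random rotation + crop, shared between image and (optional) label."""
    h, w = img.values.shape
    angle = float(rng.uniform(-rotation_deg, rotation_deg)) if rotation_deg > 0 else 0.0
    s = float(rng.uniform(crop_scale[0], crop_scale[1]))
    bh, bw = max(1, int(round(h * s))), max(1, int(round(w * s)))
    r0 = int(rng.integers(0, h - bh + 1))
    c0 = int(rng.integers(0, w - bw + 1))
    box = (r0, c0, bh, bw)
    out_img = ImageGrid(
        _rotate_crop(img.values, angle, box, order=1).astype(np.float32),
        spacing=img.spacing,
    )
    out_lbl = None
    if lbl is not None:
        out_lbl = LabelMap(
            np.round(_rotate_crop(lbl.values.astype(np.float64), angle, box, order=0))
            .astype(np.int64),
            class_names=lbl.class_names,
            spacing=lbl.spacing,
        )
    return out_img, out_lbl


def write_manifest(path: str | Path, entries: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(entries, indent=1))


def read_manifest(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
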