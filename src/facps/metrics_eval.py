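"""Segmentation evaluation: Dice, average surface distance, Hausdorff
distance, and mean +/- std experiment tables across seeds.

Surfaces are border pixels of a binary mask under 8-connectivity (mask
minus its erosion); distances between the two surface point sets use a
KD-tree, scaled by pixel spacing.  ASD is the mean of the two directed
mean nearest-surface distances; HD is the maximum of the two directed
maxima (HD95 uses the 95th percentile instead).  A class absent from
either mask has no surface: the metric is reported as missing (NaN) and
excluded from averages rather than silently zeroed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .io_prep import LabelMap, read_slice

log = logging.getLogger("facps")

__all__ = [
    "dice",
    "surface_points",
    "surface_distances",
    "EmptyMaskError",
    "evaluate_run",
    "summarize",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """Raised when a surface metric is requested for an absent class."""


def _binary(mask: LabelMap | np.ndarray, cls: int | None) -> np.ndarray:
    arr = mask.values if isinstance(mask, LabelMap) else np.asarray(mask)
    return arr.astype(bool) if cls is None else arr == cls


def dice(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray,
         cls: int | None = None) -> float:
    """Overlap 2|P∩G|/(|P|+|G|); 1.0 if both masks empty, 0.0 if only one."""
    p = _binary(pred, cls)
    g = _binary(truth, cls)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def surface_points(mask: np.ndarray, spacing=(1.0, 1.0)) -> np.ndarray:
    """Border pixels (8-connectivity erosion difference) as (N, 2) physical
    coordinates."""
    mask = mask.astype(bool)
    border = mask & ~binary_erosion(mask, structure=_STRUCT8, border_value=0)
    pts = np.argwhere(border).astype(np.float64)
    return pts * np.asarray(spacing, dtype=np.float64)


def surface_distances(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray,
                      cls: int | None = None, spacing=(1.0, 1.0),
                      hd_percentile: float = 100.0) -> tuple[float, float]:
    """(ASD, HD) between the class surfaces of two masks.

    ASD = mean of the two directed mean nearest-surface distances;
    HD = max of the two directed maxima (or the given percentile).
    """
    p = _binary(pred, cls)
    g = _binary(truth, cls)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not p.any() or not g.any():
        raise EmptyMaskError(f"class {cls}: undefined surface (empty mask)")
    sp = surface_points(p, spacing)
    sg = surface_points(g, spacing)
    d_pg, _ = cKDTree(sg).query(sp)   # pred surface -> nearest truth surface
    d_gp, _ = cKDTree(sp).query(sg)
    asd = 0.5 * (float(d_pg.mean()) + float(d_gp.mean()))
    if hd_percentile >= 100.0:
        hd = max(float(d_pg.max()), float(d_gp.max()))
    else:
        hd = max(float(np.percentile(d_pg, hd_percentile)),
                 float(np.percentile(d_gp, hd_percentile)))
    return asd, hd


def _metric_row(pred: LabelMap, truth: LabelMap, n_classes: int,
                spacing, hd_percentile: float) -> dict:
    row = {}
    for cls in range(1, n_classes):
        row[f"dice_{cls}"] = dice(pred, truth, cls)
        try:
            asd, hd = surface_distances(pred, truth, cls, spacing, hd_percentile)
        except EmptyMaskError:
            log.info("class %d missing in a mask pair; surface metrics skipped", cls)
            asd, hd = np.nan, np.nan
        row[f"asd_{cls}"] = asd
        row[f"hd_{cls}"] = hd
    return row


def evaluate_run(pred_dir: str | Path, truth_dir: str | Path,
                 seeds: list[int] | None = None, n_classes: int | None = None,
                 class_names: list[str] | None = None,
                 hd_percentile: float = 100.0,
                 out_dir: str | Path | None = None) -> pd.DataFrame:
    """Score predicted masks against reference masks.

    Layout: ``truth_dir/<id>_mask.<ext>`` and, per seed,
    ``pred_dir/seed<seed>/<id>_mask.<ext>`` (or flat in ``pred_dir`` when
    ``seeds`` is None).  Writes ``metrics.csv``/``metrics.md`` (per-class
    and average mean +/- std across seeds) when ``out_dir`` is given.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    truth_files = sorted(truth_dir.glob("*_mask.*"))
    if not truth_files:
        raise FileNotFoundError(f"no *_mask.* files in {truth_dir}")
    seed_list = [None] if seeds is None else list(seeds)
    rows = []
    for seed in seed_list:
        base = pred_dir if seed is None else pred_dir / f"seed{seed}"
        for tf in truth_files:
            pf = base / tf.name
            if not pf.exists():
                raise FileNotFoundError(f"missing prediction {pf}")
            truth = read_slice(tf, kind="mask")
            pred = read_slice(pf, kind="mask")
            nc = n_classes or max(truth.n_classes, pred.n_classes)
            row = _metric_row(pred, truth, nc, truth.spacing, hd_percentile)
            row["id"] = tf.name.replace("_mask", "").split(".")[0]
            row["seed"] = 0 if seed is None else seed
            rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "metrics.csv", index=False)
        summary = summarize(df, class_names=class_names)
        summary.to_csv(out_dir / "metrics_summary.csv")
        (out_dir / "metrics.md").write_text(summary.to_markdown())
    return df


def summarize(df: pd.DataFrame, class_names: list[str] | None = None) -> pd.DataFrame:
    """Per-class and Average rows of mean +/- std across seeds (each seed is
    first averaged over cases; missing surface metrics are excluded)."""
    metric_cols = [c for c in df.columns if c.split("_")[0] in ("dice", "asd", "hd")]
    per_seed = df.groupby("seed")[metric_cols].mean()  # NaN-aware
    classes = sorted({int(c.rsplit("_", 1)[1]) for c in metric_cols})
    out = {}
    for kind in ("dice", "asd", "hd"):
        cols = [f"{kind}_{c}" for c in classes if f"{kind}_{c}" in per_seed]
        if not cols:
            continue
        scale = 100.0 if kind == "dice" else 1.0
        row_mean, row_std = {}, {}
        for c, col in zip(classes, cols):
            name = (class_names[c - 1] if class_names and c - 1 < len(class_names)
                    else f"class_{c}")
            row_mean[name] = per_seed[col].mean() * scale
            row_std[name] = per_seed[col].std(ddof=0) * scale
        avg = per_seed[cols].mean(axis=1)
        row_mean["Average"] = avg.mean() * scale
        row_std["Average"] = avg.std(ddof=0) * scale
        out[f"{kind}_mean"] = row_mean
        out[f"{kind}_std"] = row_std
    return pd.DataFrame(out).T
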