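"""Per-cell morphology and fluorescence measurement.

Produces the per-cell data table (size, total and average-per-pixel
fluorescence per channel, background-subtracted) and a granularity score
based on a grayscale opening spectrum of the transmitted-light channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from skimage import morphology

from .imio import Tile
from .segment import CellObject

__all__ = [
    "CellRecord",
    "measure_cell",
    "measure_cells",
    "granularity_score",
    "granularity_spectrum",
    "morphology_scatter",
    "records_to_frame",
]

GRANULARITY_MAX_RADIUS = 8


@dataclass
class CellRecord:
    patient_id: int
    tile_index: int
    object_size: int  # px^2
    granularity: float
    mt_total: float
    mt_mean: float
    ppix_total: float
    ppix_mean: float


def _background(channel: np.ndarray, object_mask: np.ndarray) -> float:
    bg = channel[~object_mask]
    return float(np.median(bg)) if bg.size else 0.0


def _object_mask(shape, objects) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for o in objects:
        mask[o.coords[:, 0], o.coords[:, 1]] = True
    return mask


def measure_cell(tile: Tile, obj: CellObject,
                 all_objects: list[CellObject] | None = None,
                 with_granularity: bool = True) -> CellRecord:
    """Measure one retained singlet.

    Background per channel is the median over non-object pixels (all
    objects if given, else this object's complement); per-pixel signal is
    max(raw - background, 0); totals sum over the pixel set and means are
    totals / area, so mean * area == total exactly.
    """
    if obj.coords.size == 0:
        raise ValueError("empty pixel set")
    mask = _object_mask(tile.shape, all_objects if all_objects else [obj])
    rows, cols = obj.coords[:, 0], obj.coords[:, 1]

    def channel_totals(channel: np.ndarray) -> float:
        bg = _background(np.asarray(channel, dtype=float), mask)
        sig = np.maximum(channel[rows, cols].astype(float) - bg, 0.0)
        return float(sig.sum())

    mt_total = channel_totals(tile.mt)
    ppix_total = channel_totals(tile.ppix)
    area = int(obj.area)
    gran = granularity_score(tile.trans, obj, object_mask=mask) if with_granularity else np.nan
    return CellRecord(
        patient_id=tile.subject_id, tile_index=tile.tile_index,
        object_size=area, granularity=gran,
        mt_total=mt_total, mt_mean=mt_total / area,
        ppix_total=ppix_total, ppix_mean=ppix_total / area)


def measure_cells(tile: Tile, objects: list[CellObject],
                  with_granularity: bool = True) -> list[CellRecord]:
    """Measure all retained objects with a shared background mask (fast path)."""
    if not objects:
        return []
    mask = _object_mask(tile.shape, objects)
    mt = np.asarray(tile.mt, dtype=float)
    ppix = np.asarray(tile.ppix, dtype=float)
    mt_bg = _background(mt, mask)
    ppix_bg = _background(ppix, mask)
    records = []
    for obj in objects:
        rows, cols = obj.coords[:, 0], obj.coords[:, 1]
        mt_total = float(np.maximum(mt[rows, cols] - mt_bg, 0.0).sum())
        ppix_total = float(np.maximum(ppix[rows, cols] - ppix_bg, 0.0).sum())
        area = int(obj.area)
        gran = granularity_score(tile.trans, obj, object_mask=mask) if with_granularity else np.nan
        records.append(CellRecord(
            patient_id=tile.subject_id, tile_index=tile.tile_index,
            object_size=area, granularity=gran,
            mt_total=mt_total, mt_mean=mt_total / area,
            ppix_total=ppix_total, ppix_mean=ppix_total / area))
    return records


def granularity_spectrum(trans: np.ndarray, obj: CellObject,
                         max_radius: int = GRANULARITY_MAX_RADIUS,
                         object_mask: np.ndarray | None = None) -> np.ndarray:
    """Opening spectrum g_r = (I_{r-1} - I_r) / I_0 for r = 1..max_radius.

    I_r is the within-object integrated transmitted-light signal after
    grayscale opening with a disk of radius r, on the background-subtracted,
    contrast-inverted image (cells bright); I_0 is the unopened value.
    """
    trans = np.asarray(trans, dtype=float)
    if object_mask is None:
        object_mask = _object_mask(trans.shape, [obj])
    bg = _background(trans, object_mask)
    inverted = np.maximum(bg - trans, 0.0)

    # work on a padded bounding box so openings see the full neighbourhood
    rows, cols = obj.coords[:, 0], obj.coords[:, 1]
    pad = max_radius + 1
    r0 = max(0, rows.min() - pad)
    r1 = min(trans.shape[0], rows.max() + pad + 1)
    c0 = max(0, cols.min() - pad)
    c1 = min(trans.shape[1], cols.max() + pad + 1)
    patch = np.zeros((r1 - r0, c1 - c0))
    patch[rows - r0, cols - c0] = inverted[rows, cols]
    in_obj = (rows - r0, cols - c0)

    integrals = [float(patch[in_obj].sum())]
    for r in range(1, max_radius + 1):
        opened = morphology.opening(patch, morphology.disk(r))
        integrals.append(float(opened[in_obj].sum()))
    i0 = integrals[0]
    if i0 <= 0:
        return np.zeros(max_radius)
    # discrete disks are not perfectly nested; clamp to a true granulometry
    integrals = np.minimum.accumulate(integrals)
    return -np.diff(integrals) / i0


def granularity_score(trans: np.ndarray, obj: CellObject,
                      max_radius: int = GRANULARITY_MAX_RADIUS,
                      object_mask: np.ndarray | None = None) -> float:
    """Mean removal scale (px): sum over r of r * g_r."""
    g = granularity_spectrum(trans, obj, max_radius, object_mask)
    if not np.any(g):
        warnings.warn("zero signal inside object; granularity set to 0",
                      stacklevel=2)
        return 0.0
    radii = np.arange(1, len(g) + 1)
    return float((radii * g).sum())


def records_to_frame(records) -> pd.DataFrame:
    cols = ["patient_id", "tile_index", "object_size", "granularity",
            "mt_total", "mt_mean", "ppix_total", "ppix_mean"]
    rows = [{c: getattr(r, c) for c in cols} for r in records]
    return pd.DataFrame(rows, columns=cols)


def _within_ss(points: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for k in np.unique(labels):
        p = points[labels == k]
        ss += float(((p - p.mean(axis=0)) ** 2).sum())
    return ss


def morphology_scatter(records, n_ref: int = 20,
                       random_state: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-cell (size, granularity, mt_mean) triples plus a unimodality check.

    The check is a gap statistic comparing k=1 against k=2 on the
    standardized 2-D (size, granularity) point set, with uniform reference
    draws on the bounding box; k=2 is preferred when
    Gap(2) - s_2 > Gap(1).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        raise ValueError("need at least one record")
    scatter = df[["object_size", "granularity", "mt_mean"]].rename(
        columns={"object_size": "size"})
    if len(df) < 2:
        return scatter, {"preferred_k": 1, "gap1": np.nan, "gap2": np.nan}

    pts = df[["object_size", "granularity"]].to_numpy(dtype=float)
    sd = pts.std(axis=0)
    sd[sd == 0] = 1.0
    pts = (pts - pts.mean(axis=0)) / sd
    rng = np.random.default_rng(random_state)

    def log_wk(p: np.ndarray, k: int) -> float:
        if k == 1:
            labels = np.zeros(len(p), dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(p)
            labels = km.labels_
        return float(np.log(max(_within_ss(p, labels), 1e-300)))

    lo, hi = pts.min(axis=0), pts.max(axis=0)
    gaps, sks = {}, {}
    for k in (1, 2):
        ref = [log_wk(rng.uniform(lo, hi, size=pts.shape), k)
               for _ in range(n_ref)]
        gaps[k] = float(np.mean(ref) - log_wk(pts, k))
        sks[k] = float(np.std(ref) * np.sqrt(1 + 1 / n_ref))
    preferred = 2 if gaps[2] - sks[2] > gaps[1] else 1
    return scatter, {"preferred_k": preferred, "gap1": gaps[1],
                     "gap2": gaps[2], "s2": sks[2]}
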