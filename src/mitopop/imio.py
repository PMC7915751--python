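"""Image and table I/O: pseudocolor packing, tile-scan splitting, CSV tables.

Canonical on-disk image format is a three-channel 16-bit TIFF; a 16-bit RGB
PNG path is provided for the pseudocolor convention (red = MitoTracker,
green = PpIX, blue = transmitted light).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._png16 import read_rgb16, write_rgb16

__all__ = [
    "Tile",
    "pack_pseudocolor",
    "unpack_pseudocolor",
    "split_tilescan",
    "write_data_table",
    "read_data_table",
    "write_tile",
    "read_tile",
    "DATA_TABLE_COLUMNS",
]

DATA_TABLE_COLUMNS = ["patient_id", "object_size_px", "ppix_total",
                      "ppix_mean", "mt_total", "mt_mean"]


@dataclass
class Tile:
    """One field of view: three registered uint16 channels plus scale."""

    mt: np.ndarray
    ppix: np.ndarray
    trans: np.ndarray
    subject_id: int
    tile_index: int
    um_per_px: float

    def __post_init__(self) -> None:
        if not (self.mt.shape == self.ppix.shape == self.trans.shape):
            raise ValueError("channel dimensions must match")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mt.shape


def pack_pseudocolor(tile: Tile) -> np.ndarray:
    """Pack channels into an (H, W, 3) uint16 RGB array (R=mt, G=ppix, B=trans)."""
    return np.stack(
        [np.asarray(tile.mt, dtype=np.uint16),
         np.asarray(tile.ppix, dtype=np.uint16),
         np.asarray(tile.trans, dtype=np.uint16)], axis=-1)


def unpack_pseudocolor(rgb: np.ndarray, subject_id: int = 0,
                       tile_index: int = 0, um_per_px: float = 1.0) -> Tile:
    """Inverse of :func:`pack_pseudocolor`; rejects non-16-bit input."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if rgb.dtype != np.uint16:
        raise ValueError(f"expected uint16 samples, got {rgb.dtype}")
    return Tile(mt=rgb[..., 0].copy(), ppix=rgb[..., 1].copy(),
                trans=rgb[..., 2].copy(), subject_id=subject_id,
                tile_index=tile_index, um_per_px=um_per_px)


def split_tilescan(mosaic: np.ndarray, tile_px: int) -> list[np.ndarray]:
    """Split a mosaic into row-major tile_px x tile_px tiles.

    Works on 2-D single-channel or (H, W, C) multi-channel mosaics.
    Raises if the mosaic dimensions are not integer multiples of tile_px
    (no silent cropping).
    """
    mosaic = np.asarray(mosaic)
    h, w = mosaic.shape[:2]
    if tile_px <= 0:
        raise ValueError("tile_px must be positive")
    if h % tile_px or w % tile_px:
        raise ValueError(
            f"mosaic {h}x{w} is not an integer multiple of tile_px={tile_px}")
    tiles = []
    for i in range(h // tile_px):
        for j in range(w // tile_px):
            tiles.append(mosaic[i * tile_px:(i + 1) * tile_px,
                                j * tile_px:(j + 1) * tile_px].copy())
    return tiles


def write_data_table(records, path) -> None:
    """Write per-cell records to CSV in the canonical column order."""
    df = pd.DataFrame(list(records), columns=DATA_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_data_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != DATA_TABLE_COLUMNS:
        raise ValueError(
            f"schema mismatch: expected {DATA_TABLE_COLUMNS}, got {list(df.columns)}")
    return df


def _tile_stem(tile: Tile) -> str:
    return f"P{tile.subject_id}_T{tile.tile_index:03d}"


def write_tile(tile: Tile, out_dir, fmt: str = "tif") -> Path:
    """Write a tile as multi-channel TIFF (canonical) or pseudocolor PNG.

    A JSON sidecar carries the physical scale and identifiers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _tile_stem(tile)
    if fmt == "tif":
        path = out_dir / f"{stem}.tif"
        tifffile.imwrite(path, pack_pseudocolor(tile), photometric="rgb")
    elif fmt == "png":
        path = out_dir / f"{stem}.png"
        write_rgb16(path, pack_pseudocolor(tile))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    meta = {"subject_id": tile.subject_id, "tile_index": tile.tile_index,
            "um_per_px": tile.um_per_px}
    (out_dir / f"{stem}.json").write_text(json.dumps(meta))
    return path


def read_tile(path) -> Tile:
    """Read a tile written by :func:`write_tile` (TIFF or PNG + sidecar)."""
    path = Path(path)
    if path.suffix == ".tif":
        rgb = tifffile.imread(path)
    else:
        rgb = read_rgb16(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return unpack_pseudocolor(
        rgb.astype(np.uint16) if rgb.dtype == np.uint16 else rgb,
        subject_id=int(meta.get("subject_id", 0)),
        tile_index=int(meta.get("tile_index", 0)),
        um_per_px=float(meta.get("um_per_px", 1.0)))
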