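"""Slide preprocessing: tissue segmentation, resolution normalization, tiling.

The pipeline mirrors standard whole-slide practice: Otsu thresholding on a
downsampled grayscale rendering separates tissue from bright glass; the
slide is resampled to a standard physical resolution of 0.5 microns per
pixel (~20x magnification); the normalized image is cropped into
non-overlapping 256x256 tiles on a grid anchored at the image origin; tiles
whose tissue occupancy falls below 0.1 are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.transform import resize

__all__ = [
    "PreprocessConfig", "TileRecord", "segment_tissue", "normalize_mpp",
    "tile_slide", "write_manifest", "read_manifest", "preprocess_slide",
    "write_tiles",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_mpp: float = 0.5
    seg_downsample_long_side_px: int = 1024
    tile_size_px: int = 256
    min_occupancy: float = 0.1
    # Otsu channel: grayscale luminance by default; HSV saturation optional
    seg_channel: str = "luminance"

    def __post_init__(self):
        if self.tile_size_px <= 0:
            raise ValueError("tile_size_px must be positive")
        if not 0.0 <= self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must lie in [0, 1]")


@dataclass
class TileRecord:
    slide_id: str
    grid_col: int
    grid_row: int
    occupancy: float
    pixels: np.ndarray | None = None  # tile_size x tile_size x 3 uint8
    tile_path: str = ""


def _to_gray(image: np.ndarray, channel: str = "luminance") -> np.ndarray:
    if image.ndim == 2:
        return image.astype(float)
    if channel == "saturation":
        from skimage.color import rgb2hsv

        return rgb2hsv(image)[..., 1] * 255.0
    # ITU-R 601 luminance
    return image[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])


def segment_tissue(image: np.ndarray, seg_downsample_long_side_px: int = 1024,
                   channel: str = "luminance") -> np.ndarray:
    """Binary tissue mask (1 = tissue) at downsampled resolution.

    Tissue is the darker side of the Otsu threshold on the downsampled
    grayscale image. A constant image has no threshold: the mask is all
    background and a warning is emitted.
    """
    gray = _to_gray(image, channel)
    h, w = gray.shape
    long_side = max(h, w)
    if long_side > seg_downsample_long_side_px:
        scale = seg_downsample_long_side_px / long_side
        out_shape = (max(1, int(round(h * scale))), max(1, int(round(w * scale))))
        gray = resize(gray, out_shape, order=1, anti_aliasing=True,
                      preserve_range=True)
    if np.ptp(gray) == 0:
        warnings.warn("constant image: no Otsu threshold exists, returning all-background")
        return np.zeros(gray.shape, dtype=bool)
    thr = threshold_otsu(gray)
    if channel == "saturation":
        return gray > thr  # tissue is the saturated side
    return gray <= thr


def normalize_mpp(image: np.ndarray, source_mpp: float | None,
                  target_mpp: float = 0.5) -> np.ndarray:
    """Bilinear resample so one pixel spans ``target_mpp`` microns.

    Output side lengths are ``round(side * source_mpp / target_mpp)`` with
    banker's rounding (numpy/python round-half-even).
    """
    if source_mpp is None:
        raise ValueError("source_mpp is required; refusing to assume a scan resolution")
    if source_mpp <= 0:
        raise ValueError("source_mpp must be positive")
    if source_mpp == target_mpp:
        return image.copy()
    ratio = source_mpp / target_mpp
    h, w = image.shape[:2]
    out_shape = (int(round(h * ratio)), int(round(w * ratio)))
    if image.dtype == np.uint8 and image.ndim in (2, 3):
        pil = Image.fromarray(image)
        return np.asarray(pil.resize((out_shape[1], out_shape[0]), Image.BILINEAR))
    out = resize(image.astype(float), out_shape + image.shape[2:], order=1,
                 anti_aliasing=ratio < 1.0, preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(image.dtype)


def _upsample_mask_nearest(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample of a binary mask to the image frame."""
    h, w = shape
    rows = np.minimum((np.arange(h) * mask.shape[0] / h).astype(int), mask.shape[0] - 1)
    cols = np.minimum((np.arange(w) * mask.shape[1] / w).astype(int), mask.shape[1] - 1)
    return mask[np.ix_(rows, cols)]


def tile_slide(image: np.ndarray, mask: np.ndarray, config: PreprocessConfig,
               slide_id: str = "slide") -> list[TileRecord]:
    """Crop non-overlapping tiles from a MPP-normalized slide image.

    The grid is anchored at pixel (0, 0); partial edge tiles are dropped.
    Occupancy is the fraction of tile pixels with (nearest-upsampled)
    mask = 1; tiles below ``min_occupancy`` are discarded.
    """
    t = config.tile_size_px
    h, w = image.shape[:2]
    if h < t or w < t:
        warnings.warn(f"image {h}x{w} smaller than one {t}px tile; no tiles emitted")
        return []
    full = _upsample_mask_nearest(np.asarray(mask, dtype=bool), (h, w))
    n_rows, n_cols = h // t, w // t
    # vectorized per-tile occupancy via block reshaping
    occ = (full[: n_rows * t, : n_cols * t]
           .reshape(n_rows, t, n_cols, t)
           .mean(axis=(1, 3)))
    records: list[TileRecord] = []
    for r in range(n_rows):
        for c in range(n_cols):
            o = float(occ[r, c])
            if o < config.min_occupancy:
                continue
            records.append(TileRecord(
                slide_id=slide_id, grid_col=c, grid_row=r, occupancy=o,
                pixels=image[r * t:(r + 1) * t, c * t:(c + 1) * t].copy()))
    return records


MANIFEST_COLUMNS = ["slide_id", "grid_col", "grid_row", "occupancy", "tile_path"]


def write_manifest(tiles: list[TileRecord], path: str | Path) -> Path:
    path = Path(path)
    keys = [(t.slide_id, t.grid_col, t.grid_row) for t in tiles]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (slide_id, grid_col, grid_row) in manifest")
    df = pd.DataFrame(
        [{"slide_id": t.slide_id, "grid_col": t.grid_col, "grid_row": t.grid_row,
          "occupancy": t.occupancy, "tile_path": t.tile_path} for t in tiles],
        columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> list[TileRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"slide_id": str, "tile_path": str})
    if df.empty:
        return []
    df["tile_path"] = df["tile_path"].fillna("")
    return [TileRecord(slide_id=row.slide_id, grid_col=int(row.grid_col),
                       grid_row=int(row.grid_row), occupancy=float(row.occupancy),
                       tile_path=row.tile_path)
            for row in df.itertuples()]


def write_tiles(tiles: list[TileRecord], out_dir: str | Path) -> None:
    """Write tile rasters as PNGs sharded per slide; sets tile_path in place."""
    out_dir = Path(out_dir)
    for t in tiles:
        shard = out_dir / t.slide_id
        shard.mkdir(parents=True, exist_ok=True)
        p = shard / f"{t.grid_col:04d}_{t.grid_row:04d}.png"
        Image.fromarray(t.pixels).save(p)
        t.tile_path = str(p)


def preprocess_slide(image: np.ndarray, source_mpp: float,
                     config: PreprocessConfig | None = None,
                     slide_id: str = "slide") -> list[TileRecord]:
    """Full pipeline: segment -> normalize to target MPP -> tile -> filter."""
    config = config or PreprocessConfig()
    mask = segment_tissue(image, config.seg_downsample_long_side_px, config.seg_channel)
    norm = normalize_mpp(image, source_mpp, config.target_mpp)
    return tile_slide(norm, mask, config, slide_id=slide_id)
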