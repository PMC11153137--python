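"""Tile sequences: row-major serialization, grid discretization, augmentation.

A slide's retained tiles become an ordered sequence of (col, row) grid
coordinates plus (later) per-tile embeddings. Coordinates are discretized on
a d_grid = 256 px grid with an n_grid = 1000 overlay of rows and columns.
Training-time augmentations operate purely on coordinates: random crop of
the occupied bounding box (ratio 0.875 per axis), a single uniform integer
shift per axis keeping every tile inside the overlay, and a horizontal
coordinate flip with probability 0.5.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import h5py
import numpy as np

from .preprocess import TileRecord

__all__ = [
    "GridConfig", "AugmentConfig", "TileSequence", "serialize", "discretize",
    "augment", "save_sequences", "load_sequences", "slide_rng",
]


@dataclass(frozen=True)
class GridConfig:
    d_grid: int = 256  # pixels per grid unit at target MPP
    n_grid: int = 1000  # rows and columns in the overlay


@dataclass(frozen=True)
class AugmentConfig:
    crop_ratio: float = 0.875
    flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.crop_ratio <= 1.0:
            raise ValueError("crop_ratio must lie in (0, 1]")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")


@dataclass
class TileSequence:
    slide_id: str
    coords: np.ndarray  # N x 2 int (col, row), row-major sorted
    embeddings: np.ndarray | None = None  # N x D float

    def __len__(self):
        return len(self.coords)


def _row_major_order(coords: np.ndarray) -> np.ndarray:
    return np.lexsort((coords[:, 0], coords[:, 1]))  # by row, then col


def serialize(tiles: list[TileRecord]) -> TileSequence:
    """Order one slide's tiles row-major (by grid_row, then grid_col)."""
    if not tiles:
        raise ValueError("cannot serialize an empty tile list")
    slide_ids = {t.slide_id for t in tiles}
    if len(slide_ids) != 1:
        raise ValueError(f"tiles span multiple slides: {sorted(slide_ids)}")
    coords = np.array([[t.grid_col, t.grid_row] for t in tiles], dtype=np.int64)
    if len(np.unique(coords, axis=0)) != len(coords):
        raise ValueError("duplicate tile coordinates")
    return TileSequence(slide_id=tiles[0].slide_id,
                        coords=coords[_row_major_order(coords)])


def discretize(origins_px: np.ndarray, grid: GridConfig = GridConfig()) -> np.ndarray:
    """Pixel origins (multiples of d_grid) -> integer grid coordinates."""
    origins = np.asarray(origins_px)
    if np.any(origins % grid.d_grid != 0):
        raise ValueError("pixel origins must be multiples of d_grid")
    coords = origins // grid.d_grid
    if np.any(coords < 0) or np.any(coords >= grid.n_grid):
        raise ValueError(f"grid coordinate outside [0, {grid.n_grid}): slide exceeds overlay")
    return coords.astype(np.int64)


def slide_rng(global_seed: int, slide_id: str) -> np.random.Generator:
    """One reproducible stream per (seed, slide): keyed by a stable CRC of the id."""
    return np.random.default_rng((int(global_seed), zlib.crc32(slide_id.encode())))


def augment(seq: TileSequence, cfg: AugmentConfig,
            grid: GridConfig = GridConfig(),
            rng: np.random.Generator | None = None) -> TileSequence:
    """Coordinate augmentation: crop -> shift -> flip -> re-sort row-major.

    Crop keeps tiles inside an axis-aligned window spanning ``crop_ratio`` of
    the occupied bounding box per axis, at a uniformly random position within
    the box; if no tile survives, the tile nearest the window centre is kept.
    Shift adds one uniform integer offset per axis, sampled so every tile
    stays inside [0, n_grid). Flip maps col -> max_col - col with probability
    ``flip_prob``. Deterministic given the rng (derived from cfg.seed and the
    slide id when not passed explicitly).
    """
    if len(seq) == 0:
        raise ValueError("cannot augment an empty sequence")
    if rng is None:
        rng = slide_rng(cfg.seed, seq.slide_id)
    coords = seq.coords.copy()
    emb = None if seq.embeddings is None else seq.embeddings.copy()

    # ---- crop on the occupied bounding box
    if cfg.crop_ratio < 1.0:
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        extent = hi - lo + 1
        win = np.maximum(1, np.ceil(cfg.crop_ratio * extent).astype(int))
        start = np.array([lo[a] + rng.integers(0, extent[a] - win[a] + 1)
                          for a in range(2)])
        inside = np.all((coords >= start) & (coords < start + win), axis=1)
        if not inside.any():
            center = start + (win - 1) / 2.0
            inside = np.zeros(len(coords), dtype=bool)
            inside[np.argmin(np.abs(coords - center).sum(axis=1))] = True
        coords = coords[inside]
        if emb is not None:
            emb = emb[inside]

    # ---- one uniform shift per axis, keeping all tiles within the overlay
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    off = np.array([rng.integers(-lo[a], grid.n_grid - hi[a]) for a in range(2)])
    coords = coords + off

    # ---- horizontal coordinate flip
    if rng.random() < cfg.flip_prob:
        coords[:, 0] = coords[:, 0].max() - coords[:, 0]

    order = _row_major_order(coords)
    return TileSequence(slide_id=seq.slide_id, coords=coords[order],
                        embeddings=None if emb is None else emb[order])


# ------------------------------------------------------------------- HDF5 IO
def save_sequences(seqs: list[TileSequence], path) -> None:
    with h5py.File(path, "w") as f:
        for s in seqs:
            g = f.create_group(s.slide_id)
            g.attrs["slide_id"] = s.slide_id
            g.create_dataset("coords", data=s.coords.astype(np.int64))
            if s.embeddings is not None:
                g.create_dataset("embeddings", data=s.embeddings)


def load_sequences(path) -> list[TileSequence]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            emb = g["embeddings"][...] if "embeddings" in g else None
            out.append(TileSequence(slide_id=str(g.attrs["slide_id"]),
                                    coords=g["coords"][...], embeddings=emb))
    return out
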