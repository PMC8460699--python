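"""Attention weight maps and top-weighted tile export.

The per-tile importance beta_i = 1 + gamma * (attention received) is
projected back onto the slide's tile grid as log(beta), and rendered as a
green-intensity overlay: brighter green means a larger weight (min-max
scaled per slide, natural log). The k most-weighted tiles of a slide can
be exported to inspect the morphology the classifier attends to, and the
top-k sets of two tasks on the same slide can be intersected to compare
what different prediction targets look at.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from wsimil.model import TileWeights
from wsimil.preprocess import Tile, save_tile_png


@dataclass
class WeightMap:
    """Log tile weights on the slide grid; NaN where no tumor tile sits."""

    grid: np.ndarray  # (rows, cols) float, log(beta) at tumor positions
    positions: np.ndarray  # (N, 2) tumor-tile grid positions
    beta: np.ndarray  # (N,)
    slide_id: str = "slide"

    def rendering(self) -> np.ndarray:
        """Green-channel overlay at tile resolution (uint8 RGB).

        Log-weights are min-max scaled to [64, 255] so the dimmest tumor
        tile stays visible; non-tumor positions render black. The map is
        monotone: a larger beta never renders darker.
        """
        rows, cols = self.grid.shape
        img = np.zeros((rows, cols, 3), dtype=np.uint8)
        logw = self.grid[self.positions[:, 0], self.positions[:, 1]]
        lo, hi = float(np.min(logw)), float(np.max(logw))
        if hi - lo < 1e-12:
            scaled = np.full(len(logw), 255.0)
        else:
            scaled = 64.0 + (logw - lo) / (hi - lo) * (255.0 - 64.0)
        img[self.positions[:, 0], self.positions[:, 1], 1] = np.rint(scaled).astype(np.uint8)
        return img


def build_weight_map(weights: TileWeights, positions: np.ndarray,
                     grid_shape: tuple[int, int],
                     slide_id: str = "slide") -> WeightMap:
    """Project log tile weights to their grid positions.

    Requires beta > 0 everywhere (guaranteed while gamma > -1); positions
    outside the grid raise an error.
    """
    beta = np.asarray(weights.beta, dtype=float)
    positions = np.asarray(positions, dtype=int).reshape(-1, 2)
    if len(beta) != len(positions):
        raise ValueError("one weight per tile position required")
    if np.any(beta <= 0):
        raise ValueError("log weight undefined: beta must be > 0")
    rows, cols = grid_shape
    if positions.size and (positions.min() < 0 or positions[:, 0].max() >= rows
                           or positions[:, 1].max() >= cols):
        raise ValueError("tile position outside the slide grid")
    grid = np.full(grid_shape, np.nan)
    grid[positions[:, 0], positions[:, 1]] = np.log(beta)
    return WeightMap(grid, positions, beta, slide_id)


def top_k_tiles(weights: TileWeights, tiles: list[Tile], k: int = 20) -> list[Tile]:
    """The k tiles with the largest weights, descending.

    Ties break by row-major grid position; if fewer than k tiles exist,
    all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    beta = np.asarray(weights.beta, dtype=float)
    if len(beta) != len(tiles):
        raise ValueError("one weight per tile required")
    order = sorted(range(len(tiles)),
                   key=lambda i: (-beta[i], tiles[i].grid_pos))
    if len(tiles) < k:
        warnings.warn(f"only {len(tiles)} tiles available for top-{k}")
        return [tiles[i] for i in order]
    return [tiles[i] for i in order[:k]]


@dataclass
class OverlapReport:
    shared: list[tuple[int, int]]
    jaccard: float


def overlap_report(positions_a, positions_b, slide_a: str = "slide",
                   slide_b: str = "slide") -> OverlapReport:
    """Intersect two top-k position sets from the same slide.

    Used to compare which tiles two tasks (e.g. a gene mutation and its
    related pathway) both rely on.
    """
    if slide_a != slide_b:
        raise ValueError("overlap is only defined for top-k sets of one slide")
    set_a = {tuple(int(v) for v in p) for p in positions_a}
    set_b = {tuple(int(v) for v in p) for p in positions_b}
    shared = sorted(set_a & set_b)
    union = set_a | set_b
    jaccard = len(shared) / len(union) if union else 1.0
    return OverlapReport(shared, jaccard)


def weight_map_to_tsv(wmap: WeightMap, path: str | Path) -> None:
    """Machine-readable map: tile_row, tile_col, beta, log_beta."""
    pd.DataFrame({
        "tile_row": wmap.positions[:, 0],
        "tile_col": wmap.positions[:, 1],
        "beta": wmap.beta,
        "log_beta": np.log(wmap.beta),
    }).to_csv(path, sep="\t", index=False)


def export_top_tiles(tiles: list[Tile], directory: str | Path) -> list[Path]:
    """Write ranked tile PNGs named rank01_r{row}_c{col}.png etc."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rank, t in enumerate(tiles, start=1):
        p = directory / f"rank{rank:02d}_r{t.grid_pos[0]}_c{t.grid_pos[1]}.png"
        save_tile_png(t, p)
        paths.append(p)
    return paths


def save_weight_map_png(wmap: WeightMap, path: str | Path, tile_size: int = 1) -> None:
    from PIL import Image
    img = wmap.rendering()
    if tile_size > 1:
        img = np.kron(img, np.ones((tile_size, tile_size, 1), dtype=np.uint8))
    Image.fromarray(img).save(path)
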