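"""Slide preprocessing: tiling, background filtering, tumor-tile selection,
and slide-level color normalization.

A slide raster is cut into a grid of fixed-size, non-overlapping tiles
(512x512 by default). Tiles whose mean pixel value exceeds 220 are treated
as background and discarded. The remaining tiles are clustered into two
groups (tumor vs non-tumor) by k-means on downsampled pixel vectors, with a
manual-refinement hook for overriding individual tiles. Finally all tumor
tiles of a slide are mapped to a common color distribution by a per-channel
affine transform using slide-level mean and standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.cluster import KMeans

BACKGROUND_THRESHOLD = 220.0
DEFAULT_TILE_SIZE = 512
DEFAULT_DOWNSAMPLE_SIDE = 128

GridPos = tuple[int, int]


@dataclass
class Tile:
    """One non-overlapping square crop of a slide.

    ``grid_pos`` is the 0-based (row, col) position of the tile in the
    slide's tile grid; distinct tiles of a slide have distinct positions.
    """

    pixels: np.ndarray  # (tile, tile, 3) uint8
    grid_pos: GridPos
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile pixels must be (h, w, 3)")

    @property
    def mean_value(self) -> float:
        return float(self.pixels.mean())


@dataclass
class SlideColorStats:
    """Per-channel mean and standard deviation of a slide's tumor tiles."""

    mean: np.ndarray  # (3,)
    std: np.ndarray  # (3,)
    color_space: str = "RGB"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.std = np.asarray(self.std, dtype=float).reshape(3)
        if np.any(self.std <= 0):
            raise ValueError("color std components must be > 0 (flat channel)")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "color_space": self.color_space,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SlideColorStats":
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]), d.get("color_space", "RGB"))


@dataclass
class TumorSelection:
    """Tumor/non-tumor assignment per tile grid position, with overrides."""

    assignments: dict[GridPos, str]  # "tumor" | "nontumor"
    cluster_centroids: np.ndarray | None = None
    overrides: dict[GridPos, str] = field(default_factory=dict)

    def tumor_positions(self) -> list[GridPos]:
        return sorted(p for p, s in self.assignments.items() if s == "tumor")


def extract_tiles(slide_raster: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE,
                  slide_id: str = "slide") -> list[Tile]:
    """Cut a raster into non-overlapping tiles in row-major order.

    Partial tiles at the right/bottom edges are dropped: the grid is the
    largest one fitting entirely inside the raster. A raster smaller than
    one tile yields an empty list.
    """
    raster = np.asarray(slide_raster)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError("slide raster must have shape (h, w, 3)")
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    n_rows = raster.shape[0] // tile_size
    n_cols = raster.shape[1] // tile_size
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            block = raster[r * tile_size:(r + 1) * tile_size,
                           c * tile_size:(c + 1) * tile_size]
            tiles.append(Tile(block, (r, c), slide_id))
    return tiles


def is_background(tile: Tile, threshold: float = BACKGROUND_THRESHOLD) -> bool:
    """A tile is background iff its mean pixel value is strictly above the
    threshold (220 by default); a mean of exactly 220 is tissue."""
    return tile.mean_value > threshold


def downsample_flatten(tile: Tile, side: int = DEFAULT_DOWNSAMPLE_SIDE) -> np.ndarray:
    """Downsample a square RGB tile to side x side by area (box) averaging
    and flatten it to a vector of length side*side*3.

    For the default 512 -> 128 this is an exact 4x4 block mean. With
    side=128 the output length is 49152.
    """
    px = np.asarray(tile.pixels, dtype=np.float64)
    h, w = px.shape[:2]
    if h != w:
        raise ValueError("downsample_flatten expects a square tile")
    if h % side == 0:
        f = h // side
        small = px.reshape(side, f, side, f, 3).mean(axis=(1, 3))
    else:
        # non-integer factor: per-channel float box resampling
        chans = []
        for c in range(3):
            im = Image.fromarray(px[:, :, c].astype(np.float32), mode="F")
            chans.append(np.asarray(im.resize((side, side), Image.Resampling.BOX)))
        small = np.stack(chans, axis=-1).astype(np.float64)
    return small.reshape(-1)


def cluster_tumor_tiles(tiles: list[Tile], seed: int = 0,
                        downsample_side: int = DEFAULT_DOWNSAMPLE_SIDE) -> TumorSelection:
    """Split non-background tiles into tumor / non-tumor by 2-means.

    Each tile is downsampled and flattened; k-means with k=2 (10 restarts,
    seeded) clusters the vectors. The cluster whose centroid has the lower
    mean luminance is labeled tumor — tissue of interest is darker than
    stroma/background. If clustering degenerates to a single cluster (all
    tiles identical) every tile is labeled tumor and a warning is emitted.
    """
    if len(tiles) < 2:
        raise ValueError("tumor/non-tumor clustering needs at least 2 tiles")
    X = np.stack([downsample_flatten(t, downsample_side) for t in tiles])
    if np.allclose(X, X[0]):
        warnings.warn("degenerate clustering: all tiles identical; labeling all tumor")
        return TumorSelection({t.grid_pos: "tumor" for t in tiles},
                              cluster_centroids=np.stack([X[0], X[0]]))
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn may warn on tiny inputs
        labels = km.fit_predict(X)
    if len(np.unique(labels)) < 2:
        warnings.warn("degenerate clustering: one empty cluster; labeling all tumor")
        return TumorSelection({t.grid_pos: "tumor" for t in tiles},
                              cluster_centroids=km.cluster_centers_)
    luminance = km.cluster_centers_.mean(axis=1)
    tumor_cluster = int(np.argmin(luminance))
    assignments = {
        t.grid_pos: ("tumor" if lab == tumor_cluster else "nontumor")
        for t, lab in zip(tiles, labels)
    }
    return TumorSelection(assignments, cluster_centroids=km.cluster_centers_)


def apply_refinement(selection: TumorSelection,
                     overrides: Mapping[GridPos, str] | str | Path) -> TumorSelection:
    """Apply manual overrides on top of a clustering result.

    ``overrides`` maps grid positions to ``force_tumor`` or
    ``force_exclude`` (a TSV path with columns tile_row, tile_col, status is
    also accepted). Positions not present in the selection raise an error
    listing the offenders; all other assignments are left unchanged.
    """
    if isinstance(overrides, (str, Path)):
        df = pd.read_csv(overrides, sep="\t")
        overrides = {(int(r.tile_row), int(r.tile_col)): str(r.status)
                     for r in df.itertuples()}
    unknown = [p for p in overrides if p not in selection.assignments]
    if unknown:
        raise ValueError(f"override positions not in selection: {sorted(unknown)}")
    bad = {s for s in overrides.values()} - {"force_tumor", "force_exclude"}
    if bad:
        raise ValueError(f"unknown override statuses: {sorted(bad)}")
    new_assign = dict(selection.assignments)
    for pos, status in overrides.items():
        new_assign[pos] = "tumor" if status == "force_tumor" else "nontumor"
    return TumorSelection(new_assign, selection.cluster_centroids, dict(overrides))


def compute_slide_stats(tiles: Iterable[Tile], color_space: str = "RGB") -> SlideColorStats:
    """Slide-level per-channel pixel mean and std over the given tiles."""
    px = np.concatenate([np.asarray(t.pixels, dtype=np.float64).reshape(-1, 3)
                         for t in tiles])
    return SlideColorStats(px.mean(axis=0), px.std(axis=0), color_space)


def normalize_colors(tiles: list[Tile], source: SlideColorStats,
                     target: SlideColorStats) -> list[Tile]:
    """Map every tile's colors so the slide-level mean/std match the target.

    Per channel c: out = (in - source.mean_c) / source.std_c * target.std_c
    + target.mean_c, clipped to [0, 255]. All tiles of a slide must share
    the same source stats (computed once over its tumor tiles).
    """
    out = []
    for t in tiles:
        px = np.asarray(t.pixels, dtype=np.float64)
        mapped = (px - source.mean) / source.std * target.std + target.mean
        mapped = np.clip(np.rint(mapped), 0, 255).astype(np.uint8)
        out.append(Tile(mapped, t.grid_pos, t.slide_id))
    return out


def selection_to_tsv(selection: TumorSelection, path: str | Path) -> None:
    rows = [(r, c, s) for (r, c), s in sorted(selection.assignments.items())]
    pd.DataFrame(rows, columns=["tile_row", "tile_col", "status"]).to_csv(
        path, sep="\t", index=False)


def save_tile_png(tile: Tile, path: str | Path) -> None:
    Image.fromarray(np.asarray(tile.pixels, dtype=np.uint8)).save(path)
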