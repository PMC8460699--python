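"""Tile feature extraction and the per-patient feature cache.

Each normalized tumor tile is turned into a fixed-length feature vector by
a frozen extractor; the per-patient stack of vectors (the MIL bag) is
written to disk once so that model training never re-reads images.

The extractor is a contract, not a fixed network: anything that maps a
prepared tile tensor to a fixed-length vector deterministically in
evaluation mode qualifies. The published pipeline uses the convolutional
part of an ImageNet-pretrained ResNet-101, whose output width is 2048;
the in-repo default honours that contract with a seeded random-projection
extractor of the same output width, and a smaller variant is provided for
fast tests. Extractor parameters are never updated anywhere.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from wsimil.preprocess import Tile

# Channel statistics of the ImageNet training corpus (RGB, on [0,1] scale);
# configuration data, not code.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

BACKBONE_DIM = 2048


def prepare_tile(tile: Tile, side: int = 224,
                 channel_mean: np.ndarray = IMAGENET_MEAN,
                 channel_std: np.ndarray = IMAGENET_STD) -> np.ndarray:
    """Resize a tile to side x side, scale to [0,1], standardize per channel.

    Mirrors the standard input pipeline of ImageNet-pretrained backbones:
    bilinear resize, then (x/255 - mean) / std per channel.
    """
    px = np.asarray(tile.pixels, dtype=np.uint8)
    im = Image.fromarray(px).resize((side, side), Image.Resampling.BILINEAR)
    arr = np.asarray(im, dtype=np.float64) / 255.0
    mean = np.asarray(channel_mean, dtype=np.float64).reshape(1, 1, 3)
    std = np.asarray(channel_std, dtype=np.float64).reshape(1, 1, 3)
    return (arr - mean) / std


class FeatureExtractor(ABC):
    """Contract: prepared tile -> fixed-length vector, deterministic."""

    extractor_id: str
    dim: int

    @abstractmethod
    def __call__(self, tile: Tile) -> np.ndarray:
        """Return a (dim,) feature vector for one tile."""


class RandomProjectionExtractor(FeatureExtractor):
    """Frozen seeded Gaussian projection of downsampled tile pixels.

    The tile is box-downsampled to ``side`` x ``side``, scaled to [-1, 1],
    flattened, and projected by a fixed N(0, 1/sqrt(p)) matrix drawn once
    from ``seed``. Deterministic across runs and platforms; its parameters
    are frozen at construction, matching the pipeline's frozen-backbone
    contract.
    """

    def __init__(self, dim: int = BACKBONE_DIM, side: int = 32, seed: int = 0):
        self.dim = int(dim)
        self.side = int(side)
        self.seed = int(seed)
        self.extractor_id = f"randproj{self.dim}-d{self.side}-s{self.seed}"
        p = self.side * self.side * 3
        rng = np.random.default_rng(self.seed)
        self._proj = rng.standard_normal((p, self.dim)) / np.sqrt(p)

    def __call__(self, tile: Tile) -> np.ndarray:
        from wsimil.preprocess import downsample_flatten
        v = downsample_flatten(tile, self.side) / 127.5 - 1.0
        return v @ self._proj


def default_extractor(seed: int = 0) -> FeatureExtractor:
    """The default backbone contract: 2048-dimensional tile features."""
    return RandomProjectionExtractor(dim=BACKBONE_DIM, side=32, seed=seed)


def demo_extractor(seed: int = 0, dim: int = 64) -> FeatureExtractor:
    """Small fast extractor for tests and demos (same contract, D=64)."""
    return RandomProjectionExtractor(dim=dim, side=16, seed=seed)


@dataclass
class FeatureBag:
    """One patient's bag: an N x D feature matrix plus tile grid positions.

    N is the number of tumor tiles and varies from slide to slide; rows of
    ``features`` align one-to-one with ``tile_positions``.
    """

    patient_id: str
    features: np.ndarray  # (N, D)
    tile_positions: np.ndarray  # (N, 2) int (row, col)
    extractor_id: str = "unknown"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.tile_positions = np.asarray(self.tile_positions, dtype=np.int64).reshape(-1, 2)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty N x D matrix")
        if self.tile_positions.shape[0] != self.features.shape[0]:
            raise ValueError("tile_positions must align 1:1 with feature rows")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def extract_features(tiles: list[Tile], extractor: FeatureExtractor,
                     patient_id: str = "patient") -> FeatureBag:
    """Featurize a patient's tumor tiles into one bag (row i <- tile i)."""
    if not tiles:
        raise ValueError("cannot build a feature bag from zero tiles")
    rows = [np.asarray(extractor(t), dtype=np.float64) for t in tiles]
    dims = {r.shape for r in rows}
    if dims != {(extractor.dim,)}:
        raise ValueError(
            f"extractor output shape {dims} disagrees with declared dim {extractor.dim}")
    positions = np.array([t.grid_pos for t in tiles], dtype=np.int64)
    return FeatureBag(patient_id, np.stack(rows), positions, extractor.extractor_id)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr, dtype=np.float64).tobytes()).hexdigest()


class CacheCorruptionError(RuntimeError):
    pass


class FeatureCache:
    """On-disk bag store: one HDF5 matrix per patient plus a TSV manifest.

    The manifest (patient_id, n_tiles, dim, extractor_id, checksum) is the
    source of truth for shapes; reads verify the stored checksum so silent
    corruption surfaces as an error rather than bad training data.
    """

    MANIFEST_COLS = ["patient_id", "n_tiles", "dim", "extractor_id", "checksum"]

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.h5_path = self.directory / "bags.h5"
        self.manifest_path = self.directory / "manifest.tsv"

    def _load_manifest(self) -> pd.DataFrame:
        if self.manifest_path.exists():
            return pd.read_csv(self.manifest_path, sep="\t", dtype={"patient_id": str})
        return pd.DataFrame(columns=self.MANIFEST_COLS)

    def write_bag(self, bag: FeatureBag) -> None:
        manifest = self._load_manifest()
        with h5py.File(self.h5_path, "a") as f:
            grp_name = f"bags/{bag.patient_id}"
            if grp_name in f:
                del f[grp_name]
            grp = f.create_group(grp_name)
            grp.create_dataset("features", data=bag.features)
            grp.create_dataset("tile_positions", data=bag.tile_positions)
        manifest = manifest[manifest.patient_id != bag.patient_id]
        row = pd.DataFrame([{
            "patient_id": bag.patient_id,
            "n_tiles": bag.n_tiles,
            "dim": bag.dim,
            "extractor_id": bag.extractor_id,
            "checksum": _checksum(bag.features),
        }])
        manifest = pd.concat([manifest, row], ignore_index=True)
        manifest.to_csv(self.manifest_path, sep="\t", index=False)

    def read_bag(self, patient_id: str) -> FeatureBag:
        manifest = self._load_manifest()
        entry = manifest[manifest.patient_id == str(patient_id)]
        if entry.empty:
            raise KeyError(f"patient {patient_id!r} not in feature cache")
        entry = entry.iloc[0]
        with h5py.File(self.h5_path, "r") as f:
            grp = f[f"bags/{patient_id}"]
            features = np.asarray(grp["features"])
            positions = np.asarray(grp["tile_positions"])
        if features.shape != (int(entry.n_tiles), int(entry.dim)):
            raise CacheCorruptionError(
                f"stored shape {features.shape} disagrees with manifest "
                f"({entry.n_tiles}, {entry.dim}) for {patient_id!r}")
        if _checksum(features) != entry.checksum:
            raise CacheCorruptionError(f"checksum mismatch for {patient_id!r}")
        return FeatureBag(str(patient_id), features, positions, str(entry.extractor_id))

    def patient_ids(self) -> list[str]:
        return list(self._load_manifest().patient_id)
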