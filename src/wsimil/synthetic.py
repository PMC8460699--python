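"""Synthetic slides, feature bags, and omics tables with planted truth.

Real cohorts (gigapixel H&E slides plus matched mutation / CNA / expression
profiles) are not needed to exercise the pipeline: this module plants a
known ground truth at every level so each downstream stage can be tested
offline.

* Slides: a tile grid where background tiles are near-white (per-tile mean
  above the 220 filter threshold), tissue tiles are textured and darker,
  and a subset of tissue tiles carries a distinct darker tint — the
  "signal" texture standing in for label-predictive tumor morphology.
* Feature bags: standard-normal instances, with flagged instances shifted
  by a fixed direction; a bag is positive iff it contains a flagged
  instance (the classic MIL assumption).
* Omics: Bernoulli mutation calls at planted prevalences, discrete CNA
  calls, and expression correlated with a planted per-patient pathway
  activity sign so the pathway score recovers it.

No attempt is made at photorealistic H&E texture; the planted separations
are what matter for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from wsimil.features import FeatureBag
from wsimil.omics import OmicsTable, PathwayDefinition

# Pixel ranges chosen to sit strictly on either side of the 220 background
# threshold: background uniform in [230, 255], tissue texture in [80, 200].
_BG_LOW, _BG_HIGH = 230, 255
_TISSUE_LOW, _TISSUE_HIGH = 80, 200
# Base colors for the two tissue textures (plain tissue pink-ish, signal
# tissue darker purple-ish) — well separated for 2-means.
_TISSUE_BASE = np.array([185.0, 140.0, 170.0])
_SIGNAL_BASE = np.array([115.0, 90.0, 135.0])


@dataclass
class SyntheticSlide:
    image: np.ndarray  # (H, W, 3) uint8
    tissue_mask: np.ndarray  # (rows, cols) bool at tile resolution
    signal_mask: np.ndarray  # (rows, cols) bool, subset of tissue_mask
    slide_id: str
    seed: int
    tile_size: int


@dataclass
class SyntheticBagSet:
    bags: list[FeatureBag]
    bag_labels: np.ndarray  # (n_bags,) 0/1
    instance_flags: list[np.ndarray]  # per bag, (N,) 0/1
    generation_params: dict = field(default_factory=dict)


@dataclass
class SyntheticOmics:
    mutation_table: OmicsTable
    cna_table: OmicsTable
    expression_table: OmicsTable
    truth: dict
    seed: int


def generate_slide(width_tiles: int, height_tiles: int, tissue_fraction: float,
                   signal_fraction: float, tile_size: int = 32, seed: int = 0,
                   slide_id: str | None = None) -> SyntheticSlide:
    """Draw a synthetic slide raster with planted tissue and signal tiles.

    ``tissue_fraction`` of the grid becomes textured tissue (per-tile mean
    <= 220), the rest near-white background (mean > 220). Among tissue
    tiles, ``signal_fraction`` get the distinct signal tint. Masks are
    recorded at tile resolution; signal tiles are always tissue tiles.
    """
    if width_tiles < 1 or height_tiles < 1:
        raise ValueError("slide must be at least 1x1 tiles")
    if tile_size < 8:
        raise ValueError("tile_size must be >= 8")
    if not (0 <= tissue_fraction <= 1 and 0 <= signal_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_tiles = width_tiles * height_tiles
    n_tissue = int(round(tissue_fraction * n_tiles))
    tissue_idx = rng.choice(n_tiles, size=n_tissue, replace=False)
    tissue_mask = np.zeros(n_tiles, dtype=bool)
    tissue_mask[tissue_idx] = True
    n_signal = int(round(signal_fraction * n_tissue))
    signal_mask = np.zeros(n_tiles, dtype=bool)
    if n_signal:
        signal_mask[rng.choice(tissue_idx, size=n_signal, replace=False)] = True
    tissue_mask = tissue_mask.reshape(height_tiles, width_tiles)
    signal_mask = signal_mask.reshape(height_tiles, width_tiles)

    image = np.empty((height_tiles * tile_size, width_tiles * tile_size, 3),
                     dtype=np.uint8)
    for r in range(height_tiles):
        for c in range(width_tiles):
            sl = (slice(r * tile_size, (r + 1) * tile_size),
                  slice(c * tile_size, (c + 1) * tile_size))
            if not tissue_mask[r, c]:
                block = rng.integers(_BG_LOW, _BG_HIGH + 1,
                                     size=(tile_size, tile_size, 3))
            else:
                base = _SIGNAL_BASE if signal_mask[r, c] else _TISSUE_BASE
                noise = rng.normal(0.0, 12.0, size=(tile_size, tile_size, 3))
                block = np.clip(np.rint(base + noise), _TISSUE_LOW, _TISSUE_HIGH)
            image[sl] = block.astype(np.uint8)
    sid = slide_id if slide_id is not None else f"synth{seed}"
    return SyntheticSlide(image, tissue_mask, signal_mask, sid, seed, tile_size)


def generate_feature_bags(n_bags: int, bag_size_range: tuple[int, int] = (10, 40),
                          signal_fraction: float = 0.3, dim: int = 32,
                          effect_size: float = 1.0, seed: int = 0,
                          positive_fraction: float = 0.5,
                          direction: np.ndarray | None = None) -> SyntheticBagSet:
    """Generate MIL bags with planted instance flags.

    Instances are standard normal in ``dim`` dimensions; flagged instances
    are shifted by ``effect_size`` along a fixed unit direction drawn once
    per call (pass ``direction`` to share or shift it across sets — train,
    validation and test splits of one experiment must come from a single
    generated set or share the direction explicitly, otherwise the planted
    signal differs between them). A bag is labeled 1 iff it contains at
    least one flagged instance; positive bags flag ``signal_fraction`` of
    their instances (at least one). Bag sizes vary uniformly over
    ``bag_size_range``.
    """
    if n_bags < 2:
        raise ValueError("need at least 2 bags with both labels represented")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    n_pos = int(round(positive_fraction * n_bags))
    n_pos = min(max(n_pos, 1), n_bags - 1)
    if n_pos and not (0 < signal_fraction <= 1):
        raise ValueError("signal_fraction must be in (0, 1] for positive bags")
    rng = np.random.default_rng(seed)
    if direction is None:
        direction = rng.standard_normal(dim)
        direction = direction / np.linalg.norm(direction)
    else:
        direction = np.asarray(direction, dtype=float)
        if direction.shape != (dim,):
            raise ValueError("direction must have shape (dim,)")
    labels = np.zeros(n_bags, dtype=np.int64)
    labels[rng.choice(n_bags, size=n_pos, replace=False)] = 1

    bags, flags = [], []
    lo, hi = bag_size_range
    for b in range(n_bags):
        n = int(rng.integers(lo, hi + 1))
        x = rng.standard_normal((n, dim))
        f = np.zeros(n, dtype=np.int64)
        if labels[b] == 1:
            k = max(1, int(round(signal_fraction * n)))
            f[rng.choice(n, size=k, replace=False)] = 1
            x[f == 1] += effect_size * direction
        positions = np.column_stack([np.arange(n) // 8, np.arange(n) % 8])
        bags.append(FeatureBag(f"bag{b:04d}", x, positions, "synthetic"))
        flags.append(f)
    params = {
        "n_bags": n_bags, "bag_size_range": tuple(bag_size_range),
        "signal_fraction": signal_fraction, "dim": dim,
        "effect_size": effect_size, "seed": seed, "direction": direction,
    }
    return SyntheticBagSet(bags, labels, flags, params)


def generate_omics(n_patients: int,
                   gene_specs: Sequence[tuple[str, float, str]],
                   pathway_defs: Sequence[PathwayDefinition] = (),
                   seed: int = 0,
                   expression_effect: float = 1.0,
                   expression_noise: float = 0.3) -> SyntheticOmics:
    """Generate mutation / CNA / expression tables with planted truth.

    ``gene_specs`` rows are (gene, mutation prevalence, role); role is
    "oncogene" or "suppressor" and sets the sign linking the gene to any
    pathway it belongs to. Per patient and pathway an activity sign is
    planted; member-gene expression is ``weight * sign * effect + noise``
    so the oncogene/suppressor-weighted mean recovers the planted sign,
    and member-gene CNA calls are discrete {-2..2} correlated the same way.
    """
    names = [g for g, _, _ in gene_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names in gene_specs")
    for g, prev, _ in gene_specs:
        if not 0 <= prev <= 1:
            raise ValueError(f"prevalence for {g} outside [0, 1]")
    rng = np.random.default_rng(seed)
    patients = [f"P{i:04d}" for i in range(n_patients)]
    role_w = {g: (1.0 if role == "oncogene" else -1.0) for g, _, role in gene_specs}

    mut = np.zeros((len(names), n_patients), dtype=np.int64)
    for i, (_, prev, _) in enumerate(gene_specs):
        mut[i] = rng.random(n_patients) < prev

    member_of = {}  # gene -> (pathway index, weight)
    for pi, pd_ in enumerate(pathway_defs):
        for gene, w in pd_.members:
            member_of[gene] = (pi, float(w))

    n_pw = len(pathway_defs)
    act_expr = rng.choice([-1.0, 1.0], size=(n_patients, n_pw))
    act_cna = rng.choice([-1.0, 1.0], size=(n_patients, n_pw))

    expr = rng.normal(0.0, expression_noise, size=(len(names), n_patients))
    cna = np.zeros((len(names), n_patients))
    for i, g in enumerate(names):
        if g in member_of:
            pi, w = member_of[g]
            expr[i] += w * act_expr[:, pi] * expression_effect
            raw = w * act_cna[:, pi] * 1.5 + rng.normal(0.0, 0.6, n_patients)
            cna[i] = np.clip(np.rint(raw), -2, 2)
        else:
            prev = dict(zip(names, [p for _, p, _ in gene_specs]))[g]
            hit = rng.random(n_patients) < prev
            cna[i] = hit * rng.choice([-2, -1, 1, 2], size=n_patients)

    def _table(values, kind):
        return OmicsTable(pd.DataFrame(values, index=names, columns=patients), kind)

    truth = {
        "prevalence": {g: p for g, p, _ in gene_specs},
        "roles": role_w,
        "pathway_activity_expression": act_expr,
        "pathway_activity_cna": act_cna,
        "pathway_ids": [p.pathway_id for p in pathway_defs],
    }
    return SyntheticOmics(
        mutation_table=_table(mut, "point_mutation"),
        cna_table=_table(cna, "cna"),
        expression_table=_table(expr, "expression"),
        truth=truth, seed=seed)


def save_slide(slide: SyntheticSlide, directory: str | Path) -> dict[str, Path]:
    """Write the slide raster as PNG and its masks as a TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png = directory / f"{slide.slide_id}.png"
    Image.fromarray(slide.image).save(png)
    rows = []
    h, w = slide.tissue_mask.shape
    for r in range(h):
        for c in range(w):
            rows.append((r, c, int(slide.tissue_mask[r, c]), int(slide.signal_mask[r, c])))
    tsv = directory / f"{slide.slide_id}_masks.tsv"
    pd.DataFrame(rows, columns=["tile_row", "tile_col", "is_tissue", "is_signal"]).to_csv(
        tsv, sep="\t", index=False)
    return {"image": png, "masks": tsv}


def save_bag_labels(bag_set: SyntheticBagSet, path: str | Path) -> None:
    pd.DataFrame({
        "patient_id": [b.patient_id for b in bag_set.bags],
        "label": bag_set.bag_labels,
    }).to_csv(path, sep="\t", index=False)
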