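"""End-to-end pipeline configuration and orchestration.

A single YAML config drives every stage; all numeric defaults are the
pipeline's working constants (512-pixel tiles, 220 background threshold,
128 downsample side, 224 extractor input side, 30 epochs / batch 8 /
lr 1e-4 with 1e-3 for gamma, 70/15/15 splits, 1000 bootstrap replicates).

``run_pipeline`` executes the stages on synthetic inputs —
simulate -> tile -> select -> normalize -> featurize -> labels -> split ->
train -> eval -> visualize — and returns a manifest recording the config
hash, seeds, per-stage counts, and output checksums, so a rerun with the
same config is verifiably identical. Two demo modes exist: ``bags``
(synthetic feature bags straight into training, the fast path) and
``slides`` (synthetic rasters through the full image pipeline).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from wsimil import synthetic
from wsimil.evaluate import evaluate_model, split_patients
from wsimil.features import (FeatureCache, default_extractor, extract_features,
                             demo_extractor)
from wsimil.model import TrainConfig, save_checkpoint, save_history, tile_weights, train, model_forward
from wsimil.preprocess import (cluster_tumor_tiles, compute_slide_stats,
                               extract_tiles, is_background, normalize_colors)
from wsimil.viz import build_weight_map, weight_map_to_tsv


@dataclass
class PreprocessingConfig:
    tile_size: int = 512
    background_threshold: float = 220.0
    downsample_side: int = 128


@dataclass
class FeaturesConfig:
    extractor: str = "test"  # "default" (2048-D) or "test" (64-D)
    side: int = 224
    extractor_seed: int = 0


@dataclass
class ModelConfig:
    d_attn: int = 16
    seed: int = 0


@dataclass
class EvaluationConfig:
    ratios: tuple[float, ...] = (0.70, 0.15, 0.15)
    n_boot: int = 1000


@dataclass
class SimulateConfig:
    mode: str = "bags"  # "bags" | "slides"
    n_bags: int = 300
    bag_size_range: tuple[int, int] = (10, 40)
    signal_fraction: float = 0.3
    dim: int = 32
    effect_size: float = 4.0
    n_slides: int = 16
    slide_tiles: int = 8  # slides are slide_tiles x slide_tiles
    slide_tile_size: int = 32
    tissue_fraction: float = 0.6


@dataclass
class PipelineConfig:
    output_dir: str = "pipeline_out"
    seed: int = 0
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["evaluation"]["ratios"] = list(d["evaluation"]["ratios"])
        d["simulate"]["bag_size_range"] = list(d["simulate"]["bag_size_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "preprocessing": PreprocessingConfig,
            "features": FeaturesConfig,
            "model": ModelConfig,
            "training": TrainConfig,
            "evaluation": EvaluationConfig,
            "simulate": SimulateConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sub:
                if key == "evaluation" and "ratios" in val:
                    val = {**val, "ratios": tuple(val["ratios"])}
                if key == "simulate" and "bag_size_range" in val:
                    val = {**val, "bag_size_range": tuple(val["bag_size_range"])}
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _split_with_all_classes(patient_ids, labels, ratios, seed, max_tries=50):
    """Seeded split, re-seeded until every partition holds both classes.

    Small demo cohorts can randomly land a single-class partition, which
    makes AUC undefined; the retry is deterministic and recorded.
    """
    label_of = dict(zip(patient_ids, labels))
    for attempt in range(max_tries):
        spec = split_patients(patient_ids, ratios, seed=seed + attempt)
        ok = all(
            len({label_of[p] for p in spec.partition(k)}) == 2
            for k in range(len(ratios)))
        if ok:
            return spec, seed + attempt
    raise RuntimeError("could not find a split with both classes in every partition")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic demo pipeline and return its manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "stages": {}, "outputs": {}}
    stage = "simulate"
    try:
        if config.simulate.mode == "bags":
            bags, labels, flags = _simulate_bags(config, manifest)
        elif config.simulate.mode == "slides":
            bags, labels = _run_image_stages(config, manifest, out)
            flags = None
        else:
            raise ValueError(f"unknown simulate mode {config.simulate.mode!r}")

        stage = "split"
        patient_ids = [b.patient_id for b in bags]
        spec, used_seed = _split_with_all_classes(
            patient_ids, labels, config.evaluation.ratios, config.seed)
        spec.to_tsv(out / "split.tsv")
        manifest["stages"]["split"] = {"sizes": list(spec.sizes), "seed": used_seed}
        by_id = dict(zip(patient_ids, zip(bags, labels)))
        parts = [[by_id[p] for p in sorted(spec.partition(k))]
                 for k in range(len(config.evaluation.ratios))]
        train_bags, train_y = zip(*parts[0])
        val_bags, val_y = zip(*parts[1]) if len(parts) > 2 else zip(*parts[0])
        test_bags, test_y = zip(*parts[-1])

        stage = "train"
        tc = dataclasses.replace(config.training, seed=config.seed)
        params, history = train(list(train_bags), list(train_y), tc,
                                list(val_bags), list(val_y),
                                d_attn=config.model.d_attn)
        save_checkpoint(params, out / "model", {"config_hash": config.config_hash()})
        save_history(history, out / "history.tsv")
        manifest["stages"]["train"] = {
            "epochs": tc.epochs,
            "best_val_auc": round(max(h["val_auc"] for h in history), 6),
        }

        stage = "eval"
        result = evaluate_model(params, list(test_bags), list(test_y),
                                n_boot=config.evaluation.n_boot, seed=config.seed)
        metrics = {"task": "synthetic_signal", **result.to_dict()}
        metrics_path = out / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2))
        manifest["stages"]["eval"] = {"auc": round(result.auc, 6)}
        manifest["outputs"]["metrics.json"] = _file_checksum(metrics_path)

        stage = "visualize"
        demo_bag = test_bags[int(np.argmax(test_y))]
        _, state = model_forward(demo_bag, params)
        tw = tile_weights(state, params.gamma)
        grid_shape = (int(demo_bag.tile_positions[:, 0].max()) + 1,
                      int(demo_bag.tile_positions[:, 1].max()) + 1)
        wmap = build_weight_map(tw, demo_bag.tile_positions, grid_shape,
                                demo_bag.patient_id)
        weight_map_to_tsv(wmap, out / "weight_map.tsv")
        manifest["stages"]["visualize"] = {"slide": demo_bag.patient_id,
                                           "n_tiles": demo_bag.n_tiles}
        manifest["outputs"]["weight_map.tsv"] = _file_checksum(out / "weight_map.tsv")
    except Exception as exc:  # noqa: BLE001 - stage name must surface
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc, manifest) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _simulate_bags(config: PipelineConfig, manifest: dict):
    sim = config.simulate
    bag_set = synthetic.generate_feature_bags(
        n_bags=sim.n_bags, bag_size_range=sim.bag_size_range,
        signal_fraction=sim.signal_fraction, dim=sim.dim,
        effect_size=sim.effect_size, seed=config.seed)
    manifest["stages"]["simulate"] = {
        "mode": "bags", "n_bags": sim.n_bags,
        "n_positive": int(bag_set.bag_labels.sum()),
    }
    return bag_set.bags, list(bag_set.bag_labels), bag_set.instance_flags


def _run_image_stages(config: PipelineConfig, manifest: dict, out: Path):
    """Slides demo: rasters through tiling, selection, normalization,
    featurization; slide label = slide carries the signal texture."""
    sim = config.simulate
    rng = np.random.default_rng(config.seed)
    extractor = (demo_extractor(config.features.extractor_seed)
                 if config.features.extractor == "test"
                 else default_extractor(config.features.extractor_seed))
    cache = FeatureCache(out / "cache")
    labels = [i % 2 for i in range(sim.n_slides)]
    target_stats = None
    bags, n_tiles_total = [], 0
    for i, label in enumerate(labels):
        slide = synthetic.generate_slide(
            sim.slide_tiles, sim.slide_tiles, sim.tissue_fraction,
            signal_fraction=0.5 if label else 0.0,
            tile_size=sim.slide_tile_size,
            seed=int(rng.integers(0, 2**31)), slide_id=f"S{i:03d}")
        tiles = extract_tiles(slide.image, sim.slide_tile_size, slide.slide_id)
        fg = [t for t in tiles
              if not is_background(t, config.preprocessing.background_threshold)]
        selection = cluster_tumor_tiles(fg, seed=config.seed,
                                        downsample_side=16)
        tumor_pos = set(selection.tumor_positions())
        tumor_tiles = [t for t in fg if t.grid_pos in tumor_pos]
        stats = compute_slide_stats(tumor_tiles)
        if target_stats is None:
            target_stats = stats  # first slide anchors the color reference
        tumor_tiles = normalize_colors(tumor_tiles, stats, target_stats)
        bag = extract_features(tumor_tiles, extractor, patient_id=slide.slide_id)
        cache.write_bag(bag)
        bags.append(bag)
        n_tiles_total += len(tumor_tiles)
    manifest["stages"]["simulate"] = {"mode": "slides", "n_slides": sim.n_slides}
    manifest["stages"]["featurize"] = {
        "n_tumor_tiles": n_tiles_total, "dim": extractor.dim,
        "extractor_id": extractor.extractor_id,
    }
    return [cache.read_bag(b.patient_id) for b in bags], labels
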