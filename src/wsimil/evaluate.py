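"""Patient splitting, AUC with bootstrap confidence intervals, and the
frozen-layer transfer fine-tuning protocol.

Cohorts are split at the patient level (one slide per patient) by
largest-remainder apportionment of the requested ratios: floor each
n * r_k, then hand the remaining patients to the partitions with the
largest fractional parts, ties to earlier partitions. This convention
reproduces 659 -> 461/99/99 under 70/15/15 and 350 -> 70/280,
316 -> 63/253 under 20/80.

Model discrimination is summarized by the AUC (probability that a positive
patient outranks a negative one, midrank ties) with a 95% percentile
interval from 1000 patient-level bootstrap resamples.

Transfer to a new cohort freezes the first two fully connected layers and
fine-tunes only the self-attention layer (W_f, W_g, gamma) and the output
layer; only tasks meeting the prevalence rule in the new cohort (>3% point
mutation, >5% CNA) are eligible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from wsimil.features import FeatureBag
from wsimil.model import ModelParams, TrainConfig, predict_proba, train


@dataclass
class SplitSpec:
    """Disjoint, exhaustive partition of a patient roster."""

    ratios: tuple[float, ...]
    seed: int
    assignment: dict[str, int]  # patient_id -> partition index

    @property
    def sizes(self) -> tuple[int, ...]:
        counts = np.zeros(len(self.ratios), dtype=int)
        for part in self.assignment.values():
            counts[part] += 1
        return tuple(int(c) for c in counts)

    def partition(self, index: int) -> list[str]:
        return [p for p, k in self.assignment.items() if k == index]

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.assignment.items()),
                     columns=["patient_id", "partition"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class EvalResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    scores: np.ndarray
    labels: np.ndarray

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_boot": self.n_boot, "n_test": int(len(self.labels))}


def apportion(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n patients over the ratios."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    if abs(ratios.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    quotas = n * ratios
    sizes = np.floor(quotas).astype(int)
    remainder = n - sizes.sum()
    # distribute to largest fractional parts; ties go to earlier partitions
    order = sorted(range(len(ratios)), key=lambda k: (-(quotas[k] - sizes[k]), k))
    for k in order[:remainder]:
        sizes[k] += 1
    return [int(s) for s in sizes]


def split_patients(patients: int | Sequence[str], ratios: Sequence[float],
                   seed: int = 0) -> SplitSpec:
    """Randomly partition patients with largest-remainder size arithmetic."""
    if isinstance(patients, int):
        ids = [f"P{i:04d}" for i in range(patients)]
    else:
        ids = list(patients)
    n = len(ids)
    if n < len(list(ratios)):
        raise ValueError("fewer patients than partitions")
    sizes = apportion(n, ratios)
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(n)]
    assignment: dict[str, int] = {}
    start = 0
    for part, size in enumerate(sizes):
        for pid in shuffled[start:start + size]:
            assignment[pid] = part
        start += size
    return SplitSpec(tuple(float(r) for r in ratios), seed, assignment)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_ci(scores: Sequence[float], labels: Sequence[int],
                 n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval of the AUC over patient resamples.

    Patients are resampled with replacement ``n_boot`` times; a replicate
    that draws a single class is redrawn so exactly ``n_boot`` replicate
    AUCs enter the percentiles.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined: only one class present")
    rng = np.random.default_rng(seed)
    n = len(scores)
    replicates = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
        replicates[b] = roc_auc_score(labels[idx], scores[idx])
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(replicates, [100 * alpha, 100 * (1 - alpha)])
    return float(low), float(high)


def evaluate_model(params: ModelParams, bags: Sequence[FeatureBag | np.ndarray],
                   labels: Sequence[int], n_boot: int = 1000,
                   seed: int = 0) -> EvalResult:
    """Score a trained model on a labeled bag set with a bootstrap CI."""
    scores = predict_proba(bags, params)
    labels = np.asarray(labels, dtype=int)
    point = auc(scores, labels)
    low, high = bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
    return EvalResult(point, low, high, n_boot, scores, labels)


def fc_checksum(params: ModelParams) -> str:
    """Digest of the first two fully connected layers (the frozen block)."""
    m = hashlib.sha256()
    for k in ("W1", "b1", "W2", "b2"):
        m.update(np.ascontiguousarray(getattr(params, k), dtype=np.float64).tobytes())
    return m.hexdigest()


class TaskEligibilityError(ValueError):
    """Task prevalence in the new cohort is below the fine-tuning rule."""


# prevalence floors for transfer eligibility (point mutation / CNA)
FINETUNE_MIN_PREVALENCE = {"point": 0.03, "cna": 0.05}


def finetune(params: ModelParams, bags: Sequence[FeatureBag | np.ndarray],
             labels: Sequence[int], config: TrainConfig,
             val_bags: Sequence[FeatureBag | np.ndarray] | None = None,
             val_labels: Sequence[int] | None = None,
             task_kind: str | None = None,
             epochs: int | None = None) -> tuple[ModelParams, list[dict]]:
    """Adapt a trained model to a new cohort with fc1/fc2 frozen.

    Only the attention maps, gamma, and the output layer are updated. When
    ``task_kind`` is "point" or "cna" the new cohort's label prevalence
    must exceed 3% / 5% respectively, otherwise the task is refused.
    ``epochs`` overrides ``config.epochs``; zero epochs returns the model
    unchanged.
    """
    labels = np.asarray(labels, dtype=int)
    if task_kind is not None:
        floor = FINETUNE_MIN_PREVALENCE.get(task_kind)
        if floor is None:
            raise ValueError(f"unknown task kind {task_kind!r}")
        prevalence = float(labels.mean())
        if prevalence <= floor:
            raise TaskEligibilityError(
                f"{task_kind} task prevalence {prevalence:.3f} in the new cohort "
                f"does not exceed the {floor:.0%} fine-tuning floor")
    if epochs == 0:
        return params.copy(), []
    if epochs is not None:
        config = TrainConfig(epochs=epochs, bag_batch=config.bag_batch,
                             lr=config.lr, lr_gamma=config.lr_gamma,
                             seed=config.seed)
    if val_bags is None:
        val_bags, val_labels = bags, labels
    before = fc_checksum(params)
    tuned, history = train(bags, labels, config, val_bags, val_labels,
                           init_params=params, freeze_fc=True)
    assert fc_checksum(tuned) == before, "frozen layers changed during fine-tuning"
    return tuned, history
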