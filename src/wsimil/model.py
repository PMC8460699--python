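"""Slide-level MIL classifier: MLP head with a self-attention layer.

One patient is one bag x of N tile-feature vectors (N x D, D = 2048 for
the default extractor). The head is

    h  = relu(fc2(relu(fc1(x))))          N x 128
    f(h) = W_f h,  g(h) = W_g h           N x d_attn each
    s_{j,i} = f(h_i)^T g(h_j)             attention scores
    alpha_{j,.} = softmax_i s_{j,.}       row-stochastic N x N
    o_j = sum_i alpha_{j,i} h_i           attended features
    y = h + gamma * o                     residual, gamma trainable
    y_global = mean_j y_j                 pooled slide feature
    p = softmax(fc_out(y_global))         2-class probabilities

and the per-tile importance used for visualization is

    beta_i = 1 + gamma * sum_j alpha_{j,i}   (attention received by tile i).

Softmax normalizes over the input index i for each output j, so each
output attends over all tiles; under the alternative orientation every
beta_i would collapse to the constant 1 + gamma.

Training minimizes cross-entropy with Adam; bags are processed one at a
time with gradient accumulation to an effective batch (variable N, no
padding). gamma starts at 1 and has its own learning rate. The whole head
is implemented in NumPy with analytic gradients — bags are small enough
that a single CPU trains a task in well under a minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from wsimil.features import FeatureBag

HIDDEN1 = 512
HIDDEN2 = 128
DEFAULT_D_ATTN = 16

_WEIGHT_KEYS = ("W1", "b1", "W2", "b2", "Wf", "Wg", "Wout", "bout")
_FROZEN_IN_FINETUNE = ("W1", "b1", "W2", "b2")


@dataclass
class ModelParams:
    """All trainable parameters of the prediction head."""

    W1: np.ndarray  # (512, D)
    b1: np.ndarray  # (512,)
    W2: np.ndarray  # (128, 512)
    b2: np.ndarray  # (128,)
    Wf: np.ndarray  # (d_attn, 128)
    Wg: np.ndarray  # (d_attn, 128)
    gamma: float
    Wout: np.ndarray  # (2, 128)
    bout: np.ndarray  # (2,)

    @classmethod
    def initialize(cls, dim: int, d_attn: int = DEFAULT_D_ATTN,
                   seed: int = 0) -> "ModelParams":
        """He-initialized weights, zero biases, gamma = 1."""
        if d_attn < 1:
            raise ValueError("d_attn must be >= 1")
        rng = np.random.default_rng(seed)
        def he(out_d, in_d):
            return rng.standard_normal((out_d, in_d)) * np.sqrt(2.0 / in_d)
        return cls(
            W1=he(HIDDEN1, dim), b1=np.zeros(HIDDEN1),
            W2=he(HIDDEN2, HIDDEN1), b2=np.zeros(HIDDEN2),
            Wf=rng.standard_normal((d_attn, HIDDEN2)) / np.sqrt(HIDDEN2),
            Wg=rng.standard_normal((d_attn, HIDDEN2)) / np.sqrt(HIDDEN2),
            gamma=1.0,
            Wout=rng.standard_normal((2, HIDDEN2)) / np.sqrt(HIDDEN2),
            bout=np.zeros(2),
        )

    @property
    def dim(self) -> int:
        return self.W1.shape[1]

    @property
    def d_attn(self) -> int:
        return self.Wf.shape[0]

    def copy(self) -> "ModelParams":
        return ModelParams(**{k: getattr(self, k).copy() for k in _WEIGHT_KEYS},
                           gamma=float(self.gamma))


@dataclass
class AttentionState:
    """Intermediate quantities of one forward pass through the attention."""

    alpha: np.ndarray  # (N, N) row-stochastic
    o: np.ndarray  # (N, 128)
    y_tiles: np.ndarray  # (N, 128)
    y_global: np.ndarray  # (128,)


@dataclass
class TileWeights:
    """Per-tile importance beta_i = 1 + gamma * (attention received)."""

    beta: np.ndarray  # (N,)


@dataclass
class TrainConfig:
    epochs: int = 30
    bag_batch: int = 8
    lr: float = 1e-4
    lr_gamma: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0 or self.lr_gamma <= 0:
            raise ValueError("learning rates must be positive")


def _row_softmax(s: np.ndarray) -> np.ndarray:
    z = s - s.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def attention_forward(h: np.ndarray, params: ModelParams) -> AttentionState:
    """Self-attention over the N x 128 hidden tile features."""
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("h must be a non-empty N x d matrix")
    if not np.isfinite(h).all():
        raise ValueError("non-finite values in attention input")
    F = h @ params.Wf.T  # (N, a), row i = f(h_i)
    G = h @ params.Wg.T  # (N, a), row j = g(h_j)
    scores = G @ F.T  # scores[j, i] = f(h_i)^T g(h_j)
    alpha = _row_softmax(scores)
    o = alpha @ h
    y_tiles = h + params.gamma * o
    y_global = y_tiles.mean(axis=0)
    return AttentionState(alpha, o, y_tiles, y_global)


def _forward_cache(x: np.ndarray, params: ModelParams) -> dict:
    if x.shape[1] != params.dim:
        raise ValueError(f"bag width {x.shape[1]} != model input dim {params.dim}")
    z1 = x @ params.W1.T + params.b1
    h1 = np.maximum(z1, 0.0)
    z2 = h1 @ params.W2.T + params.b2
    h = np.maximum(z2, 0.0)
    state = attention_forward(h, params)
    logits = params.Wout @ state.y_global + params.bout
    logits = logits - logits.max()
    probs = np.exp(logits) / np.exp(logits).sum()
    return {"x": x, "z1": z1, "h1": h1, "z2": z2, "h": h,
            "state": state, "probs": probs}


def model_forward(bag: FeatureBag | np.ndarray,
                  params: ModelParams) -> tuple[np.ndarray, AttentionState]:
    """Full forward pass: bag -> ({negative, positive} probabilities, state)."""
    x = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag, dtype=np.float64)
    cache = _forward_cache(x, params)
    return cache["probs"], cache["state"]


def tile_weights(state: AttentionState | np.ndarray, gamma: float) -> TileWeights:
    """beta_i = 1 + gamma * (column sum i of alpha): attention received.

    For a row-stochastic alpha the betas total N * (1 + gamma)."""
    alpha = state.alpha if isinstance(state, AttentionState) else np.asarray(state)
    return TileWeights(1.0 + gamma * alpha.sum(axis=0))


def _backward(cache: dict, label: int, params: ModelParams) -> dict:
    """Analytic gradients of the cross-entropy loss for one bag."""
    x, h1, h = cache["x"], cache["h1"], cache["h"]
    state: AttentionState = cache["state"]
    alpha, o = state.alpha, state.o
    n = x.shape[0]

    dlogits = cache["probs"].copy()
    dlogits[label] -= 1.0
    gWout = np.outer(dlogits, state.y_global)
    gbout = dlogits
    dyg = params.Wout.T @ dlogits  # (128,)
    dy = np.broadcast_to(dyg / n, h.shape)  # mean pooling

    dh = dy.copy()
    do = params.gamma * dy
    ggamma = float(np.sum(dy * o))

    dalpha = do @ h.T  # (N, N)
    dh = dh + alpha.T @ do
    # softmax backward, row-wise over the input index
    dS = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
    F = h @ params.Wf.T
    G = h @ params.Wg.T
    dG = dS @ F  # scores[j,i] = G[j].F[i]
    dF = dS.T @ G
    gWf = dF.T @ h
    gWg = dG.T @ h
    dh = dh + dF @ params.Wf + dG @ params.Wg

    dz2 = dh * (cache["z2"] > 0)
    gW2 = dz2.T @ h1
    gb2 = dz2.sum(axis=0)
    dh1 = dz2 @ params.W2
    dz1 = dh1 * (cache["z1"] > 0)
    gW1 = dz1.T @ x
    gb1 = dz1.sum(axis=0)

    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
            "Wf": gWf, "Wg": gWg, "gamma": ggamma,
            "Wout": gWout, "bout": gbout}


class _Adam:
    """Adam with two learning-rate groups (gamma vs everything else)."""

    def __init__(self, params: ModelParams, lr: float, lr_gamma: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.lr_gamma = lr, lr_gamma
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(params, k)) for k in _WEIGHT_KEYS}
        self.v = {k: np.zeros_like(getattr(params, k)) for k in _WEIGHT_KEYS}
        self.m["gamma"] = 0.0
        self.v["gamma"] = 0.0

    def step(self, params: ModelParams, grads: dict, frozen: tuple = ()) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            if k in frozen:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g if k != "gamma" else g ** 2)
            mhat = self.m[k] / c1
            vhat = self.v[k] / c2
            lr = self.lr_gamma if k == "gamma" else self.lr
            update = lr * mhat / (np.sqrt(vhat) + self.eps)
            if k == "gamma":
                params.gamma = float(params.gamma - update)
            else:
                setattr(params, k, getattr(params, k) - update)


def bag_loss(bag: FeatureBag | np.ndarray, label: int, params: ModelParams) -> float:
    probs, _ = model_forward(bag, params)
    return float(-np.log(max(probs[int(label)], 1e-12)))


def predict_proba(bags: Sequence[FeatureBag | np.ndarray],
                  params: ModelParams) -> np.ndarray:
    """Positive-class probability per bag (the score used for AUC)."""
    return np.array([model_forward(b, params)[0][1] for b in bags])


def train(bags: Sequence[FeatureBag | np.ndarray], labels: Sequence[int],
          config: TrainConfig, val_bags: Sequence[FeatureBag | np.ndarray],
          val_labels: Sequence[int], init_params: ModelParams | None = None,
          d_attn: int = DEFAULT_D_ATTN,
          freeze_fc: bool = False) -> tuple[ModelParams, list[dict]]:
    """Train the head by Adam on accumulated bag gradients.

    Bags are visited in a seeded shuffled order each epoch, one at a time;
    gradients are averaged over ``bag_batch`` bags per optimizer step.
    After each epoch the validation AUC is computed from positive-class
    probabilities and the parameters achieving the best validation AUC are
    returned together with the per-epoch history (epoch, train_loss,
    val_auc). With ``freeze_fc`` the first two fully connected layers are
    excluded from updates (the transfer fine-tuning protocol).
    """
    labels = np.asarray(labels, dtype=int)
    val_labels = np.asarray(val_labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    xs = [b.features if isinstance(b, FeatureBag) else np.asarray(b, dtype=np.float64)
          for b in bags]
    if init_params is None:
        params = ModelParams.initialize(xs[0].shape[1], d_attn=d_attn, seed=config.seed)
    else:
        params = init_params.copy()
    frozen = _FROZEN_IN_FINETUNE if freeze_fc else ()
    opt = _Adam(params, config.lr, config.lr_gamma)
    rng = np.random.default_rng(config.seed)

    history: list[dict] = []
    best_auc = -np.inf
    best_params = params.copy()
    for epoch in range(config.epochs):
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), config.bag_batch):
            batch = order[start:start + config.bag_batch]
            acc: dict = {}
            for idx in batch:
                cache = _forward_cache(xs[idx], params)
                losses.append(-np.log(max(cache["probs"][labels[idx]], 1e-12)))
                grads = _backward(cache, labels[idx], params)
                for k, g in grads.items():
                    acc[k] = acc.get(k, 0.0) + g
            for k in acc:
                acc[k] = acc[k] / len(batch)
            opt.step(params, acc, frozen=frozen)
        val_scores = predict_proba(val_bags, params)
        val_auc = float(roc_auc_score(val_labels, val_scores))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc = val_auc
            best_params = params.copy()
    return best_params, history


def save_checkpoint(params: ModelParams, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize parameters (npz) plus JSON metadata side-car."""
    path = Path(path)
    arrays = {k: getattr(params, k) for k in _WEIGHT_KEYS}
    np.savez(path.with_suffix(".npz"), gamma=np.array(params.gamma), **arrays)
    meta = dict(metadata or {})
    meta.update({"d_attn": params.d_attn, "dim": params.dim, "gamma": params.gamma})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> ModelParams:
    data = np.load(Path(path).with_suffix(".npz"))
    return ModelParams(**{k: data[k] for k in _WEIGHT_KEYS},
                       gamma=float(data["gamma"]))


def save_history(history: list[dict], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame(history).to_csv(path, sep="\t", index=False)
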