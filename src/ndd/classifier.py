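"""Ordered-pair features and the interaction classifier.

A drug pair (i, j) is represented by concatenating row i and row j of the
fused similarity matrix — 2m features describing how each drug of the pair
relates to every drug in the panel. The representation is order-sensitive
while the interaction label is symmetric, so training uses both orderings of
each pair and evaluation averages the two directional scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import InteractionMatrix, PairSample
from .exceptions import DimensionError, ParameterError, TrainingDataError
from .network import FeedForwardNet
from .snf import FusedSimilarity


@dataclass(frozen=True)
class NNConfig:
    """Architecture and optimizer settings of the pair classifier.

    Defaults follow the tuned configuration of the method: two hidden layers
    of 300 and 400 rectifier units, dropout 0.5 after each, sigmoid output,
    binary cross-entropy, SGD with momentum 0.9 and batch size 200; weights
    drawn from N(0, 0.05²) and biases from U(-1, 0). The learning rate is
    not part of the published configuration — it defaults to 0.01 and is the
    first knob to revisit on a new dataset. ``standardize`` z-scores the
    features on the training set before they reach the network (the fused
    matrix rows live on a 1/m scale, far below the scale the bias
    initialization expects).
    """

    hidden_sizes: tuple[int, ...] = (300, 400)
    dropout: float = 0.5
    activation: str = "relu"
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 200
    epochs: int = 20
    weight_sd: float = 0.05
    bias_init: str = "uniform_neg"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ParameterError("dropout must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ParameterError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")


@dataclass
class TrainedModel:
    net: FeedForwardNet
    config: NNConfig
    input_dim: int
    feature_mean: np.ndarray = field(repr=False)
    feature_sd: np.ndarray = field(repr=False)
    epoch_losses: list[float] = field(default_factory=list, repr=False)


def pair_feature(F: FusedSimilarity, i: int, j: int) -> np.ndarray:
    """Concatenate row i and row j of the fused matrix (ordered: (i,j) != (j,i))."""
    m = F.m
    if not (0 <= i < m and 0 <= j < m):
        raise IndexError(f"pair ({i}, {j}) out of range for m={m}")
    return np.concatenate([F.F[i], F.F[j]])


def build_dataset(
    F: FusedSimilarity,
    Y: InteractionMatrix,
    pairs: Sequence[tuple[int, int]],
    both_orders: bool = False,
) -> list[PairSample]:
    """One labelled sample per pair; ``both_orders`` also adds each (j, i).

    Zero-labelled pairs are treated as negatives, the standard approximation
    when unobserved interactions cannot be distinguished from true
    non-interactions.
    """
    if F.m != Y.m:
        raise DimensionError("fused matrix and Y have different dimensions")
    samples = []
    for i, j in pairs:
        samples.append(PairSample(i, j, int(Y.Y[i, j]), pair_feature(F, i, j)))
        if both_orders and i != j:
            samples.append(PairSample(j, i, int(Y.Y[j, i]), pair_feature(F, j, i)))
    return samples


def _stack(samples: Sequence[PairSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.features for s in samples]).astype(float)
    y = np.array([s.label for s in samples], dtype=float)
    return X, y


def train(samples: Sequence[PairSample], cfg: NNConfig) -> TrainedModel:
    """Fit the feed-forward classifier on the given pair samples."""
    if not samples:
        raise TrainingDataError("no training samples")
    X, y = _stack(samples)
    if len(np.unique(y)) < 2:
        raise TrainingDataError("training data must contain both classes")
    if cfg.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = (X - mean) / sd

    rng = np.random.default_rng(cfg.seed)
    net = FeedForwardNet(
        input_dim=X.shape[1],
        hidden_sizes=cfg.hidden_sizes,
        activation=cfg.activation,
        dropout=cfg.dropout,
        weight_sd=cfg.weight_sd,
        bias_init=cfg.bias_init,
        rng=rng,
    )
    losses = [
        net.train_epoch(Xs, y, cfg.learning_rate, cfg.momentum, cfg.batch_size, rng)
        for _ in range(cfg.epochs)
    ]
    return TrainedModel(
        net=net, config=cfg, input_dim=X.shape[1],
        feature_mean=mean, feature_sd=sd, epoch_losses=losses,
    )


def predict_proba(model: TrainedModel, samples: Sequence[PairSample]) -> np.ndarray:
    """Interaction probabilities in (0, 1), dropout disabled (deterministic)."""
    X, _ = _stack(samples)
    if X.shape[1] != model.input_dim:
        raise DimensionError(
            f"feature dimension {X.shape[1]} != model input dim {model.input_dim}"
        )
    Xs = (X - model.feature_mean) / model.feature_sd
    p = model.net.predict(Xs)
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def score_unordered_pairs(
    model: TrainedModel, F: FusedSimilarity, pairs: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Symmetric pair score: mean of the (i,j) and (j,i) directional scores."""
    fwd = [PairSample(i, j, 0, pair_feature(F, i, j)) for i, j in pairs]
    bwd = [PairSample(j, i, 0, pair_feature(F, j, i)) for i, j in pairs]
    return (predict_proba(model, fwd) + predict_proba(model, bwd)) / 2.0


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path: str | Path, fused: FusedSimilarity | None = None) -> None:
    """Self-describing archive: weights, biases, scaler, config and input dim.

    Optionally embeds the fused matrix so a saved model can score new pairs
    without re-running fusion.
    """
    cfg = model.config.__dict__.copy()
    cfg["hidden_sizes"] = list(cfg["hidden_sizes"])
    arrays = {
        "feature_mean": model.feature_mean,
        "feature_sd": model.feature_sd,
        "meta": np.frombuffer(
            json.dumps({"config": cfg, "input_dim": model.input_dim}).encode(), dtype=np.uint8
        ),
    }
    for k, (W, b) in enumerate(zip(model.net.W, model.net.b)):
        arrays[f"W{k}"] = W
        arrays[f"b{k}"] = b
    if fused is not None:
        arrays["fused"] = fused.F
    np.savez(path, **arrays)


def load_model(path: str | Path) -> tuple[TrainedModel, FusedSimilarity | None]:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    cfg_dict = meta["config"]
    cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
    cfg = NNConfig(**cfg_dict)
    net = FeedForwardNet(
        input_dim=meta["input_dim"],
        hidden_sizes=cfg.hidden_sizes,
        activation=cfg.activation,
        dropout=cfg.dropout,
        weight_sd=cfg.weight_sd,
        bias_init=cfg.bias_init,
        rng=np.random.default_rng(0),
    )
    n_layers = len(cfg.hidden_sizes) + 1
    net.W = [data[f"W{k}"] for k in range(n_layers)]
    net.b = [data[f"b{k}"] for k in range(n_layers)]
    model = TrainedModel(
        net=net, config=cfg, input_dim=meta["input_dim"],
        feature_mean=data["feature_mean"], feature_sd=data["feature_sd"],
    )
    fused = FusedSimilarity(F=data["fused"]) if "fused" in data else None
    return model, fused
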