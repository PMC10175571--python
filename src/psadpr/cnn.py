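"""The convolutional peptide-window classifier family.

One architecture is shared by all five encodings. For a window encoded as a
(positions x channels) matrix the network is:

1. two convolution sublayers (128 kernels, sizes 1 and 3), each followed by
   dropout at rate 0.7;
2. two conv + max-pool blocks (128 kernels of sizes 9 and 10, pool size 2),
   each followed by dropout at rate 0.5;
3. a position-wise dense sublayer of 128 neurons (no flattening) and a global
   average pooling sublayer;
4. a single sigmoid output unit giving the crosstalk probability in [0, 1].

ReLU activates every hidden layer. The word-embedding (WE) variant prepends a
trainable 21-token, 5-dimensional embedding so integer-coded windows enter the
same convolutional stack. Training uses Adam with binary cross-entropy and
early stopping on validation AUC.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .encoders import ENCODING_NAMES, scheme
from .metrics import roc_auc

#: Target specificity implied by the evaluation protocol's constant-SP rows.
DEFAULT_TARGET_SPECIFICITY = 0.694

EMBEDDING_DIM = 5


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters for one encoding.

    All training fields are explicit and serialized with every trained model,
    so a run can be audited and reproduced from its artifacts alone.
    """

    encoding: str
    stage1_filters: int = 128
    stage1_kernel_sizes: tuple[int, int] = (1, 3)
    stage1_dropout: float = 0.7
    block_filters: int = 128
    block_kernel_sizes: tuple[int, int] = (9, 10)
    pool_size: int = 2
    block_dropout: float = 0.5
    dense_width: int = 128
    flatten_dense: bool = False  # contract: position-wise dense, never flattened
    padding: str = "same"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int | None = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoding.upper() not in ENCODING_NAMES:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.flatten_dense:
            raise ValueError(
                "the fully connected stage is position-wise by contract; "
                "flattening is not supported"
            )
        object.__setattr__(self, "encoding", self.encoding.upper())

    @property
    def input_shape(self) -> tuple[int, ...]:
        s = scheme(self.encoding)
        if self.encoding == "WE":
            return (s.positions,)  # integer tokens, embedded in-model
        return (s.positions, s.channels)


@dataclass
class TrainedModel:
    """A fitted network with its config, decision threshold and history."""

    net: nn.Network
    config: ModelConfig
    threshold: float = 0.5
    history: list[dict[str, float]] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def build_model(config: ModelConfig, rng: np.random.Generator | None = None) -> nn.Network:
    """Assemble the untrained network for ``config``'s encoding."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s = scheme(config.encoding)
    layers: list[nn.Layer] = []
    if config.encoding == "WE":
        layers.append(nn.Embedding(21, EMBEDDING_DIM, rng))
        in_ch = EMBEDDING_DIM
    else:
        in_ch = s.channels
    k1, k2 = config.stage1_kernel_sizes
    layers += [
        nn.Conv1D(in_ch, config.stage1_filters, k1, rng, padding=config.padding),
        nn.Dropout(config.stage1_dropout),
        nn.Conv1D(config.stage1_filters, config.stage1_filters, k2, rng,
                  padding=config.padding),
        nn.Dropout(config.stage1_dropout),
    ]
    ch = config.stage1_filters
    for k in config.block_kernel_sizes:
        layers += [
            nn.Conv1D(ch, config.block_filters, k, rng, padding=config.padding),
            nn.MaxPool1D(config.pool_size),
            nn.Dropout(config.block_dropout),
        ]
        ch = config.block_filters
    # Position-wise dense (a size-1 convolution), then pool positions away.
    layers += [
        nn.Conv1D(ch, config.dense_width, 1, rng, padding="valid"),
        nn.GlobalAveragePooling1D(),
        nn.Dense(config.dense_width, 1, rng, activation="linear"),
    ]
    return nn.Network(layers)


def _check_input(config: ModelConfig, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    expected = config.input_shape
    if X.shape[1:] != expected:
        raise ValueError(
            f"encoding {config.encoding}: expected input shape (n, {expected}), "
            f"got {X.shape}"
        )
    if config.encoding == "WE":
        if not np.issubdtype(X.dtype, np.integer):
            raise ValueError("WE input must be integer tokens")
        return X
    return X.astype(np.float32, copy=False)


def train(
    config: ModelConfig,
    X: np.ndarray,
    y: Sequence[int],
    val_X: np.ndarray | None = None,
    val_y: Sequence[int] | None = None,
    seed: int | None = None,
) -> TrainedModel:
    """Fit the CNN; with validation data, early-stop on validation AUC.

    Deterministic given ``seed`` (initialization, dropout and shuffling all
    derive from it). The best-validation-AUC weights are restored at the end.
    Without validation data the model trains for ``config.max_epochs``.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    X = _check_input(config, X)
    y = np.asarray(y).astype(np.float32).ravel()
    if X.shape[0] != y.size or y.size < 2:
        raise ValueError("need matching X/y with at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    has_val = val_X is not None and val_y is not None
    if has_val:
        val_X = _check_input(config, val_X)
        val_y = np.asarray(val_y).ravel()

    rng = np.random.default_rng(config.seed)
    net = build_model(config, rng)
    opt = nn.Adam(net, lr=config.learning_rate)
    history: list[dict[str, float]] = []
    best_auc, best_weights, since_best = -np.inf, None, 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(X.shape[0])
        losses = []
        for start in range(0, X.shape[0], config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(X[idx], train=True, rng=rng)
            loss, dz = nn.bce_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            net.backward(dz.astype(np.float32))
            opt.step()
            losses.append(loss)
        record = {"epoch": epoch, "loss": float(np.mean(losses))}
        if has_val:
            val_auc = roc_auc(val_y, _forward_scores(net, val_X))
            record["val_auc"] = val_auc
            if val_auc > best_auc:
                best_auc, best_weights, since_best = val_auc, net.get_weights(), 0
            else:
                since_best += 1
            history.append(record)
            if config.patience is not None and since_best > config.patience:
                break
        else:
            history.append(record)

    if best_weights is not None:
        net.set_weights(best_weights)
    net.clear_caches()
    return TrainedModel(net=net, config=config, history=history)


def _forward_scores(net: nn.Network, X: np.ndarray, batch: int = 1024) -> np.ndarray:
    out = [
        nn.sigmoid(net.forward(X[i:i + batch], train=False))
        for i in range(0, X.shape[0], batch)
    ]
    net.clear_caches()
    if not out:
        return np.zeros(0)
    return np.concatenate(out).ravel().astype(np.float64)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Crosstalk probability per window, in input order; each in [0, 1]."""
    X = np.asarray(X)
    if X.shape[0] == 0:
        return np.zeros(0)
    X = _check_input(model.config, X)
    return _forward_scores(model.net, X)


def calibrate_threshold(
    negative_scores: Sequence[float],
    target_specificity: float = DEFAULT_TARGET_SPECIFICITY,
) -> float:
    """Smallest threshold achieving the target specificity on given negatives.

    Specificity at threshold ``t`` counts negatives scored strictly below
    ``t`` (the classification rule is positive at ``score >= t``). Candidates
    are the observed score values plus one just above the maximum (for targets
    only reachable by calling nothing positive).
    """
    s = np.sort(np.asarray(negative_scores, dtype=float))
    if s.size == 0:
        raise ValueError("no negative scores to calibrate on")
    if not 0 < target_specificity < 1:
        raise ValueError("target specificity must be in (0, 1)")
    candidates = np.append(np.unique(s), np.nextafter(s[-1], np.inf))
    below = np.searchsorted(s, candidates, side="left")
    ok = below / s.size >= target_specificity
    return float(candidates[np.argmax(ok)])


def achieved_specificity(negative_scores: Sequence[float], threshold: float) -> float:
    s = np.asarray(negative_scores, dtype=float)
    return float(np.mean(s < threshold))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Save config (JSON), weights (NPZ) and history (CSV) into a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["threshold"] = model.threshold
    (d / "config.json").write_text(json.dumps(cfg, indent=2))
    np.savez(d / "weights.npz",
             **{f"p{i}": w for i, w in enumerate(model.net.get_weights())})
    if model.history:
        import pandas as pd

        pd.DataFrame(model.history).to_csv(d / "history.csv", index=False)


def load_model(directory: str | Path) -> TrainedModel:
    d = Path(directory)
    cfg = json.loads((d / "config.json").read_text())
    threshold = cfg.pop("threshold", 0.5)
    cfg["stage1_kernel_sizes"] = tuple(cfg["stage1_kernel_sizes"])
    cfg["block_kernel_sizes"] = tuple(cfg["block_kernel_sizes"])
    config = ModelConfig(**cfg)
    net = build_model(config)
    with np.load(d / "weights.npz") as z:
        weights = [z[f"p{i}"] for i in range(len(z.files))]
    net.set_weights(weights)
    return TrainedModel(net=net, config=config, threshold=threshold)
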