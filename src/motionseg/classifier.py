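"""Training and inference for the per-timestep motion-state classifier.

The classifier maps a sliding window of L=100 feature vectors to L
probability vectors over the motion model's states plus the none class.
Training data is built by densely sliding the window over labeled
recordings; because boundary states occupy a single frame each they are
hundreds of times rarer than performing/none states, so the loss weights
every class inversely to its frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import FeatureSequence, Standardizer
from .network import Adam, GruNet, cce_grad_logits, softmax, weighted_cce

__all__ = [
    "ClassifierConfig",
    "TrainingWindowSet",
    "SequenceClassifier",
    "make_windows",
    "class_weights",
    "one_hot",
]


@dataclass
class ClassifierConfig:
    window_len: int = 100
    feature_dim: int = 11
    dense_units: int = 48
    gru_units: tuple[int, int] = (48, 32)
    num_classes: int = 12
    dropout_rate: float = 0.2
    batch_size: int = 100
    epochs: int = 20
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 4:
            raise ValueError("num_classes must be >= 4 (one phase plus none)")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.gru_units = tuple(self.gru_units)


@dataclass
class TrainingWindowSet:
    """Stacked training windows: inputs (M, L, 11), targets (M, L) class indices."""

    inputs: np.ndarray
    targets: np.ndarray
    class_counts: np.ndarray

    def __post_init__(self) -> None:
        if self.inputs.shape[:2] != self.targets.shape:
            raise ValueError("inputs and targets must share the first two dimensions")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @classmethod
    def concatenate(cls, parts: list["TrainingWindowSet"]) -> "TrainingWindowSet":
        return cls(
            np.concatenate([p.inputs for p in parts]),
            np.concatenate([p.targets for p in parts]),
            np.sum([p.class_counts for p in parts], axis=0),
        )


def make_windows(features: FeatureSequence | np.ndarray, labels: np.ndarray,
                 window_len: int, stride: int = 1,
                 num_classes: int | None = None) -> TrainingWindowSet:
    """Slice a labeled recording into overlapping fixed-length windows.

    Windows start at offsets 0, stride, 2*stride, ... with start <= T - L,
    giving floor((T - L) / stride) + 1 windows.
    """
    x = features.values if isinstance(features, FeatureSequence) else np.asarray(features)
    labels = np.asarray(labels, dtype=np.int64)
    T = x.shape[0]
    if labels.shape[0] != T:
        raise ValueError("features and labels must have the same length")
    if T < window_len:
        raise ValueError(f"recording of {T} frames is shorter than window_len={window_len}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = np.arange(0, T - window_len + 1, stride)
    idx = starts[:, None] + np.arange(window_len)[None, :]
    inputs = x[idx]
    targets = labels[idx]
    k = num_classes if num_classes is not None else int(labels.max()) + 1
    counts = np.bincount(targets.ravel(), minlength=k).astype(np.float64)
    return TrainingWindowSet(inputs, targets, counts)


def class_weights(class_counts: np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights: alpha_i = total / (K * count_i).

    Balanced counts give all-ones; classes absent from the data get
    weight 0 so they contribute nothing to the loss.
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("negative class count")
    total = counts.sum()
    if total == 0:
        raise ValueError("all class counts are zero")
    k = len(counts)
    alpha = np.zeros(k)
    nz = counts > 0
    alpha[nz] = total / (k * counts[nz])
    return alpha


def one_hot(targets: np.ndarray, num_classes: int) -> np.ndarray:
    return np.eye(num_classes)[np.asarray(targets, dtype=np.int64)]


class SequenceClassifier:
    """The trained state labeler plus its input standardizer and config."""

    def __init__(self, config: ClassifierConfig, standardizer: Standardizer | None = None):
        self.config = config
        self.net = GruNet(
            feature_dim=config.feature_dim,
            num_classes=config.num_classes,
            dense_units=config.dense_units,
            gru_units=config.gru_units,
            dropout_rate=config.dropout_rate,
            seed=config.seed,
        )
        self.standardizer = standardizer or Standardizer(
            mean=np.zeros(config.feature_dim), scale=np.ones(config.feature_dim)
        )

    # -- training -----------------------------------------------------------

    def train(self, windows: TrainingWindowSet, alpha: np.ndarray | None = None,
              epochs: int | None = None, verbose: bool = False) -> dict:
        """Train with Adam on the class-weighted cross-entropy.

        Inputs are assumed already standardized.  Returns a history dict
        with per-epoch mean training loss.
        """
        if len(windows) == 0:
            raise ValueError("empty training set")
        cfg = self.config
        if alpha is None:
            alpha = class_weights(windows.class_counts)
        alpha = np.asarray(alpha, dtype=np.float64)
        epochs = cfg.epochs if epochs is None else epochs
        opt = Adam(self.net.params(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        m = len(windows)
        history: dict = {"loss": [], "alpha": alpha.tolist()}
        for epoch in range(epochs):
            order = rng.permutation(m)
            losses = []
            for lo in range(0, m, cfg.batch_size):
                sel = order[lo:lo + cfg.batch_size]
                xb = windows.inputs[sel]
                yb = one_hot(windows.targets[sel], cfg.num_classes)
                probs, cache = self.net.forward(xb, training=True)
                loss = weighted_cce(yb, probs, alpha)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss}; "
                        f"check learning rate and input scaling"
                    )
                grads = self.net.backward(cce_grad_logits(yb, probs, alpha), cache)
                opt.step(grads)
                losses.append(loss)
            history["loss"].append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}  loss {history['loss'][-1]:.4f}")
        return history

    # -- inference ----------------------------------------------------------

    def predict_window(self, features: np.ndarray) -> np.ndarray:
        """Probabilities (L, K) for one window of exactly L feature rows."""
        x = np.asarray(features, dtype=np.float64)
        if x.shape != (self.config.window_len, self.config.feature_dim):
            raise ValueError(
                f"expected ({self.config.window_len}, {self.config.feature_dim}), got {x.shape}"
            )
        return self.net.predict(x[None])[0]

    def predict_batch(self, windows: np.ndarray) -> np.ndarray:
        """Probabilities (M, L, K) for a stack of windows."""
        x = np.asarray(windows, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != self.config.window_len:
            raise ValueError(f"expected (M, {self.config.window_len}, F), got {x.shape}")
        out = np.empty((x.shape[0], x.shape[1], self.config.num_classes))
        bs = max(1, self.config.batch_size)
        for lo in range(0, x.shape[0], bs):
            out[lo:lo + bs] = self.net.predict(x[lo:lo + bs])
        return out

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights to ``<path>.npz`` and config to a JSON sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_arrays())
        sidecar = {
            "config": asdict(self.config),
            "standardizer": self.standardizer.to_dict(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SequenceClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = sidecar["config"]
        cfg_dict["gru_units"] = tuple(cfg_dict["gru_units"])
        cfg = ClassifierConfig(**cfg_dict)
        clf = cls(cfg, Standardizer.from_dict(sidecar["standardizer"]))
        with np.load(path.with_suffix(".npz")) as data:
            arrays = clf.net.state_arrays()
            for k in arrays:
                arrays[k][...] = data[k]
        return clf
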