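"""Residue-level paratope classifier: an MLP over concatenated embeddings.

The classifier maps each residue's feature vector to a paratope probability
through three fully connected ReLU layers (default widths 2000, 1000, 500)
and a logistic output.  Training minimizes mean binary cross-entropy with
Adam, applying dropout (rate 0.4) to all hidden layers and random zeroing of
40% of the input coordinates; model selection is by per-protein PR AUC on a
validation set with early stopping (patience 10 epochs, at most 300),
retaining the weights of the best-validation epoch.  Everything runs on CPU
with seeded, reproducible initialization and batching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .errors import AlignmentError, ConfigurationError, ContractViolationError
from .metrics import pr_auc, UndefinedMetricError

_EPS = 1e-7  # probability clamp inside the loss


@dataclass(frozen=True)
class ModelConfig:
    input_dimension: int
    hidden_widths: tuple[int, ...] = (2000, 1000, 500)
    dropout_rate: float = 0.4
    activation: str = "relu"

    def __post_init__(self):
        if self.input_dimension <= 0:
            raise ValueError("input_dimension must be positive")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size_sequences: int = 16
    l2_weight: float = 1e-5
    input_mask_rate: float = 0.4
    early_stop_patience_epochs: int = 10
    max_epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size_sequences <= 0:
            raise ValueError("learning rate and batch size must be positive")
        if not 0 <= self.input_mask_rate < 1:
            raise ValueError("input_mask_rate must be in [0, 1)")


@dataclass
class SequenceExample:
    """Features and labels for one antibody (all residues of one sequence)."""

    id: str
    features: np.ndarray  # (n_residues, d)
    labels: np.ndarray  # (n_residues,) in {0, 1}

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise AlignmentError("feature rows must align 1:1 with labels")


def bce_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities are clamped to
    [1e-7, 1 - 1e-7] for numerical safety."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise AlignmentError("probabilities and labels must have equal length")
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def mask_inputs(
    features: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero a Bernoulli(rate) subset of input coordinates, independently per
    residue and per dimension.  Training-time augmentation only; inference
    never masks."""
    if not 0 <= rate < 1:
        raise ValueError("mask rate must be in [0, 1)")
    if rate == 0:
        return features
    keep = rng.random(features.shape) >= rate
    return features * keep


class ParatopeMLP:
    """Feed-forward paratope classifier with a logistic output unit."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        dims = [config.input_dimension, *config.hidden_widths, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- introspection -------------------------------------------------
    @property
    def parameter_count(self) -> int:
        """Closed-form trainable parameter count: sum over layers of
        (fan_in + 1) * fan_out."""
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def get_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in (*self.weights, *self.biases)]

    def set_parameters(self, params: Sequence[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [np.array(p) for p in params[:k]]
        self.biases = [np.array(p) for p in params[k:]]

    # -- forward / backward --------------------------------------------
    def _forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Forward pass; returns probabilities and the per-layer cache needed
        for backprop.  Dropout (inverted scaling) on hidden activations only
        when training."""
        drop = self.config.dropout_rate if training else 0.0
        h = x
        cache = []
        n_hidden = len(self.weights) - 1
        for li in range(n_hidden):
            z = h @ self.weights[li] + self.biases[li]
            a = np.maximum(z, 0.0)
            if drop > 0:
                mask = (rng.random(a.shape) >= drop) / (1.0 - drop)
                a_out = a * mask
            else:
                mask = None
                a_out = a
            cache.append((h, z, mask))
            h = a_out
        z_out = h @ self.weights[-1] + self.biases[-1]
        p = expit(z_out)
        cache.append((h, z_out, None))
        return p.ravel(), cache

    def _backward(self, probs: np.ndarray, labels: np.ndarray, cache):
        """Gradients of mean BCE w.r.t. all weights and biases."""
        n = labels.shape[0]
        delta = ((probs - labels) / n).reshape(-1, 1)  # dL/dz_out
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        h_last = cache[-1][0]
        grads_w[-1] = h_last.T @ delta
        grads_b[-1] = delta.sum(axis=0)
        upstream = delta @ self.weights[-1].T
        for li in range(len(self.weights) - 2, -1, -1):
            h_in, z, mask = cache[li]
            d = upstream
            if mask is not None:
                d = d * mask
            d = d * (z > 0)
            grads_w[li] = h_in.T @ d
            grads_b[li] = d.sum(axis=0)
            if li > 0:
                upstream = d @ self.weights[li].T
        return grads_w, grads_b

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Deterministic inference: no dropout, no input masking."""
        x = np.asarray(features, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.config.input_dimension:
            raise ContractViolationError(
                f"feature dimension {x.shape} does not match model input "
                f"dimension {self.config.input_dimension}"
            )
        p, _ = self._forward(x, training=False)
        return p

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(path / "weights.npz", **arrays)
        (path / "config.json").write_text(
            json.dumps({"model": asdict(self.config), "seed": self.seed})
        )

    @classmethod
    def load(cls, path: str | Path) -> "ParatopeMLP":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        cfg = meta["model"]
        cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
        model = cls(ModelConfig(**cfg), seed=meta.get("seed", 0))
        with np.load(path / "weights.npz") as data:
            model.weights = [data[f"w{i}"] for i in range(len(model.weights))]
            model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
        return model


def init_model(config: ModelConfig, seed: int = 0) -> ParatopeMLP:
    """Seeded, reproducible model construction."""
    return ParatopeMLP(config, seed=seed)


def predict(model: ParatopeMLP, features: np.ndarray) -> np.ndarray:
    """Per-residue paratope probabilities in [0, 1]."""
    return model.predict_proba(features)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def per_protein_pr_auc(
    model: ParatopeMLP, examples: Sequence[SequenceExample]
) -> float:
    """Validation selection metric: PR AUC per protein, averaged over the
    proteins where it is defined."""
    scores = []
    for ex in examples:
        try:
            scores.append(pr_auc(ex.labels, model.predict_proba(ex.features)))
        except UndefinedMetricError:
            continue
    if not scores:
        raise ConfigurationError(
            "validation set has no protein with both classes; "
            "the selection metric is undefined"
        )
    return float(np.mean(scores))


def train(
    model: ParatopeMLP,
    train_set: Sequence[SequenceExample],
    val_set: Sequence[SequenceExample],
    config: TrainConfig,
    validation_metric: Callable[[ParatopeMLP, Sequence[SequenceExample]], float]
    | None = None,
) -> tuple[ParatopeMLP, TrainingHistory]:
    """Train with Adam, per-sequence batching, input masking, dropout and
    early stopping; returns the model restored to its best-validation epoch.

    Batches are formed at sequence level (``batch_size_sequences`` antibodies
    per step) and the loss is averaged over all residues in the batch.  L2
    regularization is applied as weight decay on weight matrices only.
    """
    if not train_set or not val_set:
        raise ConfigurationError("train and validation sets must be non-empty")
    if validation_metric is None:
        if not any(ex.labels.sum() > 0 for ex in val_set):
            raise ConfigurationError("validation set contains no positive label")
        validation_metric = per_protein_pr_auc

    rng = np.random.default_rng(config.seed)
    params = model.weights + model.biases
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = TrainingHistory()
    best_metric = -np.inf
    best_params = model.get_parameters()
    epochs_since_improvement = 0

    n_weights = len(model.weights)
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size_sequences):
            batch = [train_set[i] for i in order[start : start + config.batch_size_sequences]]
            x = np.vstack([ex.features for ex in batch])
            y = np.concatenate([ex.labels for ex in batch]).astype(float)
            x = mask_inputs(x, config.input_mask_rate, rng)
            probs, cache = model._forward(x, training=True, rng=rng)
            epoch_losses.append(bce_loss(probs, y))
            grads_w, grads_b = model._backward(probs, y, cache)
            grads = grads_w + grads_b
            step += 1
            for i, (p, g) in enumerate(zip(params, grads)):
                if i < n_weights and config.l2_weight > 0:
                    g = g + config.l2_weight * p  # decay on weights, not biases
                m_state[i] = beta1 * m_state[i] + (1 - beta1) * g
                v_state[i] = beta2 * v_state[i] + (1 - beta2) * g * g
                m_hat = m_state[i] / (1 - beta1**step)
                v_hat = v_state[i] / (1 - beta2**step)
                p -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        history.train_loss.append(float(np.mean(epoch_losses)))
        metric = float(validation_metric(model, val_set))
        history.val_metric.append(metric)

        if metric > best_metric:
            best_metric = metric
            best_params = model.get_parameters()
            history.best_epoch = epoch
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if epochs_since_improvement >= config.early_stop_patience_epochs:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = config.max_epochs - 1

    model.set_parameters(best_params)
    return model, history
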