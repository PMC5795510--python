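"""Training loop: minibatch Adam, early stopping, warm starting, checkpoints.

The classifier minimizes cross-entropy over the seven segment classes; the
regressor minimizes the squared error of the stereographic 3-vector (mean
over the batch, summed over components), each plus an L2 weight penalty
handled inside the optimizer.  Stochastic layers (Gaussian-noise
augmentation, input dropout) are active only during training, and by
default the augmentation noise touches only windows tagged as simulated.
Everything is driven by one seeded generator, so a fixed seed reproduces
the training history bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from imu2seg.dataset_windows import DatasetSplit, stack_windows
from imu2seg.networks.layers import F32, Adam, softmax
from imu2seg.networks.model import ModelConfig, SequenceModel

__all__ = ["TrainedModel", "train", "cross_entropy_loss", "stereo_l2_loss"]


def cross_entropy_loss(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def stereo_l2_loss(pred: np.ndarray, target: np.ndarray):
    """Squared-error loss on the stereographic vector (batch mean)."""
    diff = pred - target
    loss = float(np.mean(np.sum(diff * diff, axis=1)))
    return loss, 2.0 * diff / len(pred)


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reproduce or reuse it."""

    model: SequenceModel
    config: ModelConfig
    history: list = field(default_factory=list)
    provenance: str = "cold-start"

    @property
    def task(self) -> str:
        return self.config.task

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint as <path>.npz (weights) + <path>.json (config, history)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model.get_weights())
        meta = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "history": self.history,
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = ModelConfig(**{**meta["config"], "conv": meta["config"]["conv"]})
        model = SequenceModel(config)
        with np.load(path.with_suffix(".npz")) as data:
            model.set_weights({k: data[k] for k in data.files})
        return cls(model=model, config=config, history=meta["history"],
                   provenance=meta["provenance"])


def _dataset_loss(model: SequenceModel, X, targets, task: str,
                  batch_size: int = 256) -> float:
    total, n = 0.0, len(X)
    for i in range(0, n, batch_size):
        out = model.forward(X[i:i + batch_size], training=False)
        if task == "assignment":
            loss, _ = cross_entropy_loss(out, targets[i:i + batch_size])
        else:
            loss, _ = stereo_l2_loss(out, targets[i:i + batch_size])
        total += loss * len(out)
    return total / n


def train(config: ModelConfig, split: DatasetSplit,
          warm_start: TrainedModel | None = None,
          verbose: bool = False) -> TrainedModel:
    """Train a network on a LOSO split.

    ``warm_start`` initializes the weights from a previously trained model
    with an identical architecture (shape-checked).  Early stopping watches
    the validation loss with the configured patience and restores the best
    weights before returning.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must be non-empty")
    tr = stack_windows(split.train)
    va = stack_windows(split.validation)
    task = config.task
    tr_targets = tr["y"] if task == "assignment" else tr["s"]
    va_targets = va["y"] if task == "assignment" else va["s"]

    model = SequenceModel(config)
    provenance = "cold-start"
    if warm_start is not None:
        if warm_start.config.task != task:
            raise ValueError("warm-start model solves a different task")
        model.set_weights(warm_start.model.get_weights())
        provenance = f"warm-started:{warm_start.config.config_hash()}"

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.param_handles(), lr=config.learning_rate,
                     l2=config.l2_weight)
    sim_mask_all = (tr["source"] == "simulated") if config.noise_simulated_only else None

    X = tr["X"]
    history: list[dict] = []
    best_val = np.inf
    best_weights = model.get_weights()
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(X), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = X[idx]
            mask = sim_mask_all[idx] if sim_mask_all is not None else None
            out = model.forward(xb, training=True, rng=rng, sim_mask=mask)
            if task == "assignment":
                loss, grad = cross_entropy_loss(out, tr_targets[idx])
            else:
                loss, grad = stereo_l2_loss(out, tr_targets[idx])
            model.backward(grad.astype(F32))
            optimizer.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        val_loss = _dataset_loss(model, va["X"], va_targets, task)
        history.append({"epoch": epoch, "train_loss": epoch_loss / seen,
                        "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch:3d}  train {epoch_loss / seen:.4f}  "
                  f"val {val_loss:.4f}")
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    model.set_weights(best_weights)
    return TrainedModel(model=model, config=config, history=history,
                        provenance=provenance)
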