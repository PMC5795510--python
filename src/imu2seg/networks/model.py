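"""Model configuration and the assembled convolutional-recurrent network."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from imu2seg.networks.layers import (
    F32,
    ConvBlock,
    Dense,
    GaussianNoise,
    InputDropout,
    softmax,
)
from imu2seg.networks.recurrent import GRULayer, LSTMLayer
from imu2seg.rotmath import stereographic_unproject

__all__ = ["ConvLayerSpec", "ModelConfig", "SequenceModel",
           "assignment_forward", "alignment_forward", "N_CLASSES"]

N_CLASSES = 7


@dataclass(frozen=True)
class ConvLayerSpec:
    """One temporal convolution layer: odd kernel width, feature-map count."""

    kernel: int = 9
    maps: int = 64

    def __post_init__(self) -> None:
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ValueError("kernel width must be odd and >= 3")
        if self.maps < 1:
            raise ValueError("need at least one feature map")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The defaults follow the reference architecture at full scale: four
    convolution layers of 64 maps with kernel width 9 (valid padding), two
    recurrent layers of 128 units (GRU for assignment, LSTM for alignment),
    input Gaussian noise matching the simulator's accelerometer noise,
    input dropout with keep probability 0.8, a small L2 weight penalty, and
    Adam with early stopping on the validation loss.  ``tiny`` builds the
    desk-scale variant used in CPU experiments.
    """

    task: str = "assignment"            # "assignment" | "alignment"
    conv: list = field(default_factory=lambda: [ConvLayerSpec()] * 4)
    recurrent_type: str = ""            # defaults from task if empty
    recurrent_units: list = field(default_factory=lambda: [128, 128])
    noise_sigma: tuple = (1.0, 1.0, 1.0, 0.0, 0.0, 0.0)  # acc xyz, gyr xyz
    noise_simulated_only: bool = True
    input_keep: float = 0.8
    l2_weight: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 100
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("assignment", "alignment"):
            raise ValueError("task must be 'assignment' or 'alignment'")
        if not self.recurrent_type:
            self.recurrent_type = "gru" if self.task == "assignment" else "lstm"
        if self.recurrent_type not in ("gru", "lstm"):
            raise ValueError("recurrent type must be 'gru' or 'lstm'")
        if not 0.0 < self.input_keep <= 1.0:
            raise ValueError("keep probability must be in (0, 1]")
        if self.l2_weight < 0:
            raise ValueError("L2 weight must be non-negative")
        self.conv = [c if isinstance(c, ConvLayerSpec) else ConvLayerSpec(**c)
                     for c in self.conv]

    @classmethod
    def tiny(cls, task: str, **overrides) -> "ModelConfig":
        """Desk-scale model: 2 conv layers x 32 maps, 1 recurrent layer x 64."""
        kw = dict(task=task, conv=[ConvLayerSpec(9, 32)] * 2,
                  recurrent_units=[64], max_epochs=30, patience=5)
        kw.update(overrides)
        return cls(**kw)

    @property
    def out_dim(self) -> int:
        return N_CLASSES if self.task == "assignment" else 3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv"] = [asdict(c) for c in self.conv]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


class SequenceModel:
    """Gaussian noise -> input dropout -> conv stack -> recurrent stack -> head."""

    def __init__(self, config: ModelConfig, n_channels: int = 6) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.noise = GaussianNoise(np.asarray(config.noise_sigma))
        self.dropout = InputDropout(config.input_keep)
        self.blocks = []
        c = n_channels
        for spec in config.conv:
            self.blocks.append(ConvBlock(c, spec.maps, spec.kernel, rng))
            c = spec.maps
        rnn_cls = GRULayer if config.recurrent_type == "gru" else LSTMLayer
        self.rnns = []
        for units in config.recurrent_units:
            self.rnns.append(rnn_cls(c, units, rng))
            c = units
        self.head = Dense(c, config.out_dim, rng)
        self._layers = [self.noise, self.dropout, *self.blocks, *self.rnns,
                        self.head]

    # ------------------------------------------------------------------
    def output_length(self, t: int = 128) -> int:
        """Sequence length after the valid-padding convolution stack."""
        for spec in self.config.conv:
            t -= spec.kernel - 1
        if t < 1:
            raise ValueError("conv stack longer than the input window")
        return t

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                sim_mask: np.ndarray | None = None) -> np.ndarray:
        """Network output for a batch (N, T, 6): logits (N, 7) or stereo (N, 3)."""
        x = np.asarray(x)
        if x.dtype != np.float64:      # float64 kept for numerical checks
            x = x.astype(F32)
        x = self.noise.forward(x, training=training, rng=rng, sim_mask=sim_mask)
        x = self.dropout.forward(x, training=training, rng=rng)
        for blk in self.blocks:
            x = blk.forward(x, training=training, rng=rng)
        for rnn in self.rnns:
            x = rnn.forward(x, training=training, rng=rng)
        self._t_out = x.shape[1]
        return self.head.forward(x[:, -1], training=training, rng=rng)

    def backward(self, dout: np.ndarray) -> None:
        dlast = self.head.backward(np.asarray(dout))
        dH = np.zeros((dlast.shape[0], self._t_out, dlast.shape[1]),
                      dtype=dlast.dtype)
        dH[:, -1] = dlast
        for rnn in reversed(self.rnns):
            dH = rnn.backward(dH)
        dy = dH
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        self.dropout.backward(dy)

    # ------------------------------------------------------------------
    def param_handles(self) -> list:
        handles = []
        for layer in self._iter_param_layers():
            for name in layer.params:
                handles.append((layer, name))
        return handles

    def _iter_param_layers(self):
        for blk in self.blocks:
            yield blk.conv
            yield blk.bn
        yield from self.rnns
        yield self.head

    def get_weights(self) -> dict:
        """Flat name -> array snapshot, including batch-norm running stats."""
        out = {}
        for i, (layer, name) in enumerate(self.param_handles()):
            out[f"p{i}_{name}"] = layer.params[name].copy()
        for j, blk in enumerate(self.blocks):
            out[f"bn{j}_mean"] = blk.bn.running_mean.copy()
            out[f"bn{j}_var"] = blk.bn.running_var.copy()
        return out

    def set_weights(self, weights: dict) -> None:
        for i, (layer, name) in enumerate(self.param_handles()):
            key = f"p{i}_{name}"
            if weights[key].shape != layer.params[name].shape:
                raise ValueError(f"shape mismatch for {key}: "
                                 f"{weights[key].shape} vs {layer.params[name].shape}")
            layer.params[name] = weights[key].astype(F32).copy()
        for j, blk in enumerate(self.blocks):
            blk.bn.running_mean = weights[f"bn{j}_mean"].astype(F32).copy()
            blk.bn.running_var = weights[f"bn{j}_var"].astype(F32).copy()

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference in batches (stochastic layers off, BN running stats)."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i:i + batch_size], training=False))
        return np.concatenate(outs, axis=0)


# ----------------------------------------------------------------------
# task-specific views
# ----------------------------------------------------------------------

def assignment_forward(window, model: SequenceModel) -> np.ndarray:
    """Class-probability 7-vector for one window (softmax over the logits)."""
    if model.config.task != "assignment":
        raise ValueError("model was not built for the assignment task")
    data = window.data if hasattr(window, "data") else np.asarray(window)
    logits = model.forward(data[None], training=False)
    return softmax(logits)[0]


def alignment_forward(window, model: SequenceModel,
                      decode: bool = False):
    """Stereographic alignment estimate for one window.

    With ``decode=True`` returns the corresponding unit quaternion instead.
    """
    if model.config.task != "alignment":
        raise ValueError("model was not built for the alignment task")
    data = window.data if hasattr(window, "data") else np.asarray(window)
    s = model.forward(data[None], training=False)[0]
    if decode:
        return stereographic_unproject(s)
    return s
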