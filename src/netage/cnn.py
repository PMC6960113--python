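"""VGG-style 3D CNN for voxelwise brain-age regression.

The network maps one gray-matter network image (a single-channel 3D volume)
to a scalar predicted age.  The architecture is five repeated stacks of

    conv 3x3x3 (stride 1, pad 1) -> ReLU ->
    conv 3x3x3 (stride 1, pad 1) -> batch norm -> ReLU ->
    max pool 2x2x2 (stride 2)

with the channel count starting at ``base_channels`` in the first stack and
doubling after every pooling layer, followed by three fully connected layers
ending in a single output.  Conv and FC weights use He (fan-in) init with
zero biases.  Training is mini-batch SGD with momentum, weight decay and an
MAE loss, with a step learning-rate decay.

Training at the full acquisition grid (121 x 145 x 121, 200 epochs) is
configuration-reachable; the desk-scale profile used throughout the tests is
a 32-voxel (or smaller) grid with ``base_channels`` 4 and tens of epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn


@dataclass(frozen=True)
class ArchSpec:
    """Architecture hyperparameters.

    ``fc_widths`` are the two hidden fully connected widths; the final
    layer always has width 1 (the predicted age).
    """

    input_dims: tuple[int, int, int] = (121, 145, 121)
    n_stacks: int = 5
    base_channels: int = 8
    fc_widths: tuple[int, int] = (128, 64)
    input_channels: int = 1

    def __post_init__(self) -> None:
        if self.n_stacks < 1 or self.base_channels < 1 or self.input_channels < 1:
            raise ValueError("n_stacks, base_channels, input_channels must be >= 1")
        if any(w < 1 for w in self.fc_widths) or len(self.fc_widths) != 2:
            raise ValueError("fc_widths must be two positive hidden widths")
        feature_map_shape(self.input_dims, self.n_stacks)  # raises SizingError

    @property
    def channel_schedule(self) -> tuple[int, ...]:
        """Output channels per stack: base * 2^(stack-1)."""
        return tuple(self.base_channels * 2**s for s in range(self.n_stacks))


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (defaults follow the study protocol)."""

    batch_size: int = 16
    learning_rate: float = 0.01
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 10
    lr_decay_mode: str = "step"  # "step": decay every N epochs; "once": only at N
    weight_decay: float = 0.0005
    momentum: float = 0.9
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if min(self.learning_rate, self.lr_decay_factor, self.momentum + 1) <= 0:
            raise ValueError("rates must be positive")
        if self.lr_decay_mode not in ("step", "once"):
            raise ValueError("lr_decay_mode must be 'step' or 'once'")

    def lr_at(self, epoch: int) -> float:
        """Learning rate in force during ``epoch`` (0-based)."""
        if self.lr_decay_mode == "step":
            k = epoch // self.lr_decay_every
        else:
            k = 1 if epoch >= self.lr_decay_every else 0
        return self.learning_rate * self.lr_decay_factor**k


class SizingError(ValueError):
    """Input grid collapses below one voxel before the final pooling stage."""


def feature_map_shape(
    input_dims: Sequence[int], n_stacks: int
) -> tuple[int, int, int]:
    """Spatial dims after ``n_stacks`` floor-halving pools.

    The 3x3x3 / stride 1 / padding 1 convolutions preserve spatial size, so
    only the pools shrink the grid: each dim is floor-halved per stack.
    """
    dims = [int(d) for d in input_dims]
    if any(d < 1 for d in dims):
        raise ValueError("input dims must be positive")
    for s in range(n_stacks):
        dims = [d // 2 for d in dims]
        if any(d < 1 for d in dims):
            raise SizingError(
                f"input {tuple(input_dims)} collapses below 1 voxel at stack "
                f"{s + 1} of {n_stacks}"
            )
    return tuple(dims)  # type: ignore[return-value]


def parameter_count(arch: ArchSpec) -> int:
    """Closed-form trainable-parameter count for the architecture.

    Each stack holds two 3x3x3 convs (27 * c_in * c_out + c_out each) and one
    batch norm (2 * c_out); each FC layer holds w_in * w_out + w_out.
    """
    total = 0
    c_in = arch.input_channels
    for c_out in arch.channel_schedule:
        total += 27 * c_in * c_out + c_out  # conv 1
        total += 27 * c_out * c_out + c_out  # conv 2
        total += 2 * c_out  # batch norm gamma/beta
        c_in = c_out
    spatial = feature_map_shape(arch.input_dims, arch.n_stacks)
    w_in = c_in * int(np.prod(spatial))
    for w_out in (*arch.fc_widths, 1):
        total += w_in * w_out + w_out
        w_in = w_out
    return total


def build_cnn(
    arch: ArchSpec, seed: int = 0, dtype=np.float32
) -> nn.Sequential:
    """Instantiate the untrained network with He-initialized weights."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = arch.input_channels
    for c_out in arch.channel_schedule:
        layers += [
            nn.Conv3d(c_in, c_out, rng, dtype),
            nn.ReLU(),
            nn.Conv3d(c_out, c_out, rng, dtype),
            nn.BatchNorm3d(c_out, dtype),
            nn.ReLU(),
            nn.MaxPool3d(),
        ]
        c_in = c_out
    spatial = feature_map_shape(arch.input_dims, arch.n_stacks)
    layers.append(nn.Flatten())
    w_in = c_in * int(np.prod(spatial))
    for w_out in arch.fc_widths:
        layers += [nn.Linear(w_in, w_out, rng, dtype), nn.ReLU()]
        w_in = w_out
    layers.append(nn.Linear(w_in, 1, rng, dtype))
    return nn.Sequential(layers)


@dataclass
class TrainedCnn:
    """A trained network plus its provenance and training history."""

    arch: ArchSpec
    config: TrainingConfig
    model: nn.Sequential
    history: list[dict] = field(default_factory=list)  # epoch, lr, train_mae

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) with a JSON sidecar (arch + config + history)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model.state_arrays())
        sidecar = {
            "arch": asdict(self.arch),
            "config": asdict(self.config),
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedCnn":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        arch_d = sidecar["arch"]
        for key in ("input_dims", "fc_widths"):
            arch_d[key] = tuple(arch_d[key])
        arch = ArchSpec(**arch_d)
        config = TrainingConfig(**sidecar["config"])
        model = build_cnn(arch, seed=config.seed)
        with np.load(path.with_suffix(".npz")) as state:
            model.load_state_arrays(dict(state))
        return cls(arch=arch, config=config, model=model,
                   history=sidecar["history"])


def _as_batch(images: np.ndarray, arch: ArchSpec) -> np.ndarray:
    """Coerce (n, D, H, W) volumes to the channels-last batch layout."""
    x = np.asarray(images)
    if x.ndim == 4:
        x = x[..., None]
    if x.ndim != 5 or tuple(x.shape[1:4]) != tuple(arch.input_dims):
        raise ValueError(
            f"images must be (n, {arch.input_dims[0]}, {arch.input_dims[1]}, "
            f"{arch.input_dims[2]}), got {x.shape}"
        )
    return x


def recalibrate_batchnorm(
    model: nn.Sequential, images: np.ndarray, batch_size: int = 16
) -> None:
    """Recompute batch-norm running statistics over a reference set.

    The exponential moving average tracked during SGD lags behind the final
    weights, which can leave inference-mode outputs with a large constant
    offset even when training converged.  One pass over the training set in
    batch-statistics mode, averaging each layer's per-batch mean/variance,
    pins the running statistics to the final weights.  Called by
    :func:`train_cnn` after the last epoch.
    """
    bn_layers = [l for l in model.layers if isinstance(l, nn.BatchNorm3d)]
    if not bn_layers:
        return
    sums = {id(l): [0.0, 0.0, 0.0] for l in bn_layers}  # mean, var, weight
    n = images.shape[0]
    for start in range(0, n, batch_size):
        batch = images[start : start + batch_size]
        model.forward(batch, train=True)
        w = batch.shape[0]
        for layer in bn_layers:
            acc = sums[id(layer)]
            acc[0] += w * layer.last_batch_mean
            acc[1] += w * layer.last_batch_var
            acc[2] += w
    for layer in bn_layers:
        mean_sum, var_sum, weight = sums[id(layer)]
        layer.running_mean = mean_sum / weight
        layer.running_var = var_sum / weight
        layer._cache = None


def train_cnn(
    model: nn.Sequential,
    images: np.ndarray,
    ages: np.ndarray,
    config: TrainingConfig,
    arch: ArchSpec,
    verbose: bool = False,
) -> TrainedCnn:
    """Train the network with mini-batch SGD + momentum on the MAE loss.

    Shuffling is reseeded per epoch from ``config.seed``; the final partial
    batch is used.  Returns the trained model with per-epoch mean training
    MAE recorded in ``history``.
    """
    x = _as_batch(images, arch).astype(np.float32)
    y = np.asarray(ages, dtype=np.float32).ravel()
    if not np.isfinite(y).all():
        raise ValueError("ages contain NaN or infinite values")
    if not np.isfinite(x).all():
        raise ValueError("images contain NaN or infinite voxels")
    if x.shape[0] != y.size:
        raise ValueError(f"{x.shape[0]} images but {y.size} ages")

    opt = nn.SGD(
        model.params,
        lr=config.learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    history: list[dict] = []
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model.forward(x[idx], train=True)[:, 0]
            loss, dpred = nn.mae_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the inputs"
                )
            model.backward(dpred[:, None])
            opt.step()
            losses.append(loss)
            weights.append(idx.size)
        epoch_mae = float(np.average(losses, weights=weights))
        history.append({"epoch": epoch, "lr": opt.lr, "train_mae": epoch_mae})
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  train MAE {epoch_mae:.3f}")
    if history:
        recalibrate_batchnorm(model, x, config.batch_size)
    return TrainedCnn(arch=arch, config=config, model=model, history=history)


def predict_cnn(
    trained: TrainedCnn | nn.Sequential,
    images: np.ndarray,
    arch: ArchSpec | None = None,
    batch_size: int = 16,
) -> np.ndarray:
    """Predict ages in inference mode (batch norm uses running statistics)."""
    if isinstance(trained, TrainedCnn):
        model, arch = trained.model, trained.arch
    else:
        model = trained
        if arch is None:
            raise ValueError("arch required when passing a bare model")
    x = _as_batch(images, arch).astype(np.float32)
    preds = []
    for start in range(0, x.shape[0], batch_size):
        preds.append(model.forward(x[start : start + batch_size], train=False)[:, 0])
    out = np.concatenate(preds) if preds else np.empty(0, dtype=np.float32)
    return out.astype(np.float64)
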