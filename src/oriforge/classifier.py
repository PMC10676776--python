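"""The origin-of-replication classifier and its training loop.

The model stacks ``n_blocks`` identical structure blocks followed by an MLP.
One block is: single-head self-attention over the feature components,
a same-padded 1-D convolution with ELU activation, average pooling along the
token axis, and nearest-neighbour up-sampling that restores the token count.
The flat Z-space feature vector (dimension D in {12, 48, 60, 192, 204, 240,
252}) enters as a length-D token sequence with one channel; attention and
convolution lift it to ``conv_channels`` channels.  The MLP flattens the
final block's output and maps it through ELU hidden layers to a single
sigmoid probability that the input sequence is a replication origin.

Training minimises mean binary cross-entropy with Adam (learning rate 2e-4,
batch size 64 by default), with early stopping on validation loss; the
parameters from the best validation epoch are returned.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import elu, scaled_dot_attention, sigmoid  # noqa: F401  (public API)
from .zcurve import ADMISSIBLE_DIMS


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class BlockConfig:
    """Geometry of one structure block."""

    conv_kernel: int = 3
    conv_channels: int = 8
    pool_size: int = 2
    upsample_factor: int = 2
    elu_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.conv_kernel < 1 or self.conv_kernel % 2 == 0:
            raise ConfigError("conv_kernel must be an odd positive integer")
        if self.upsample_factor != self.pool_size:
            raise ConfigError(
                "upsample_factor must equal pool_size so each block preserves "
                "the token-sequence length"
            )
        if self.elu_alpha <= 0:
            raise ConfigError("elu_alpha must be positive")


@dataclass(frozen=True)
class ClassifierConfig:
    n_blocks: int = 3
    block: BlockConfig = field(default_factory=BlockConfig)
    mlp_hidden: tuple[int, ...] = (64, 16)
    input_dim: int = 252
    use_attention: bool = True  # ablation hook: drop the attention layers

    def __post_init__(self) -> None:
        if self.input_dim not in ADMISSIBLE_DIMS:
            raise ConfigError(
                f"input_dim must be one of {sorted(ADMISSIBLE_DIMS)}, got {self.input_dim}"
            )
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if self.input_dim % self.block.pool_size:
            raise ConfigError("input_dim must be divisible by pool_size")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.0002
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ConfigError("learning_rate and batch_size must be positive")


def bce_loss(y, y_hat, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy; predictions are clamped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_hat, dtype=np.float64), eps, 1.0 - eps)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))


class OriClassifier:
    """A built model: layer stack, its config, and training history."""

    def __init__(self, config: ClassifierConfig, net: nn.Sequential, seed: int):
        self.config = config
        self.net = net
        self.seed = seed
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- inference -----------------------------------------------------
    def logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=nn.DTYPE)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input dimension {X.shape[1]} != configured {self.config.input_dim}"
            )
        return self.net.forward(X[:, :, None], train=train)[:, 0]

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """ORI probabilities in [0, 1]; scalar for a single 1-D input."""
        X = np.asarray(X, dtype=nn.DTYPE)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        out = np.concatenate(
            [sigmoid(self.logits(X[i : i + batch_size])) for i in range(0, len(X), batch_size)]
        )
        return float(out[0]) if single else out

    # -- persistence ---------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.net.params()]

    def load_state(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.net.params(), values, strict=True):
            p.value[...] = v

    def save(self, path: "str | Path") -> None:
        """Binary checkpoint (.npz) plus a JSON config sidecar (.json)."""
        path = Path(path)
        with open(path, "wb") as fh:  # exact path; np.savez would append .npz
            np.savez(fh, **{f"p{i}": v for i, v in enumerate(self.state_dict())})
        cfg = asdict(self.config)
        cfg["block"] = asdict(self.config.block)
        sidecar = {"config": cfg, "seed": self.seed}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: "str | Path") -> "OriClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        cfg_d = sidecar["config"]
        cfg_d["block"] = BlockConfig(**cfg_d["block"])
        cfg_d["mlp_hidden"] = tuple(cfg_d["mlp_hidden"])
        model = build_model(ClassifierConfig(**cfg_d), seed=sidecar["seed"])
        with np.load(path) as npz:
            model.load_state([npz[f"p{i}"] for i in range(len(npz.files))])
        return model


def build_model(config: ClassifierConfig | None = None, seed: int = 0) -> OriClassifier:
    """Initialise an untrained model; same seed gives bitwise-identical weights."""
    config = config or ClassifierConfig()
    rng = np.random.default_rng(seed)
    b = config.block
    layers: list[nn.Layer] = []
    in_ch = 1
    for _ in range(config.n_blocks):
        if config.use_attention:
            layers.append(nn.SelfAttention(in_ch, b.conv_channels, b.conv_channels, rng))
            in_ch = b.conv_channels
        layers.append(nn.Conv1d(in_ch, b.conv_channels, b.conv_kernel, rng))
        layers.append(nn.ELU(b.elu_alpha))
        layers.append(nn.AvgPool1d(b.pool_size))
        layers.append(nn.Upsample1d(b.upsample_factor))
        in_ch = b.conv_channels
    layers.append(nn.Flatten())
    d = config.input_dim * in_ch
    for h in config.mlp_hidden:
        layers.append(nn.Linear(d, h, rng))
        layers.append(nn.ELU(b.elu_alpha))
        d = h
    layers.append(nn.Linear(d, 1, rng))
    return OriClassifier(config, nn.Sequential(layers), seed)


def forward(z: np.ndarray, model: OriClassifier) -> "float | np.ndarray":
    """Probability that the encoded sequence(s) are replication origins."""
    return model.predict_proba(z)


def _check_two_classes(y: np.ndarray, name: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{name} set contains a single class; training needs both")


def train(
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cconfig: ClassifierConfig | None = None,
    tconfig: TrainConfig | None = None,
) -> OriClassifier:
    """Fit the classifier with Adam on mean BCE, early-stopped on validation loss.

    Returns the model restored to the parameters of the best validation epoch,
    with per-epoch train/val losses in ``model.history``.
    """
    cconfig = cconfig or ClassifierConfig()
    tconfig = tconfig or TrainConfig()
    X, y = (np.asarray(a) for a in train_set)
    Xv, yv = (np.asarray(a) for a in val_set)
    _check_two_classes(y, "training")
    _check_two_classes(yv, "validation")

    model = build_model(cconfig, seed=tconfig.seed)
    opt = nn.Adam(model.net.params(), lr=tconfig.learning_rate)
    rng = np.random.default_rng(tconfig.seed + 1)

    best_loss, best_state, best_epoch = math.inf, model.state_dict(), -1
    n = len(X)
    for epoch in range(tconfig.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tconfig.batch_size):
            idx = order[start : start + tconfig.batch_size]
            xb, yb = X[idx], y[idx]
            logit = model.logits(xb, train=True)
            # stable BCE on logits: softplus(l) - y*l
            epoch_loss += float(np.sum(np.logaddexp(0.0, logit) - yb * logit))
            model.net.zero_grad()
            g = ((sigmoid(logit) - yb) / len(idx)).astype(nn.DTYPE)
            model.net.backward(g[:, None])
            opt.step()
        val_loss = bce_loss(yv, model.predict_proba(Xv))
        model.history["train_loss"].append(epoch_loss / n)
        model.history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-9:
            best_loss, best_state, best_epoch = val_loss, model.state_dict(), epoch
        elif epoch - best_epoch >= tconfig.patience:
            break
    model.load_state(best_state)
    model.history["best_epoch"] = [best_epoch]
    return model
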