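"""1D and 3D bottleneck residual networks for maturity classification and
SSC regression.

Both tasks share an identical trunk — a large-kernel strided stem
convolution (receptive-field expansion near the input), three bottleneck
residual stages with small kernels, global average pooling and dropout —
and differ only in the dense head (4 logits vs 1 scalar) and the loss
(softmax cross-entropy vs L2).  Defaults follow the study protocol:
dropout 0.3, Adam, classification 1000 epochs at lr 0.01, regression 1500
epochs at lr 1e-4.  Inputs are additionally standardized per band with
training-set statistics before entering the network.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn

__all__ = ["ModelConfig", "TrainedModel", "TrainingError", "build_resnet_1d", "build_resnet_3d", "train", "predict"]

TASK_DEFAULTS = {
    "classification": {"epochs": 1000, "learning_rate": 0.01, "loss": "softmax_cross_entropy"},
    "regression": {"epochs": 1500, "learning_rate": 0.0001, "loss": "l2"},
}


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int, message: str):
        super().__init__(f"epoch {epoch}: {message}")
        self.epoch = epoch


@dataclass
class ModelConfig:
    """Architecture and optimization settings for one residual network."""

    input_kind: str = "spectrum"  # "spectrum" | "cube"
    task: str = "classification"  # "classification" | "regression"
    n_bands: int = 400
    spatial_dims: tuple[int, int] | None = None  # (rows, cols), 3D only
    n_classes: int = 4
    stem_kernel: int = 7
    stem_stride: int = 2
    stage_widths: tuple[int, ...] = (16, 32, 64)
    blocks_per_stage: int = 1
    bottleneck_compression: int = 4
    dropout: float = 0.3
    epochs: int | None = None
    learning_rate: float | None = None
    batch_size: int = 32
    seed: int = 0
    standardize_inputs: bool = True
    dtype: str | None = None  # default: float64 for spectra, float32 for cubes

    def __post_init__(self) -> None:
        if self.task not in TASK_DEFAULTS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.input_kind not in ("spectrum", "cube"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.input_kind == "cube" and self.spatial_dims is None:
            raise ValueError("cube models need spatial_dims")

    @property
    def resolved_epochs(self) -> int:
        return self.epochs if self.epochs is not None else TASK_DEFAULTS[self.task]["epochs"]

    @property
    def resolved_lr(self) -> float:
        return self.learning_rate if self.learning_rate is not None else TASK_DEFAULTS[self.task]["learning_rate"]

    @property
    def loss_name(self) -> str:
        return TASK_DEFAULTS[self.task]["loss"]

    @property
    def n_outputs(self) -> int:
        return self.n_classes if self.task == "classification" else 1

    @property
    def resolved_dtype(self) -> np.dtype:
        if self.dtype is not None:
            return np.dtype(self.dtype)
        return np.dtype(np.float64 if self.input_kind == "spectrum" else np.float32)


class ResNet:
    """The assembled network: trunk + head, with loss dispatch."""

    def __init__(self, trunk: nn.Sequential, head: nn.Sequential, config: ModelConfig):
        self.trunk = trunk
        self.head = head
        self.config = config

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.head.forward(self.trunk.forward(x, train), train)

    def backward(self, dout: np.ndarray, need_input_grad: bool = False) -> np.ndarray | None:
        dh = self.head.backward(dout, need_input_grad=True)
        return self.trunk.backward(dh, need_input_grad=need_input_grad)

    def params(self) -> list[nn.Param]:
        return self.trunk.params() + self.head.params()

    def trunk_param_shapes(self) -> list[tuple[int, ...]]:
        return [p.value.shape for p in self.trunk.params()]

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self) -> dict:
        """Snapshot of all trainable parameters and BN running statistics
        (both are needed to restore a consistent network)."""
        return {
            "params": [p.value.copy() for p in self.params()],
            "bn": [(b.running_mean.copy(), b.running_var.copy()) for b in _iter_batchnorms(self)],
        }

    def set_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.value[...] = v
        for b, (mean, var) in zip(_iter_batchnorms(self), state["bn"]):
            b.running_mean = mean.copy()
            b.running_var = var.copy()

    def loss(self, out: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        if self.config.loss_name == "softmax_cross_entropy":
            return nn.softmax_cross_entropy(out, targets)
        return nn.l2_loss(out, targets)


def _build(conv_cls, config: ModelConfig, rng: np.random.Generator, dims: tuple[int, ...]) -> ResNet:
    dtype = config.resolved_dtype
    mk_bn = lambda ch, name: nn.BatchNorm(ch, dtype=dtype, name=name)
    w0 = config.stage_widths[0]
    layers: list[nn.Layer] = [
        conv_cls(1, w0, config.stem_kernel, stride=config.stem_stride, rng=rng, dtype=dtype, name="stem"),
        mk_bn(w0, "stem_bn"),
        nn.ReLU(),
    ]
    dims = tuple((d + 2 * (config.stem_kernel // 2) - config.stem_kernel) // config.stem_stride + 1 for d in dims)
    in_ch = w0
    for si, width in enumerate(config.stage_widths):
        mid = max(1, width // config.bottleneck_compression)
        for bi in range(config.blocks_per_stage):
            stride = 2 if bi == 0 else 1
            layers.append(
                nn.Bottleneck(conv_cls, in_ch, width, mid, stride, rng=rng, dtype=dtype, name=f"s{si}b{bi}")
            )
            if stride == 2:
                new_dims = tuple((d + 2 * 1 - 3) // 2 + 1 for d in dims)
                if any(d < 1 for d in new_dims):
                    raise ValueError(f"input too small for the stride plan at stage {si} (dims {dims})")
                dims = new_dims
            in_ch = width
    layers += [mk_bn(in_ch, "final_bn"), nn.ReLU(), nn.GlobalAvgPool()]
    trunk = nn.Sequential(layers)
    head = nn.Sequential(
        [nn.Dropout(config.dropout, rng), nn.Dense(in_ch, config.n_outputs, rng=rng, dtype=dtype, name="head")]
    )
    return ResNet(trunk, head, config)


def build_resnet_1d(config: ModelConfig) -> ResNet:
    """Residual network over (N, 1, n_bands) spectra."""
    if config.input_kind != "spectrum":
        raise ValueError("build_resnet_1d expects input_kind='spectrum'")
    if config.n_bands < 32:
        raise ValueError(f"need n_bands >= 32 for the stride plan, got {config.n_bands}")
    rng = np.random.default_rng(config.seed)
    return _build(nn.Conv1d, config, rng, (config.n_bands,))


def build_resnet_3d(config: ModelConfig) -> ResNet:
    """Residual network over (N, 1, rows, cols, n_bands) cubes."""
    if config.input_kind != "cube":
        raise ValueError("build_resnet_3d expects input_kind='cube'")
    r, c = config.spatial_dims
    if r < 16 or c < 16:
        raise ValueError(f"need spatial dims >= 16, got {config.spatial_dims}")
    if config.n_bands < 32:
        raise ValueError(f"need n_bands >= 32, got {config.n_bands}")
    rng = np.random.default_rng(config.seed)
    return _build(nn.Conv3d, config, rng, (r, c, config.n_bands))


def _to_net_input(X: np.ndarray, config: ModelConfig) -> np.ndarray:
    X = np.asarray(X, dtype=config.resolved_dtype)
    if config.input_kind == "spectrum":
        if X.ndim != 2:
            raise ValueError(f"spectrum input must be (N, n_bands), got shape {X.shape}")
        if X.shape[1] != config.n_bands:
            raise ValueError(f"expected {config.n_bands} bands, got {X.shape[1]}")
        return X[:, None, :]
    if X.ndim != 4:
        raise ValueError(f"cube input must be (N, rows, cols, bands), got shape {X.shape}")
    if X.shape[1:] != (*config.spatial_dims, config.n_bands):
        raise ValueError(f"expected cubes of shape {(*config.spatial_dims, config.n_bands)}, got {X.shape[1:]}")
    return X[:, None, :, :, :]


@dataclass
class Scaler:
    """Per-band standardization fitted on the training set."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X_net: np.ndarray) -> "Scaler":
        axes = tuple(i for i in range(X_net.ndim) if i != X_net.ndim - 1)
        mean = X_net.mean(axis=axes)
        sd = X_net.std(axis=axes)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mean, sd)

    def transform(self, X_net: np.ndarray) -> np.ndarray:
        return (X_net - self.mean) / self.sd

    @classmethod
    def identity(cls, n_bands: int, dtype) -> "Scaler":
        return cls(np.zeros(n_bands, dtype=dtype), np.ones(n_bands, dtype=dtype))


@dataclass
class TrainedModel:
    """A fitted network plus its scaler, training log and task kind.

    After training the network carries the best-validation snapshot (the
    final-epoch parameters are kept in ``final_state``).
    """

    net: ResNet
    config: ModelConfig
    scaler: Scaler
    log: pd.DataFrame
    task: str
    final_state: list[np.ndarray] = field(default_factory=list, repr=False)

    def _standardized(self, X: np.ndarray) -> np.ndarray:
        x = _to_net_input(X, self.config)
        return self.scaler.transform(x).astype(self.config.resolved_dtype)

    def forward_raw(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._standardized(X), train)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("predict_proba is for classification models")
        return nn.softmax(self.forward_raw(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = self.forward_raw(X)
        if self.task == "classification":
            return np.argmax(out, axis=1)
        return out.reshape(-1)


def predict(model: TrainedModel, samples: np.ndarray) -> dict:
    """Apply a trained model in eval mode (dropout off, BN running stats).

    Classification returns per-class probabilities and argmax labels;
    regression returns scalar SSC estimates.
    """
    if model.task == "classification":
        probs = model.predict_proba(samples)
        return {"probabilities": probs, "labels": np.argmax(probs, axis=1)}
    return {"values": model.predict(samples)}


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model (parameters, BN statistics, scaler, config,
    log) to an ``.npz`` checkpoint plus the architecture config as JSON."""
    import dataclasses
    import json

    state = model.net.get_state()
    arrays = {f"param_{i}": v for i, v in enumerate(state["params"])}
    bn_stats = {}
    for i, (mean, var) in enumerate(state["bn"]):
        bn_stats[f"bn_mean_{i}"] = mean
        bn_stats[f"bn_var_{i}"] = var
    np.savez(
        path,
        **arrays,
        **bn_stats,
        scaler_mean=model.scaler.mean,
        scaler_sd=model.scaler.sd,
        config=json.dumps(dataclasses.asdict(model.config)),
        log=model.log.to_csv(index=False),
    )


def load_model(path) -> TrainedModel:
    """Rebuild a :class:`TrainedModel` from a checkpoint written by
    :func:`save_model`."""
    import json

    data = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(str(data["config"]))
    for key in ("stage_widths", "spatial_dims"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    net = build_resnet_1d(config) if config.input_kind == "spectrum" else build_resnet_3d(config)
    n_params = len([k for k in data.files if k.startswith("param_")])
    n_bn = len([k for k in data.files if k.startswith("bn_mean_")])
    net.set_state(
        {
            "params": [data[f"param_{i}"] for i in range(n_params)],
            "bn": [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"]) for i in range(n_bn)],
        }
    )
    scaler = Scaler(data["scaler_mean"], data["scaler_sd"])
    import io

    log = pd.read_csv(io.StringIO(str(data["log"])))
    return TrainedModel(net=net, config=config, scaler=scaler, log=log, task=config.task)


def _iter_batchnorms(net: ResNet):
    def walk(layer):
        if isinstance(layer, nn.BatchNorm):
            yield layer
        elif isinstance(layer, nn.Sequential):
            for sub in layer.layers:
                yield from walk(sub)
        elif isinstance(layer, nn.Bottleneck):
            yield from walk(layer.main)
            if layer.shortcut is not None:
                yield from walk(layer.shortcut)

    for part in (net.trunk, net.head):
        yield from walk(part)


def train(
    net: ResNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Adam optimization for the configured number of epochs.

    Logs per-epoch train/validation losses (and the validation metric:
    accuracy for classification, RMSE for regression), retains the
    best-validation snapshot, and is deterministic given ``config.seed``.
    """
    config = config or net.config
    if len(X_train) == 0:
        raise ValueError("empty training set")
    dtype = config.resolved_dtype
    Xtr = _to_net_input(X_train, config)
    if config.task == "classification":
        ytr = np.asarray(y_train, dtype=int)
        if ytr.min() < 0 or ytr.max() >= config.n_classes:
            raise ValueError("labels out of range for the configured class count")
    else:
        ytr = np.asarray(y_train, dtype=dtype)
    scaler = Scaler.fit(Xtr) if config.standardize_inputs else Scaler.identity(config.n_bands, dtype)
    Xtr = scaler.transform(Xtr).astype(dtype)
    has_val = X_val is not None and len(X_val) > 0
    if has_val:
        Xva = scaler.transform(_to_net_input(X_val, config)).astype(dtype)
        yva = np.asarray(y_val, dtype=int if config.task == "classification" else dtype)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9151]))
    opt = nn.Adam(net.params(), lr=config.resolved_lr)
    n = Xtr.shape[0]
    batch = min(config.batch_size, n)
    rows = []
    best_val = np.inf
    best_state = net.get_state()
    for epoch in range(config.resolved_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            out = net.forward(Xtr[idx], train=True)
            loss, dout = net.loss(out, ytr[idx])
            if not np.isfinite(loss):
                raise TrainingError(epoch, f"non-finite training loss ({loss})")
            epoch_loss += loss * idx.size
            opt.zero_grad()
            net.backward(dout, need_input_grad=False)
            opt.step()
        epoch_loss /= n
        val_loss = np.nan
        val_metric = np.nan
        if has_val:
            val_out = net.forward(Xva, train=False)
            val_loss, _ = net.loss(val_out, yva)
            if config.task == "classification":
                val_metric = float(np.mean(np.argmax(val_out, axis=1) == yva))
            else:
                val_metric = float(np.sqrt(np.mean((val_out.reshape(-1) - yva) ** 2)))
            if val_loss < best_val:
                best_val = val_loss
                best_state = net.get_state()
        rows.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss, "val_metric": val_metric}
        )
    final_state = net.get_state()
    if has_val:
        net.set_state(best_state)
    log = pd.DataFrame(rows)
    return TrainedModel(net=net, config=config, scaler=scaler, log=log, task=config.task, final_state=final_state)
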