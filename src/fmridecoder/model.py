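"""The 3D residual task-decoding CNN.

Layer order: a 1×1×1 convolution that treats the k input frames as channels
and compresses them to a few temporal descriptor channels (27 → 3 by
default), a strided 3×3×3 convolution, four residual blocks with 32/64/64/128
output channels (stride 2 in the last three), a final "full" convolution
whose kernel equals the incoming feature-map extent (replacing global
pooling, so the map collapses to 1×1×1), and two fully connected layers
(64-wide, then the class head with softmax). ReLU + batch normalization
follow every convolution.

Several structural details (conv2 width, convs per residual block, bias
placement, shortcut style, final-conv width) are not uniquely determined by
the published description; the defaults below were fixed by enumerating the
candidate space and keeping the unique configuration consistent with the
stated stride plan, "same" 3×3×3 padding, and the published total of
3,981,852 trainable parameters on the 75×93×81 grid.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .io import Bold4DSample, VolumeGrid
from .nn import (
    Adam,
    BatchNorm3d,
    Conv3d,
    Flatten,
    Linear,
    ReLU,
    ResidualBlock,
    Sequential,
    softmax,
)

__all__ = [
    "ArchitectureConfig",
    "TaskCNN",
    "build_model",
    "count_parameters",
    "expected_parameter_count",
    "describe_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """All structural hyperparameters of the CNN (calibrated defaults)."""

    input_frames: int = 27
    n_ch1: int = 3
    conv2_channels: int = 48
    conv2_stride: int = 2
    block_channels: tuple[int, int, int, int] = (32, 64, 64, 128)
    block_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    kernel_size: int = 3
    convs_per_block: int = 1
    conv_bias: bool = False
    projection_kernel: int = 3
    projection_bias: bool = True
    projection_bn: bool = False
    final_conv_channels: int = 135
    fc_width: int = 64
    n_classes: int = 7

    def __post_init__(self):
        if self.n_ch1 < 1:
            raise ValueError("n_ch1 must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.block_channels) != 4 or len(self.block_strides) != 4:
            raise ValueError("exactly four residual blocks are expected")
        if self.convs_per_block not in (1, 2):
            raise ValueError("convs_per_block must be 1 or 2")


def _conv_out(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def feature_map_shape(cfg: ArchitectureConfig, grid_shape) -> tuple[int, int, int]:
    """Spatial extent entering the final full convolution."""
    k, p = cfg.kernel_size, cfg.kernel_size // 2
    shape = tuple(_conv_out(n, k, cfg.conv2_stride, p) for n in grid_shape)
    for s in cfg.block_strides:
        shape = tuple(_conv_out(n, k, s, p) for n in shape)
        if min(shape) < 1:
            raise ValueError(
                f"grid {tuple(grid_shape)} collapses below one voxel in a "
                f"strided residual block"
            )
    return shape


class TaskCNN:
    """The assembled network plus its config and target grid."""

    def __init__(self, cfg: ArchitectureConfig, grid: VolumeGrid, net: Sequential):
        self.cfg = cfg
        self.grid = grid
        self.net = net

    # -- inference -------------------------------------------------------
    def forward_logits(self, x: np.ndarray, mode: str = "eval") -> np.ndarray:
        """Logits for a batch ``(N, k, x, y, z)`` (frames lead as channels)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1] != self.cfg.input_frames:
            raise ValueError(
                f"expected {self.cfg.input_frames} frames, got {x.shape[1]}"
            )
        if tuple(x.shape[2:]) != self.grid.shape:
            raise ValueError(
                f"expected grid {self.grid.shape}, got {tuple(x.shape[2:])}"
            )
        return self.net.forward(x, mode)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(x, mode="eval"))

    def forward_sample(self, sample: Bold4DSample) -> np.ndarray:
        """Class probabilities for one sample; deterministic in eval mode."""
        return self.predict_proba(sample.data[None])[0]

    def backward(self, grad_logits: np.ndarray, guided: bool = False) -> np.ndarray:
        return self.net.backward(grad_logits, guided)

    def input_gradient(self, x: np.ndarray, target_class: int,
                       guided: bool = True) -> np.ndarray:
        """d logit[target]/d input for one 4-D fragment, in inference mode."""
        logits = self.forward_logits(np.asarray(x)[None], mode="eval")
        if not 0 <= target_class < self.cfg.n_classes:
            raise IndexError(f"target_class {target_class} out of range")
        seed = np.zeros_like(logits)
        seed[0, target_class] = 1.0
        return self.backward(seed, guided=guided)[0]

    # -- bookkeeping -----------------------------------------------------
    def params(self):
        return self.net.params()

    def n_parameters(self) -> int:
        return count_parameters(self)

    def trunk_params(self):
        """All parameters except the classification head (last Linear)."""
        head = self.net.layers[-1].params()
        head_ids = {id(p) for p in head}
        return [p for p in self.params() if id(p) not in head_ids]


def _conv_bn_relu(cin, cout, k, stride, padding, bias):
    return [Conv3d(cin, cout, k, stride=stride, padding=padding, bias=bias),
            BatchNorm3d(cout), ReLU()]


def build_model(cfg: ArchitectureConfig = ArchitectureConfig(),
                grid: VolumeGrid | None = None,
                seed: int = 0) -> TaskCNN:
    """Instantiate the network for a grid; weights are He-initialized."""
    if grid is None:
        grid = VolumeGrid(shape=(75, 93, 81))
    k = cfg.kernel_size
    p = k // 2
    layers: list = []
    # 1x1x1 temporal compression: k frames as channels -> n_ch1 descriptors
    layers += _conv_bn_relu(cfg.input_frames, cfg.n_ch1, 1, 1, 0, cfg.conv_bias)
    # strided stem conv
    layers += _conv_bn_relu(cfg.n_ch1, cfg.conv2_channels, k, cfg.conv2_stride,
                            p, cfg.conv_bias)
    cin = cfg.conv2_channels
    for cout, s in zip(cfg.block_channels, cfg.block_strides):
        main = [Conv3d(cin, cout, k, stride=s, padding=p, bias=cfg.conv_bias),
                BatchNorm3d(cout)]
        if cfg.convs_per_block == 2:
            main += [ReLU(),
                     Conv3d(cout, cout, k, stride=1, padding=p, bias=cfg.conv_bias),
                     BatchNorm3d(cout)]
        shortcut = None
        if cin != cout or s != 1:
            pk = cfg.projection_kernel
            sc = [Conv3d(cin, cout, pk, stride=s, padding=pk // 2,
                         bias=cfg.projection_bias)]
            if cfg.projection_bn:
                sc.append(BatchNorm3d(cout))
            shortcut = Sequential(*sc)
        layers.append(ResidualBlock(Sequential(*main), shortcut))
        cin = cout
    fshape = feature_map_shape(cfg, grid.shape)
    layers += _conv_bn_relu(cin, cfg.final_conv_channels, fshape, 1, 0, cfg.conv_bias)
    layers.append(Flatten())
    layers.append(Linear(cfg.final_conv_channels, cfg.fc_width))
    layers.append(ReLU())
    layers.append(Linear(cfg.fc_width, cfg.n_classes))
    net = Sequential(*layers)
    net.initialize(np.random.default_rng(seed))
    return TaskCNN(cfg, grid, net)


def count_parameters(model: TaskCNN) -> int:
    """Number of trainable scalars, by enumerating the actual arrays."""
    return int(sum(p.size for p in model.params()))


def expected_parameter_count(cfg: ArchitectureConfig, grid_shape=(75, 93, 81)) -> int:
    """Closed-form per-layer parameter count (independent of the arrays).

    Each convolution contributes cout*cin*prod(kernel) (+cout bias) and its
    batch norm 2*cout; fully connected layers contribute dout*(din+1).
    """
    kvol = cfg.kernel_size ** 3
    bias = 1 if cfg.conv_bias else 0
    total = cfg.n_ch1 * (cfg.input_frames + bias) + 2 * cfg.n_ch1
    total += cfg.conv2_channels * (kvol * cfg.n_ch1 + bias) + 2 * cfg.conv2_channels
    cin = cfg.conv2_channels
    for cout, s in zip(cfg.block_channels, cfg.block_strides):
        total += cout * (kvol * cin + bias) + 2 * cout
        if cfg.convs_per_block == 2:
            total += cout * (kvol * cout + bias) + 2 * cout
        if cin != cout or s != 1:
            total += cout * (cfg.projection_kernel ** 3 * cin +
                             (1 if cfg.projection_bias else 0))
            if cfg.projection_bn:
                total += 2 * cout
        cin = cout
    fshape = feature_map_shape(cfg, grid_shape)
    total += cfg.final_conv_channels * (int(np.prod(fshape)) * cin + bias)
    total += 2 * cfg.final_conv_channels
    total += cfg.fc_width * (cfg.final_conv_channels + 1)
    total += cfg.n_classes * (cfg.fc_width + 1)
    return int(total)


def describe_model(model: TaskCNN) -> str:
    """Human-readable per-layer parameter table."""
    lines = [f"{'layer':<28}{'params':>12}"]

    def walk(layer, prefix=""):
        name = type(layer).__name__
        if isinstance(layer, Sequential):
            for i, sub in enumerate(layer.layers):
                walk(sub, f"{prefix}{i}.")
        elif isinstance(layer, ResidualBlock):
            walk(layer.main, prefix + "main.")
            if layer.shortcut is not None:
                walk(layer.shortcut, prefix + "short.")
        else:
            n = sum(p.size for p in layer.params())
            if n:
                lines.append(f"{prefix + name:<28}{n:>12,}")

    walk(model.net)
    lines.append(f"{'total':<28}{count_parameters(model):>12,}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _state_arrays(model: TaskCNN) -> dict[str, np.ndarray]:
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"param_{i}"] = p.value
    bn_idx = 0
    for layer in _iter_layers(model.net):
        if isinstance(layer, BatchNorm3d):
            arrays[f"bn_{bn_idx}_mean"] = layer.running_mean
            arrays[f"bn_{bn_idx}_var"] = layer.running_var
            bn_idx += 1
    return arrays


def _iter_layers(layer):
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    elif isinstance(layer, ResidualBlock):
        yield from _iter_layers(layer.main)
        if layer.shortcut is not None:
            yield from _iter_layers(layer.shortcut)
        yield layer.out_relu
    else:
        yield layer


def save_checkpoint(model: TaskCNN, path) -> None:
    """Single-file checkpoint: weights, BN statistics and embedded config."""
    meta = json.dumps({"cfg": asdict(model.cfg), "grid": list(model.grid.shape)})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **_state_arrays(model))


def load_checkpoint(path) -> TaskCNN:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_dict = meta["cfg"]
        cfg_dict["block_channels"] = tuple(cfg_dict["block_channels"])
        cfg_dict["block_strides"] = tuple(cfg_dict["block_strides"])
        cfg = ArchitectureConfig(**cfg_dict)
        model = build_model(cfg, VolumeGrid(shape=tuple(meta["grid"])))
        for i, p in enumerate(model.params()):
            p.value = z[f"param_{i}"].copy()
        bn_idx = 0
        for layer in _iter_layers(model.net):
            if isinstance(layer, BatchNorm3d):
                layer.running_mean = z[f"bn_{bn_idx}_mean"].copy()
                layer.running_var = z[f"bn_{bn_idx}_var"].copy()
                bn_idx += 1
    return model


def clone_model(model: TaskCNN, n_classes: int | None = None,
                seed: int = 0) -> TaskCNN:
    """Copy a model, optionally with a fresh classification head.

    Trunk weights and BN statistics are copied; when ``n_classes`` differs,
    the head Linear is re-initialized (the transfer-learning starting point).
    """
    from dataclasses import replace

    cfg = model.cfg if n_classes is None else replace(model.cfg, n_classes=n_classes)
    new = build_model(cfg, model.grid, seed=seed)
    old_params = model.params()
    new_params = new.params()
    n_head = len(new.net.layers[-1].params())
    for po, pn in zip(old_params[:-n_head], new_params[:-n_head]):
        pn.value = po.value.copy()
    bns_old = [l for l in _iter_layers(model.net) if isinstance(l, BatchNorm3d)]
    bns_new = [l for l in _iter_layers(new.net) if isinstance(l, BatchNorm3d)]
    for bo, bn in zip(bns_old, bns_new):
        bn.running_mean = bo.running_mean.copy()
        bn.running_var = bo.running_var.copy()
    return new
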