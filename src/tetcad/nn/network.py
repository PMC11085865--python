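"""The multi-state ECG network: block stack, classifier and checkpoints.

The backbone is a stack of 13 state-context blocks.  Each block composes
three stages::

    depthwise Dk x Dk (intra-state)  ->  [BN, ReLU]
    grouped 1x1, one group per lead (inter-state)  ->  [BN, ReLU]
    dense 1x1 channel mixing in_ch -> out_ch  ->  [BN, ReLU]

The default channel schedule is 36 -> 72, 72, 72, 144, 144, 288, 288, 288,
288, 576, 576, 576, 576 with stride 2 in the stem block's depthwise stage,
a 3x3/2 max pool after the stem, and stride 2 in the depthwise stage of
blocks 4, 6 and 10 -- the minimal schedule consistent with spatial sizes
224 -> 112 -> 56 -> 28 -> 14 -> 7.  Global average pooling feeds a
576 -> 128 -> 2 classifier with a softmax over (non-CAD, CAD).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm2d, Dense, DepthwiseConv2d, GlobalAvgPool, GroupedPointwise,
    Identity, Layer, MaxPool2d, Param, ReLU, softmax,
)

__all__ = [
    "BlockConfig", "NetworkConfig", "MultiStateNet", "DiagnosisPrediction",
    "build_network", "CLASS_NAMES",
]

CLASS_NAMES = ("non-CAD", "CAD")
"""Output class order: index 1 is the positive (CAD) class."""

DEFAULT_BLOCK_CHANNELS = (72, 72, 72, 144, 144, 288, 288, 288, 288, 576, 576, 576, 576)
DEFAULT_STRIDE2_BLOCKS = (1, 4, 6, 10)  # 1-based block indices with stride 2


@dataclass(frozen=True)
class BlockConfig:
    """Per-block parameters of one state-context block."""

    in_channels: int
    out_channels: int
    dk: int = 3
    stride: int = 1
    groups: int = 12
    with_norm: bool = True
    with_act: bool = True
    inter_state: str = "grouped"  # "grouped" | "identity" (ablation)

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.inter_state not in ("grouped", "identity"):
            raise ValueError(f"unknown inter_state mode {self.inter_state!r}")
        if self.inter_state == "grouped" and (
            self.in_channels % self.groups or self.out_channels % self.groups
        ):
            raise ValueError(
                f"block channels {self.in_channels}->{self.out_channels} not "
                f"divisible by groups={self.groups}"
            )


@dataclass(frozen=True)
class NetworkConfig:
    """Whole-network configuration (defaults reproduce the 13-block stack)."""

    input_size: int = 224
    in_channels: int = 36
    groups: int = 12
    num_classes: int = 2
    block_channels: tuple[int, ...] = DEFAULT_BLOCK_CHANNELS
    stride2_blocks: tuple[int, ...] = DEFAULT_STRIDE2_BLOCKS
    stem_dk: int = 7
    dk: int = 3
    pool_after_stem: bool = True
    hidden_features: int = 128
    with_norm: bool = True
    inter_state: str = "grouped"

    def blocks(self) -> list[BlockConfig]:
        cfgs = []
        in_ch = self.in_channels
        for b, out_ch in enumerate(self.block_channels, start=1):
            cfgs.append(BlockConfig(
                in_channels=in_ch,
                out_channels=out_ch,
                dk=self.stem_dk if b == 1 else self.dk,
                stride=2 if b in self.stride2_blocks else 1,
                groups=self.groups,
                with_norm=self.with_norm,
                inter_state=self.inter_state,
            ))
            in_ch = out_ch
        return cfgs


@dataclass
class DiagnosisPrediction:
    """Per-sample prediction: class probabilities and thresholded label."""

    probabilities: np.ndarray  # (p_nonCAD, p_CAD)
    threshold: float = 0.5
    label: str = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (2,) or p.min() < 0 or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"invalid probability pair {p}")
        self.probabilities = p
        # predictions at or above the threshold are called positive
        self.label = "CAD" if p[1] >= self.threshold else "non-CAD"

    @property
    def p_cad(self) -> float:
        return float(self.probabilities[1])


def _build_block(cfg: BlockConfig, rng: np.random.Generator, idx: int) -> list[Layer]:
    name = f"block{idx}"
    layers: list[Layer] = [DepthwiseConv2d(
        cfg.in_channels, cfg.dk, stride=cfg.stride, rng=rng, tie=3,
        name=f"{name}.intra",
    )]
    if cfg.with_norm:
        layers.append(BatchNorm2d(cfg.in_channels, name=f"{name}.intra_bn"))
    if cfg.with_act:
        layers.append(ReLU())
    if cfg.inter_state == "grouped":
        layers.append(GroupedPointwise(
            cfg.in_channels, cfg.in_channels, groups=cfg.groups, rng=rng,
            init="identity", name=f"{name}.inter",
        ))
    else:
        # ablation: the mixing conv becomes the identity but the stage's
        # norm/activation stay, so depth and capacity remain comparable
        rng.normal(0.0, 0.05, size=(cfg.groups,
                                    cfg.in_channels // cfg.groups,
                                    cfg.in_channels // cfg.groups))  # keep rng stream aligned
        layers.append(Identity())
    if cfg.with_norm:
        layers.append(BatchNorm2d(cfg.in_channels, name=f"{name}.inter_bn"))
    if cfg.with_act:
        layers.append(ReLU())
    layers.append(GroupedPointwise(
        cfg.in_channels, cfg.out_channels, groups=1, rng=rng, name=f"{name}.mix"
    ))
    if cfg.with_norm:
        layers.append(BatchNorm2d(cfg.out_channels, name=f"{name}.mix_bn"))
    if cfg.with_act:
        layers.append(ReLU())
    return layers


class StateContextBlock:
    """Thin composite over one block's layer slice (used for forward of a
    single block in tests; the model itself runs the flat layer list)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class MultiStateNet:
    """The full network: backbone blocks + pooled classifier head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks: list[StateContextBlock] = []
        backbone: list[Layer] = []
        shape = (config.input_size, config.input_size, config.in_channels)
        self.shape_table: list[tuple[str, tuple[int, int, int]]] = [("input", shape)]
        for idx, bcfg in enumerate(config.blocks(), start=1):
            block_layers = _build_block(bcfg, rng, idx)
            for layer in block_layers:
                shape = self._propagate(layer, shape, f"block{idx}")
            self.blocks.append(StateContextBlock(block_layers))
            backbone.extend(block_layers)
            self.shape_table.append((f"block{idx}", shape))
            if idx == 1 and config.pool_after_stem:
                pool = MaxPool2d(k=3, stride=2, pad=1, name="stem_pool")
                shape = self._propagate(pool, shape, "stem_pool")
                backbone.append(pool)
                self.shape_table.append(("stem_pool", shape))
        self.prepool_shape = shape
        self.avgpool = GlobalAvgPool()
        if shape[2] != config.block_channels[-1]:
            raise ValueError(
                f"classifier: expected {config.block_channels[-1]} pooled "
                f"features, got {shape[2]}"
            )
        self.fc1 = Dense(shape[2], config.hidden_features, rng=rng, name="fc1")
        self.fc_act = ReLU()
        self.fc2 = Dense(config.hidden_features, config.num_classes, rng=rng, name="fc2")
        self.backbone_layers = backbone
        self.classifier_layers: list[Layer] = [self.avgpool, self.fc1, self.fc_act, self.fc2]
        self.layers: list[Layer] = backbone + self.classifier_layers

    @staticmethod
    def _propagate(layer: Layer, shape, where: str):
        try:
            return layer.out_shape(shape)
        except ValueError as exc:
            raise ValueError(f"inconsistent configuration at {where}: {exc}") from exc

    # ------------------------------------------------------------------
    def param_groups(self) -> dict[str, list[Param]]:
        """Parameters split into the two optimizer groups."""
        backbone = [p for layer in self.backbone_layers for p in layer.params()]
        classifier = [p for layer in self.classifier_layers for p in layer.params()]
        return {"backbone": backbone, "classifier": classifier}

    def params(self) -> list[Param]:
        groups = self.param_groups()
        return groups["backbone"] + groups["classifier"]

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        expected = (self.config.input_size, self.config.input_size, self.config.in_channels)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != expected:
            raise ValueError(f"expected input of shape {expected}, got {x.shape[1:]}")
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 30) -> np.ndarray:
        """Class probabilities, deterministic inference mode."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        chunks = [
            softmax(self.forward_logits(x[i:i + batch_size], training=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 30) -> list[DiagnosisPrediction]:
        return [DiagnosisPrediction(probabilities=p)
                for p in self.predict_proba(x, batch_size=batch_size)]

    def summary(self) -> str:
        lines = [f"{name:12s} {h}x{w}x{c}" for name, (h, w, c) in self.shape_table]
        lines.append(f"{'avgpool':12s} 1x1x{self.prepool_shape[2]}")
        lines.append(f"{'fc1':12s} 1x1x{self.config.hidden_features}")
        lines.append(f"{'fc2':12s} 1x1x{self.config.num_classes}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: npz of weights + JSON config header."""
        arrays = {f"param/{p.name}": p.value for p in self.params()}
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                arrays[f"buffer/{layer.name}.running_mean"] = layer.running_mean
                arrays[f"buffer/{layer.name}.running_var"] = layer.running_var
        header = json.dumps({
            "config": asdict(self.config),
            "class_names": list(CLASS_NAMES),
            "channel_convention": "c = 3*lead_index + state_index",
        })
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with open(path, "wb") as fh:
            fh.write(len(header).to_bytes(8, "little"))
            fh.write(header.encode())
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "MultiStateNet":
        with open(path, "rb") as fh:
            hlen = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(hlen).decode())
            data = np.load(io.BytesIO(fh.read()))
        cfg_dict = header["config"]
        for key in ("block_channels", "stride2_blocks"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(NetworkConfig(**cfg_dict))
        by_name = {p.name: p for p in model.params()}
        for key in data.files:
            kind, name = key.split("/", 1)
            if kind == "param":
                by_name[name].value[...] = data[key]
            else:
                base, attr = name.rsplit(".", 1)
                for layer in model.layers:
                    if isinstance(layer, BatchNorm2d) and layer.name == base:
                        setattr(layer, attr, data[key].copy())
        return model


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> MultiStateNet:
    """Build the network, failing loudly on any shape inconsistency."""
    return MultiStateNet(config or NetworkConfig(), seed=seed)
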