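"""Analytic multiply-accumulate (MAC) counting.

Convention: one MAC = one multiply-add.  For a convolution,

    MACs = H_out * W_out * Dk^2 * (C_in / groups) * C_out

per sample; for a linear layer, MACs = in_features * out_features.
Biases, normalization, activations and pooling are excluded.  The counter
covers the default multi-state network and an analytic count of the
standard 18-layer residual topology for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import NetworkConfig

__all__ = ["MacCount", "conv_macs", "linear_macs", "count_macs",
           "resnet18_macs", "reduction_percent"]


@dataclass
class MacCount:
    """Per-layer MAC counts and their total."""

    layers: list[tuple[str, int]]

    @property
    def total(self) -> int:
        return sum(macs for _, macs in self.layers)

    def table(self) -> str:
        width = max(len(name) for name, _ in self.layers)
        lines = [f"{name:<{width}}  {macs:>14,d}" for name, macs in self.layers]
        lines.append(f"{'total':<{width}}  {self.total:>14,d}")
        return "\n".join(lines)


def conv_macs(h_out: int, w_out: int, dk: int, c_in: int, c_out: int,
              groups: int = 1) -> int:
    if c_in % groups:
        raise ValueError(f"c_in={c_in} not divisible by groups={groups}")
    return h_out * w_out * dk * dk * (c_in // groups) * c_out


def linear_macs(in_features: int, out_features: int) -> int:
    return in_features * out_features


def _conv_out(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def count_macs(config: NetworkConfig | None = None) -> MacCount:
    """Per-layer MACs of the multi-state network under *config*."""
    config = config or NetworkConfig()
    layers: list[tuple[str, int]] = []
    size = config.input_size
    for idx, block in enumerate(config.blocks(), start=1):
        size = _conv_out(size, block.dk, block.stride, block.dk // 2)
        layers.append((
            f"block{idx}.intra",
            conv_macs(size, size, block.dk, block.in_channels,
                      block.in_channels, groups=block.in_channels),
        ))
        if block.inter_state == "grouped":
            layers.append((
                f"block{idx}.inter",
                conv_macs(size, size, 1, block.in_channels, block.in_channels,
                          groups=block.groups),
            ))
        layers.append((
            f"block{idx}.mix",
            conv_macs(size, size, 1, block.in_channels, block.out_channels),
        ))
        if idx == 1 and config.pool_after_stem:
            size = _conv_out(size, 3, 2, 1)
    layers.append(("fc1", linear_macs(config.block_channels[-1], config.hidden_features)))
    layers.append(("fc2", linear_macs(config.hidden_features, config.num_classes)))
    return MacCount(layers=layers)


def resnet18_macs(input_size: int = 224, in_channels: int = 3,
                  num_classes: int = 1000) -> MacCount:
    """Analytic MACs of the standard 18-layer residual topology.

    7x7/2 stem (64), 3x3/2 max pool, four stages of two basic blocks at
    64/128/256/512 channels with stride-2 stage transitions and 1x1
    projection shortcuts, global average pool, final linear.  The canonical
    (3-channel, 1000-class) and adapted (36-channel, 2-class) variants are
    both expressible through the parameters.
    """
    layers: list[tuple[str, int]] = []
    size = _conv_out(input_size, 7, 2, 3)
    layers.append(("stem", conv_macs(size, size, 7, in_channels, 64)))
    size = _conv_out(size, 3, 2, 1)  # max pool, no MACs
    channels = in_stage = 64
    for stage, channels in enumerate((64, 128, 256, 512), start=1):
        for block in (1, 2):
            stride = 2 if (stage > 1 and block == 1) else 1
            if stride == 2:
                size = _conv_out(size, 3, stride, 1)
            layers.append((
                f"stage{stage}.block{block}.conv1",
                conv_macs(size, size, 3, in_stage, channels),
            ))
            layers.append((
                f"stage{stage}.block{block}.conv2",
                conv_macs(size, size, 3, channels, channels),
            ))
            if in_stage != channels:
                layers.append((
                    f"stage{stage}.block{block}.proj",
                    conv_macs(size, size, 1, in_stage, channels),
                ))
            in_stage = channels
    layers.append(("fc", linear_macs(512, num_classes)))
    return MacCount(layers=layers)


def reduction_percent(ours: MacCount, reference: MacCount) -> float:
    """Percentage reduction 100 * (1 - ours/reference)."""
    return 100.0 * (1.0 - ours.total / reference.total)
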