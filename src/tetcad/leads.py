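"""Lead splitting and assembly of the 36-channel multi-state input.

Each clean state image is split into 12 per-lead patches according to the
lead tile layout; the three states' patches are stacked into an
H x W x 36 tensor with the channel convention

    channel c = 3 * g + s

where ``g`` is the lead index in ``lead_order`` and ``s`` indexes the
state (0 pretest, 1 exercise, 2 recovery).  Keeping one lead's three state
channels contiguous aligns the 12-group inter-state convolution's groups
with leads by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from . import LEAD_NAMES, STATES
from . import defaults
from .preprocess import CropRect, crop_region

__all__ = [
    "LeadLayout", "MultiStateTensor", "split_leads", "assemble_tensor",
    "disassemble_tensor", "save_tensor", "load_tensor",
]

STATE_INDEX = {state: s for s, state in enumerate(STATES)}


@dataclass(frozen=True)
class LeadLayout:
    """12 lead tiles on a page: a rows x cols grid or explicit rectangles.

    ``lead_order`` gives the lead name of each tile in row-major order.
    """

    rows: int = defaults.LEAD_GRID[0]
    cols: int = defaults.LEAD_GRID[1]
    lead_order: tuple[str, ...] = LEAD_NAMES
    rects: tuple[CropRect, ...] | None = None

    def __post_init__(self) -> None:
        if self.rows * self.cols != 12:
            raise ValueError(f"lead layout must tile 12 leads, got {self.rows}x{self.cols}")
        if sorted(self.lead_order) != sorted(LEAD_NAMES):
            raise ValueError("lead_order must be a permutation of the 12 standard leads")
        if self.rects is not None and len(self.rects) != 12:
            raise ValueError(f"explicit layout needs 12 tiles, got {len(self.rects)}")

    def tile_rects(self, image_shape: tuple[int, int]) -> tuple[CropRect, ...]:
        """The 12 tile rectangles for an image of the given (H, W) shape."""
        if self.rects is not None:
            return self.rects
        h, w = image_shape[:2]
        row_edges = [round(i * h / self.rows) for i in range(self.rows + 1)]
        col_edges = [round(j * w / self.cols) for j in range(self.cols + 1)]
        rects = []
        for i in range(self.rows):
            for j in range(self.cols):
                rects.append(CropRect(
                    left=col_edges[j], top=row_edges[i],
                    width=col_edges[j + 1] - col_edges[j],
                    height=row_edges[i + 1] - row_edges[i],
                ))
        return tuple(rects)


@dataclass
class MultiStateTensor:
    """The H x W x 36 network input with its channel bookkeeping."""

    values: np.ndarray  # float32 in [0, 1]
    lead_order: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[2] != 36:
            raise ValueError(f"expected an (H, W, 36) tensor, got {self.values.shape}")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("tensor intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def channel(self, lead: int | str, state: str) -> np.ndarray:
        """The single channel for (lead, state); lead by index or name."""
        g = lead if isinstance(lead, int) else self.lead_order.index(lead)
        return self.values[:, :, 3 * g + STATE_INDEX[state]]


def split_leads(image: np.ndarray, layout: LeadLayout = LeadLayout()) -> list[np.ndarray]:
    """Split one state image into 12 per-lead patches in lead order."""
    return [crop_region(image, rect) for rect in layout.tile_rects(image.shape)]


def _resize_patch(patch: np.ndarray, size: int) -> np.ndarray:
    # area-average downsampling keeps a binary patch's gray coverage fraction
    arr = np.asarray(patch, dtype=np.float32)
    if arr.shape == (size, size):
        return arr
    img = Image.fromarray(arr, mode="F")
    return np.asarray(img.resize((size, size), Image.Resampling.BOX), dtype=np.float32)


def assemble_tensor(
    patches_by_state: Mapping[str, Sequence[np.ndarray]],
    target_size: int = defaults.INPUT_SIZE,
    lead_order: tuple[str, ...] = LEAD_NAMES,
) -> MultiStateTensor:
    """Assemble 3 x 12 patches into the multi-state tensor.

    Each patch is area-resampled to ``target_size`` squared and rescaled
    from [0, 255] to [0, 1]; patch (g, s) lands on channel ``3 g + s``.
    """
    missing = [s for s in STATES if s not in patches_by_state]
    if missing:
        raise ValueError(f"missing state patch set(s): {', '.join(missing)}")
    values = np.empty((target_size, target_size, 36), dtype=np.float32)
    for s, state in enumerate(STATES):
        patches = list(patches_by_state[state])
        if len(patches) != 12:
            raise ValueError(
                f"state {state!r}: expected 12 lead patches, got {len(patches)}"
            )
        for g, patch in enumerate(patches):
            values[:, :, 3 * g + s] = _resize_patch(patch, target_size) / 255.0
    return MultiStateTensor(values=values, lead_order=lead_order)


def disassemble_tensor(tensor: MultiStateTensor) -> dict[str, list[np.ndarray]]:
    """Recover the per-state lead patches (at tensor resolution, [0, 255])."""
    out: dict[str, list[np.ndarray]] = {}
    for s, state in enumerate(STATES):
        out[state] = [tensor.values[:, :, 3 * g + s] * 255.0 for g in range(12)]
    return out


def save_tensor(tensor: MultiStateTensor, path: str | Path) -> None:
    """Persist a tensor plus a JSON manifest of its channel convention."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), values=tensor.values)
    manifest = {
        "lead_order": list(tensor.lead_order),
        "states": list(STATES),
        "channel_convention": "c = 3*lead_index + state_index",
        "shape": list(tensor.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_tensor(path: str | Path) -> MultiStateTensor:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        values = data["values"]
    return MultiStateTensor(values=values, lead_order=tuple(manifest["lead_order"]))
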