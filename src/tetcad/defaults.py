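"""Shared layout defaults for report pages and the network input.

The page geometry mirrors the simplified report dialect the synthetic
generator emits: a text banner across the top carrying the state keyword,
and a 6x2 grid of lead tiles over a light grid background below it.
"""

PAGE_SIZE = (1080, 640)
"""Report page resolution as (width, height) pixels."""

BANNER_HEIGHT = 40
"""Rows at the top of a page reserved for the state-keyword banner."""

GRID_STEP = 20
"""Spacing of the background grid lines, pixels."""

GRID_VALUE = 220
"""Gray level of background grid lines (traces are drawn at 0)."""

LEAD_GRID = (6, 2)
"""Lead tile layout (rows, cols) on a page; rows * cols == 12."""

BINARIZE_THRESHOLD = 128
"""Default grayscale threshold separating traces from grid/background."""

INPUT_SIZE = 224
"""Default network input side length."""
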