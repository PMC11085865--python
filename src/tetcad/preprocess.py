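"""Report preprocessing: rendering, state identification, cropping, binarization.

A simplified TET report is a three-page document, one 12-lead ECG page per
physiological state.  Preprocessing turns it into three clean binary ECG
images in canonical state order:

    render -> identify states (OCR text) -> crop -> grayscale -> binarize

State identification is driven by an injected text extractor so that the
pipeline runs identically with a real OCR engine (production) or with the
generator's sidecar truth files (tests, offline environments).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from . import STATES
from . import defaults
from . import pdfio

__all__ = [
    "StatePageImage", "CropRect", "BinarizationSpec", "PreprocessConfig",
    "render_report", "normalize_text", "match_state_keyword",
    "identify_state_pages", "crop_region", "to_grayscale", "binarize",
    "preprocess_report", "SidecarTextExtractor", "TesseractTextExtractor",
    "MissingStateError", "default_config", "load_config",
]


class MissingStateError(ValueError):
    """Raised when a report lacks a page for one or more states."""

    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(f"no page matched state(s): {', '.join(missing)}")


@dataclass
class StatePageImage:
    """One rendered report page with its (possibly unknown) state."""

    pixels: np.ndarray  # (H, W) grayscale or (H, W, 3) RGB, uint8
    state: str | None = None
    source_page_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3) or 0 in self.pixels.shape[:2]:
            raise ValueError(f"invalid page pixel array of shape {self.pixels.shape}")


@dataclass(frozen=True)
class CropRect:
    """Pixel rectangle: 0-based, top-left origin, half-open on right/bottom."""

    left: int
    top: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"crop rectangle must have positive size, got {self}")
        if self.left < 0 or self.top < 0:
            raise ValueError(f"crop rectangle origin must be non-negative, got {self}")


@dataclass(frozen=True)
class BinarizationSpec:
    """Threshold and polarity for trace/background separation.

    With the default ``trace_dark_on_white`` polarity, pixels strictly above
    the threshold become background (255) and pixels at or below it become
    trace (0); the opposite polarity inverts that mapping.
    """

    threshold: int = defaults.BINARIZE_THRESHOLD
    polarity: str = "trace_dark_on_white"

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.polarity not in ("trace_dark_on_white", "trace_light_on_black"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


# ---------------------------------------------------------------------------
# rendering


def _resize(arr: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Area-average (box) resample of a uint8 image to (width, height)."""
    w, h = target_size
    if arr.shape[1] == w and arr.shape[0] == h:
        return arr
    img = Image.fromarray(arr)
    return np.asarray(img.resize((w, h), Image.Resampling.BOX))


def render_report(
    source,
    target_size: tuple[int, int] = defaults.PAGE_SIZE,
) -> list[StatePageImage]:
    """Render a report document into per-page rasters at *target_size*.

    *source* may be a multi-page PDF path, a directory of page images
    (read in sorted filename order), or a sequence of pixel arrays.
    States are left unset; pages already at the target size pass through
    unchanged.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(
                p for p in path.iterdir()
                if p.suffix.lower() in (".png", ".tif", ".tiff", ".bmp")
            )
            if not files:
                raise ValueError(f"{path}: directory contains no page images")
            arrays = [np.asarray(Image.open(p)) for p in files]
        elif path.suffix.lower() == ".pdf":
            arrays = pdfio.read_pdf(path)
        elif path.exists():
            arrays = [np.asarray(Image.open(path))]
        else:
            raise FileNotFoundError(path)
    else:
        arrays = [np.asarray(a) for a in source]
        if not arrays:
            raise ValueError("document contains no pages")
    return [
        StatePageImage(pixels=_resize(a, target_size), source_page_index=i)
        for i, a in enumerate(arrays)
    ]


# ---------------------------------------------------------------------------
# state identification

_NORMALIZE_RE = re.compile(r"[^a-z0-9]+")


def normalize_text(raw: str) -> str:
    """Lowercase and strip every character outside a-z, 0-9.

    Removing separators as well makes OCR variants such as "Pre-test" and
    "PRE TEST" match the keyword "pretest" by substring.
    """
    return _NORMALIZE_RE.sub("", raw.lower())


def match_state_keyword(normalized: str) -> str | None:
    """First state keyword (priority pretest > exercise > recovery) found
    as a substring of already-normalized text, or ``None``."""
    for state in STATES:
        if state in normalized:
            return state
    return None


TextExtractor = Callable[[StatePageImage], str]


def identify_state_pages(
    pages: Sequence[StatePageImage],
    text_extractor: TextExtractor,
) -> dict[str, int]:
    """Map each state to the first page whose extracted text matches it.

    Raises :class:`MissingStateError` naming every state that no page
    matched.  Keyword priority makes a single page match at most one state.
    """
    mapping: dict[str, int] = {}
    for i, page in enumerate(pages):
        state = match_state_keyword(normalize_text(text_extractor(page)))
        if state is not None and state not in mapping:
            mapping[state] = i
    missing = [s for s in STATES if s not in mapping]
    if missing:
        raise MissingStateError(missing)
    return mapping


class SidecarTextExtractor:
    """Text extractor backed by the generator's ``truth.json`` sidecars.

    Stands in for a real OCR engine: for page *i* it returns the true state
    keyword recorded at generation time.
    """

    def __init__(self, texts: Sequence[str]):
        self._texts = list(texts)

    @classmethod
    def from_patient_dir(cls, patient_dir: str | Path) -> "SidecarTextExtractor":
        """Build from a patient directory containing ``truth.json``.

        Page order follows sorted filenames, matching
        :func:`render_report` on the same directory.
        """
        patient_dir = Path(patient_dir)
        truth = json.loads((patient_dir / "truth.json").read_text())
        by_file = truth["pages"]
        return cls([by_file[name] for name in sorted(by_file)])

    def __call__(self, page: StatePageImage) -> str:
        return self._texts[page.source_page_index]


class TesseractTextExtractor:
    """Adapter around the tesseract OCR engine (optional dependency)."""

    def __init__(self) -> None:
        try:
            import pytesseract  # type: ignore
        except ImportError as exc:  # pragma: no cover - depends on environment
            raise RuntimeError(
                "pytesseract is not installed; install the 'ocr' extra or "
                "use the sidecar stub extractor"
            ) from exc
        self._engine = pytesseract

    def __call__(self, page: StatePageImage) -> str:  # pragma: no cover
        return self._engine.image_to_string(Image.fromarray(page.pixels))


# ---------------------------------------------------------------------------
# pixel operations


def crop_region(image: np.ndarray, rect: CropRect) -> np.ndarray:
    """Extract *rect* from *image*; out-of-bounds rectangles are an error."""
    h, w = image.shape[:2]
    if rect.left + rect.width > w or rect.top + rect.height > h:
        raise ValueError(
            f"crop rectangle {rect} exceeds image bounds {w}x{h}"
        )
    return image[rect.top:rect.top + rect.height, rect.left:rect.left + rect.width]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma conversion round(0.299 R + 0.587 G + 0.114 B); gray passes through."""
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        weights = np.array([0.299, 0.587, 0.114])
        return np.rint(image.astype(np.float64) @ weights).astype(np.uint8)
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {image.shape}")


def binarize(gray: np.ndarray, spec: BinarizationSpec = BinarizationSpec()) -> np.ndarray:
    """Threshold a single-plane image to exactly two values {0, 255}."""
    if gray.ndim != 2:
        raise ValueError(f"binarize expects a single-plane image, got shape {gray.shape}")
    above = gray > spec.threshold
    if spec.polarity == "trace_dark_on_white":
        return np.where(above, 255, 0).astype(np.uint8)
    return np.where(above, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# composed pipeline


@dataclass
class PreprocessConfig:
    """Crop/threshold configuration for one report dialect."""

    target_size: tuple[int, int] = defaults.PAGE_SIZE
    crop: CropRect = field(default_factory=lambda: CropRect(
        left=0,
        top=defaults.BANNER_HEIGHT,
        width=defaults.PAGE_SIZE[0],
        height=defaults.PAGE_SIZE[1] - defaults.BANNER_HEIGHT,
    ))
    binarization: BinarizationSpec = field(default_factory=BinarizationSpec)


def default_config() -> PreprocessConfig:
    """Configuration matching the synthetic renderer's banner/plot split."""
    return PreprocessConfig()


def load_config(path: str | Path) -> PreprocessConfig:
    """Read a :class:`PreprocessConfig` from a YAML file.

    Recognized keys: ``target_size`` ([width, height]), ``crop``
    ({left, top, width, height}), ``threshold`` and ``polarity``.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = default_config()
    if "target_size" in raw:
        cfg = replace(cfg, target_size=tuple(raw["target_size"]))
    if "crop" in raw:
        cfg = replace(cfg, crop=CropRect(**raw["crop"]))
    spec = cfg.binarization
    if "threshold" in raw:
        spec = replace(spec, threshold=int(raw["threshold"]))
    if "polarity" in raw:
        spec = replace(spec, polarity=raw["polarity"])
    return replace(cfg, binarization=spec)


def preprocess_report(
    source,
    text_extractor: TextExtractor,
    config: PreprocessConfig | None = None,
) -> list[StatePageImage]:
    """Full pipeline: render -> identify -> crop -> grayscale -> binarize.

    Returns three binary state pages in canonical order
    (pretest, exercise, recovery) regardless of the page order in *source*.
    """
    config = config or default_config()
    pages = render_report(source, target_size=config.target_size)
    mapping = identify_state_pages(pages, text_extractor)
    out: list[StatePageImage] = []
    for state in STATES:
        page = pages[mapping[state]]
        try:
            clean = binarize(
                to_grayscale(crop_region(page.pixels, config.crop)),
                config.binarization,
            )
        except ValueError as exc:
            raise ValueError(
                f"page {page.source_page_index} ({state}): {exc}"
            ) from exc
        out.append(StatePageImage(pixels=clean, state=state,
                                  source_page_index=page.source_page_index))
    return out
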