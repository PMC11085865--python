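"""Minimal multi-page PDF assembly and reading for report pages.

Reports are natively per-page PNG rasters; real-world exports wrap the same
rasters in a PDF container.  This module writes a deliberately simple PDF
dialect -- one Flate-compressed image XObject per page, drawn full-page --
and reads exactly that dialect back.  It is not a general PDF parser:
documents produced by other tools may use filters or layouts it does not
understand, and are rejected with an error.
"""

from __future__ import annotations

import re
import zlib
from pathlib import Path

import numpy as np

__all__ = ["write_pdf", "read_pdf"]


def _page_objects(index: int, img: np.ndarray, first_obj: int, pages_ref: int) -> list[bytes]:
    """Build the (page, xobject, content) objects for one page image."""
    if img.ndim == 2:
        colorspace = b"/DeviceGray"
    elif img.ndim == 3 and img.shape[2] == 3:
        colorspace = b"/DeviceRGB"
    else:
        raise ValueError(f"page {index}: expected (H, W) or (H, W, 3) uint8 array, got {img.shape}")
    h, w = img.shape[:2]
    raw = np.ascontiguousarray(img, dtype=np.uint8).tobytes()
    data = zlib.compress(raw)
    page_num, img_num, content_num = first_obj, first_obj + 1, first_obj + 2

    page = (
        b"<< /Type /Page /Parent %d 0 R /MediaBox [0 0 %d %d] "
        b"/Resources << /XObject << /Im%d %d 0 R >> >> /Contents %d 0 R >>"
        % (pages_ref, w, h, index, img_num, content_num)
    )
    xobj_dict = (
        b"<< /Type /XObject /Subtype /Image /Width %d /Height %d "
        b"/ColorSpace %s /BitsPerComponent 8 /Filter /FlateDecode /Length %d >>"
        % (w, h, colorspace, len(data))
    )
    xobj = xobj_dict + b"\nstream\n" + data + b"\nendstream"
    stream = b"q %d 0 0 %d 0 0 cm /Im%d Do Q" % (w, h, index)
    content = b"<< /Length %d >>\nstream\n%s\nendstream" % (len(stream), stream)
    return [page, xobj, content]


def write_pdf(images: list[np.ndarray], path: str | Path) -> None:
    """Assemble uint8 page rasters into a multi-page PDF at *path*."""
    if not images:
        raise ValueError("cannot write a PDF with zero pages")
    pages_ref = 2
    bodies: list[bytes] = [b"<< /Type /Catalog /Pages 2 0 R >>"]  # obj 1
    page_refs = []
    next_obj = 3
    page_bodies: list[bytes] = []
    for i, img in enumerate(images):
        page_refs.append(next_obj)
        page_bodies.extend(_page_objects(i, np.asarray(img), next_obj, pages_ref))
        next_obj += 3
    kids = b" ".join(b"%d 0 R" % r for r in page_refs)
    bodies.append(b"<< /Type /Pages /Kids [%s] /Count %d >>" % (kids, len(page_refs)))
    bodies.extend(page_bodies)

    out = bytearray(b"%PDF-1.4\n")
    offsets = []
    for num, body in enumerate(bodies, start=1):
        offsets.append(len(out))
        out += b"%d 0 obj\n" % num + body + b"\nendobj\n"
    xref_at = len(out)
    out += b"xref\n0 %d\n0000000000 65535 f \n" % (len(bodies) + 1)
    for off in offsets:
        out += b"%010d 00000 n \n" % off
    out += (
        b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
        % (len(bodies) + 1, xref_at)
    )
    Path(path).write_bytes(bytes(out))


_OBJ = re.compile(rb"(\d+) 0 obj\s*(.*?)\s*endobj", re.S)
_IMG_HEADER = re.compile(rb"\A(<<.*?/Subtype\s*/Image.*?>>)\s*stream\r?\n", re.S)
_FIELD = {
    "width": re.compile(rb"/Width\s+(\d+)"),
    "height": re.compile(rb"/Height\s+(\d+)"),
    "length": re.compile(rb"/Length\s+(\d+)"),
    "colorspace": re.compile(rb"/ColorSpace\s*/(\w+)"),
    "filter": re.compile(rb"/Filter\s*/(\w+)"),
}


def read_pdf(path: str | Path) -> list[np.ndarray]:
    """Read page rasters back from a PDF written by :func:`write_pdf`.

    Returns one uint8 array per page, in page order.  Raises ``ValueError``
    for PDFs using unsupported filters or color spaces, and ``OSError`` /
    ``ValueError`` for unreadable or page-less documents.
    """
    blob = Path(path).read_bytes()
    if not blob.startswith(b"%PDF"):
        raise ValueError(f"{path}: not a PDF document")
    pages: list[tuple[int, np.ndarray]] = []
    for obj in _OBJ.finditer(blob):
        obj_num = int(obj.group(1))
        match = _IMG_HEADER.match(obj.group(2))
        if match is None:
            continue
        header = match.group(1)
        fields = {}
        for key, rx in _FIELD.items():
            m = rx.search(header)
            if m is None:
                raise ValueError(f"{path}: image object {obj_num} lacks /{key.capitalize()}")
            fields[key] = m.group(1)
        if fields["filter"] != b"FlateDecode":
            raise ValueError(
                f"{path}: unsupported image filter {fields['filter'].decode()} "
                "(only FlateDecode PDFs from this module are supported)"
            )
        w, h = int(fields["width"]), int(fields["height"])
        start = obj.start(2) + match.end()
        data = zlib.decompress(blob[start:start + int(fields["length"])])
        if fields["colorspace"] == b"DeviceGray":
            arr = np.frombuffer(data, dtype=np.uint8).reshape(h, w)
        elif fields["colorspace"] == b"DeviceRGB":
            arr = np.frombuffer(data, dtype=np.uint8).reshape(h, w, 3)
        else:
            raise ValueError(f"{path}: unsupported color space {fields['colorspace'].decode()}")
        pages.append((obj_num, arr))
    if not pages:
        raise ValueError(f"{path}: document contains no pages")
    pages.sort(key=lambda item: item[0])
    return [arr for _, arr in pages]
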