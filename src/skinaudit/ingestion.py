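"""Document ingestion: extract embedded figures with provenance.

A document is either a PDF (embedded raster XObjects are pulled out with
their page number and placement rectangle) or a directory of PNG/JPEG
files treated as one page per file, in sorted filename order.  Tiny images
— anything under ``min_dim`` pixels in either dimension — are dropped, as
icons and decorations rather than figures.

Extraction results can be persisted to a JSON manifest plus sibling PNG
files and read back losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from ._pdfmini import PdfError, read_pdf_images

__all__ = ["IngestionError", "ImageRecord", "extract_images",
           "write_manifest", "read_manifest"]

DEFAULT_MIN_DIM = 100

_RASTER_SUFFIXES = {".png", ".jpg", ".jpeg"}


class IngestionError(RuntimeError):
    """A document could not be read or a manifest is malformed."""


@dataclass
class ImageRecord:
    """An extracted figure with document provenance.

    ``bbox`` is (x0, y0, x1, y1) in page points with a top-left origin;
    ``page`` is 1-based.  For directory input, page is the file's 1-based
    index and the bbox spans the full image in pixel units.
    """

    doc_id: str
    page: int
    bbox: tuple[float, float, float, float]
    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty H x W x 3 array")
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"invalid bbox {self.bbox}: need x0 < x1 and y0 < y1")
        if self.page < 1:
            raise ValueError("page numbers are 1-based")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def _load_raster(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as img:
            return np.asarray(img.convert("RGB"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise IngestionError(f"cannot read image file {path}: {exc}") from exc


def extract_images(document: str | Path, min_dim: int = DEFAULT_MIN_DIM) -> list[ImageRecord]:
    """Extract every embedded raster image with min(H, W) >= ``min_dim``.

    Returns records in (page, reading-order); vector graphics are ignored.
    An unreadable or encrypted document raises IngestionError naming the
    file; a document with zero images returns an empty list.
    """
    path = Path(document)
    if not path.exists():
        raise IngestionError(f"document not found: {path}")
    records: list[ImageRecord] = []
    doc_id = path.stem if path.is_file() else path.name
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _RASTER_SUFFIXES)
        page = 0
        for f in files:
            pixels = _load_raster(f)
            page += 1
            h, w = pixels.shape[:2]
            if min(h, w) < min_dim:
                continue
            records.append(ImageRecord(doc_id=doc_id, page=page,
                                       bbox=(0.0, 0.0, float(w), float(h)),
                                       pixels=pixels, source_path=str(f)))
        return records
    if path.suffix.lower() == ".pdf":
        try:
            placed = read_pdf_images(path)
        except PdfError as exc:
            raise IngestionError(f"cannot ingest {path}: {exc}") from exc
        for p in placed:
            h, w = p.pixels.shape[:2]
            if min(h, w) < min_dim:
                continue
            records.append(ImageRecord(doc_id=doc_id, page=p.page, bbox=p.bbox,
                                       pixels=p.pixels, source_path=str(path)))
        return records
    raise IngestionError(f"unsupported document type: {path} "
                         "(expected a .pdf or a directory of PNG/JPEG files)")


def write_manifest(records: list[ImageRecord], out_dir: str | Path,
                   doc_id: str | None = None) -> Path:
    """Write extracted images as PNGs plus a JSON manifest describing them.

    The manifest references each image by relative path and records its
    SHA-256 so a reader can verify integrity.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    if doc_id is None:
        doc_id = records[0].doc_id if records else "empty"
    for i, rec in enumerate(records):
        name = f"img_{i:04d}.png"
        Image.fromarray(rec.pixels).save(out / name)
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        entries.append({
            "page": rec.page,
            "bbox": list(rec.bbox),
            "image_path": name,
            "sha256": digest,
        })
    manifest = {"doc_id": doc_id, "entries": entries}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_manifest(manifest_path: str | Path) -> list[ImageRecord]:
    """Read a manifest back into ImageRecords (pixels loaded from PNGs)."""
    mpath = Path(manifest_path)
    try:
        data = json.loads(mpath.read_text())
    except json.JSONDecodeError as exc:
        raise IngestionError(
            f"malformed manifest {mpath}: line {exc.lineno}, col {exc.colno}: {exc.msg}"
        ) from exc
    except OSError as exc:
        raise IngestionError(f"cannot read manifest {mpath}: {exc}") from exc
    if not isinstance(data, dict) or "entries" not in data or "doc_id" not in data:
        raise IngestionError(f"malformed manifest {mpath}: missing doc_id/entries")
    records = []
    for entry in data["entries"]:
        img_path = mpath.parent / entry["image_path"]
        if not img_path.exists():
            raise IngestionError(f"manifest references missing image file: {img_path}")
        pixels = _load_raster(img_path)
        records.append(ImageRecord(doc_id=data["doc_id"], page=int(entry["page"]),
                                   bbox=tuple(float(v) for v in entry["bbox"]),
                                   pixels=pixels, source_path=str(img_path)))
    return records
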