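"""Minimal PDF reader/writer for embedded raster images.

This module deliberately implements only the slice of PDF needed by the
document auditor: writing pages that place 8-bit RGB images, and reading
back embedded image XObjects together with the page number and placement
rectangle of each ``Do`` operation.  Supported image encodings are
FlateDecode (DeviceRGB / DeviceGray, 8 bits per component) and DCTDecode
(baseline JPEG, handed to Pillow).  Vector graphics, text, encryption,
object streams and exotic color spaces are out of scope; encrypted files
raise, unknown XObjects are skipped.

Coordinates returned to callers use a top-left origin in PDF points
(native PDF is bottom-left; the flip uses the page's MediaBox height).
"""

from __future__ import annotations

import io
import re
import zlib
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = ["PdfError", "PlacedImage", "read_pdf_images", "PdfImageWriter"]


class PdfError(ValueError):
    """Raised for unreadable, encrypted or structurally unsupported PDFs."""


@dataclass
class PlacedImage:
    """An embedded raster image and where it appears on its page."""

    page: int                     # 1-based
    bbox: tuple[float, float, float, float]  # x0, y0, x1, y1; top-left origin, points
    pixels: np.ndarray            # H x W x 3 uint8 sRGB


# ---------------------------------------------------------------------------
# tokenizer / object parser


_WS = b"\x00\t\n\x0c\r "
_DELIM = b"()<>[]{}/%"


class _Lexer:
    def __init__(self, data: bytes, pos: int = 0):
        self.data = data
        self.pos = pos

    def _skip_ws(self) -> None:
        d, n = self.data, len(self.data)
        while self.pos < n:
            c = d[self.pos]
            if c == 0x25:  # % comment to end of line
                eol = d.find(b"\n", self.pos)
                self.pos = n if eol < 0 else eol + 1
            elif c in _WS:
                self.pos += 1
            else:
                break

    def parse(self):
        self._skip_ws()
        d = self.data
        c = d[self.pos:self.pos + 1]
        if c == b"<" and d[self.pos:self.pos + 2] == b"<<":
            return self._parse_dict()
        if c == b"[":
            return self._parse_array()
        if c == b"/":
            return self._parse_name()
        if c == b"(":
            return self._parse_string()
        if c == b"<":
            return self._parse_hex_string()
        return self._parse_misc()

    def _parse_dict(self):
        self.pos += 2
        out = {}
        while True:
            self._skip_ws()
            if self.data[self.pos:self.pos + 2] == b">>":
                self.pos += 2
                return out
            key = self._parse_name()
            out[key] = self.parse()

    def _parse_array(self):
        self.pos += 1
        out = []
        while True:
            self._skip_ws()
            if self.data[self.pos:self.pos + 1] == b"]":
                self.pos += 1
                return out
            out.append(self.parse())

    def _parse_name(self) -> str:
        assert self.data[self.pos:self.pos + 1] == b"/"
        self.pos += 1
        start = self.pos
        while self.pos < len(self.data):
            c = self.data[self.pos:self.pos + 1]
            if c in (b"\t", b"\n", b"\r", b"\x0c", b"\x00", b" ") or c in [bytes([b]) for b in _DELIM]:
                break
            self.pos += 1
        return self.data[start:self.pos].decode("latin-1")

    def _parse_string(self) -> bytes:
        self.pos += 1
        depth, out = 1, bytearray()
        while self.pos < len(self.data) and depth:
            c = self.data[self.pos]
            if c == 0x5C:  # backslash
                self.pos += 1
                out.append(self.data[self.pos])
            elif c == 0x28:
                depth += 1
                out.append(c)
            elif c == 0x29:
                depth -= 1
                if depth:
                    out.append(c)
            else:
                out.append(c)
            self.pos += 1
        return bytes(out)

    def _parse_hex_string(self) -> bytes:
        end = self.data.find(b">", self.pos)
        hx = re.sub(rb"\s", b"", self.data[self.pos + 1:end])
        self.pos = end + 1
        if len(hx) % 2:
            hx += b"0"
        return bytes.fromhex(hx.decode("ascii"))

    def _parse_misc(self):
        start = self.pos
        while self.pos < len(self.data):
            c = self.data[self.pos:self.pos + 1]
            if c in (b"\t", b"\n", b"\r", b"\x0c", b"\x00", b" ") or c in [bytes([b]) for b in _DELIM]:
                break
            self.pos += 1
        tok = self.data[start:self.pos]
        if tok in (b"true", b"false"):
            return tok == b"true"
        if tok == b"null":
            return None
        # indirect reference lookahead: "N G R"
        m = re.match(rb"^[+-]?\d+$", tok)
        if m:
            save = self.pos
            try:
                self._skip_ws()
                m2 = re.match(rb"\d+", self.data[self.pos:self.pos + 16])
                if m2:
                    p2 = self.pos + m2.end()
                    lx = _Lexer(self.data, p2)
                    lx._skip_ws()
                    if lx.data[lx.pos:lx.pos + 1] == b"R":
                        self.pos = lx.pos + 1
                        return _Ref(int(tok))
            except Exception:
                pass
            self.pos = save
            return int(tok)
        try:
            return float(tok)
        except ValueError:
            return tok.decode("latin-1")


@dataclass(frozen=True)
class _Ref:
    num: int


# ---------------------------------------------------------------------------
# reading


_OBJ_RE = re.compile(rb"(\d+)\s+(\d+)\s+obj\b", re.S)


def _scan_objects(data: bytes) -> dict[int, tuple[dict, bytes | None]]:
    """Map object number -> (dictionary, raw stream bytes or None).

    Objects are located by scanning for ``N G obj`` headers rather than by
    xref parsing, which tolerates files with broken or incremental xrefs.
    """
    objects: dict[int, tuple[dict, bytes | None]] = {}
    raw: dict[int, tuple[dict | object, int]] = {}
    for m in _OBJ_RE.finditer(data):
        num = int(m.group(1))
        lx = _Lexer(data, m.end())
        try:
            obj = lx.parse()
        except Exception:
            continue
        raw[num] = (obj, lx.pos)
    for num, (obj, pos) in raw.items():
        stream = None
        if isinstance(obj, dict):
            lx = _Lexer(data, pos)
            lx._skip_ws()
            if data[lx.pos:lx.pos + 6] == b"stream":
                p = lx.pos + 6
                if data[p:p + 2] == b"\r\n":
                    p += 2
                elif data[p:p + 1] == b"\n":
                    p += 1
                length = obj.get("Length")
                if isinstance(length, _Ref):
                    ref_obj = raw.get(length.num)
                    length = ref_obj[0] if ref_obj else None
                if isinstance(length, (int, float)):
                    stream = data[p:p + int(length)]
                else:
                    end = data.find(b"endstream", p)
                    stream = data[p:end].rstrip(b"\r\n")
        objects[num] = (obj if isinstance(obj, dict) else {"__value__": obj}, stream)
    return objects


class _Doc:
    def __init__(self, data: bytes):
        if not data.startswith(b"%PDF"):
            raise PdfError("not a PDF file (missing %PDF header)")
        self.objects = _scan_objects(data)
        self.data = data
        tail = data[data.rfind(b"trailer"):] if b"trailer" in data else b""
        if b"/Encrypt" in tail or any("Encrypt" in obj for obj, _ in self.objects.values()):
            raise PdfError("encrypted PDF is not supported")

    def resolve(self, value):
        while isinstance(value, _Ref):
            entry = self.objects.get(value.num)
            if entry is None:
                return None
            obj, stream = entry
            value = obj.get("__value__", obj)
            if value is obj and stream is not None:
                return obj
        return value

    def stream_of(self, ref) -> bytes | None:
        if isinstance(ref, _Ref):
            entry = self.objects.get(ref.num)
            return entry[1] if entry else None
        return None

    def pages(self) -> list[tuple[dict, _Ref | None]]:
        root_ref = None
        for obj, _ in self.objects.values():
            if obj.get("Type") == "Catalog":
                root_ref = obj.get("Pages")
                break
        out: list[dict] = []
        if root_ref is not None:
            self._walk_pages(self.resolve(root_ref), out, set())
        if not out:  # fall back: any object typed /Page
            for num in sorted(self.objects):
                obj, _ = self.objects[num]
                if obj.get("Type") == "Page":
                    out.append(obj)
        return [(p, None) for p in out]

    def _walk_pages(self, node, out: list, seen: set) -> None:
        if not isinstance(node, dict) or id(node) in seen:
            return
        seen.add(id(node))
        if node.get("Type") == "Page":
            out.append(node)
            return
        for kid in node.get("Kids", []) or []:
            self._walk_pages(self.resolve(kid), out, seen)


def _decode_image(doc: _Doc, xdict: dict, stream: bytes) -> np.ndarray | None:
    if xdict.get("Subtype") != "Image" or stream is None:
        return None
    filters = xdict.get("Filter")
    if isinstance(filters, str):
        filters = [filters]
    elif filters is None:
        filters = []
    filters = [doc.resolve(f) if isinstance(f, _Ref) else f for f in filters]
    w = int(doc.resolve(xdict.get("Width", 0)) or 0)
    h = int(doc.resolve(xdict.get("Height", 0)) or 0)
    if w <= 0 or h <= 0:
        return None
    if "DCTDecode" in filters:
        try:
            img = Image.open(io.BytesIO(stream)).convert("RGB")
        except Exception:
            return None
        return np.asarray(img, dtype=np.uint8)
    payload = stream
    if "FlateDecode" in filters:
        try:
            payload = zlib.decompress(stream)
        except zlib.error:
            return None
    if xdict.get("DecodeParms") is not None:
        return None  # predictors not supported
    bpc = int(doc.resolve(xdict.get("BitsPerComponent", 8)) or 8)
    if bpc != 8:
        return None
    cs = doc.resolve(xdict.get("ColorSpace"))
    if isinstance(cs, list) and cs:
        cs = cs[0]
    ncomp = {"DeviceRGB": 3, "DeviceGray": 1, "DeviceCMYK": 4}.get(cs)
    if ncomp is None:
        return None
    if len(payload) < w * h * ncomp:
        return None
    arr = np.frombuffer(payload[: w * h * ncomp], dtype=np.uint8).reshape(h, w, ncomp)
    if ncomp == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif ncomp == 4:  # naive CMYK -> RGB
        c, m, y, k = [arr[..., i].astype(np.float64) / 255.0 for i in range(4)]
        rgb = np.stack([(1 - c) * (1 - k), (1 - m) * (1 - k), (1 - y) * (1 - k)], axis=-1)
        arr = (rgb * 255).round().astype(np.uint8)
    return np.ascontiguousarray(arr)


_NUM = rb"[+-]?(?:\d+\.?\d*|\.\d+)"
_CS_OP = re.compile(
    rb"(?:(" + _NUM + rb")\s+(" + _NUM + rb")\s+(" + _NUM + rb")\s+(" + _NUM
    + rb")\s+(" + _NUM + rb")\s+(" + _NUM + rb")\s+cm)|(/[^\s/\[\]()<>{}%]+)\s+Do|(q)\b|(Q)\b"
)


def _matmul3(a, b):
    # 2x3 affine [a b c d e f] composition: result = a then b
    a0, a1, a2, a3, a4, a5 = a
    b0, b1, b2, b3, b4, b5 = b
    return (
        a0 * b0 + a1 * b2,
        a0 * b1 + a1 * b3,
        a2 * b0 + a3 * b2,
        a2 * b1 + a3 * b3,
        a4 * b0 + a5 * b2 + b4,
        a4 * b1 + a5 * b3 + b5,
    )


def _placements(content: bytes) -> list[tuple[str, tuple[float, float, float, float]]]:
    """(xobject name, bbox in PDF user space bottom-left origin) per Do."""
    ctm = (1.0, 0.0, 0.0, 1.0, 0.0, 0.0)
    stack: list[tuple] = []
    out = []
    for m in _CS_OP.finditer(content):
        if m.group(1) is not None:
            vals = tuple(float(m.group(i)) for i in range(1, 7))
            ctm = _matmul3(vals, ctm)
        elif m.group(7) is not None:
            name = m.group(7).decode("latin-1")[1:]
            a, b, c, d, e, f = ctm
            xs = [e, a + e, c + e, a + c + e]
            ys = [f, b + f, d + f, b + d + f]
            out.append((name, (min(xs), min(ys), max(xs), max(ys))))
        elif m.group(8) is not None:
            stack.append(ctm)
        elif m.group(9) is not None:
            if stack:
                ctm = stack.pop()
    return out


def read_pdf_images(path) -> list[PlacedImage]:
    """Extract every supported embedded raster image with page + bbox.

    Bboxes are in page points with a top-left origin.  Images placed more
    than once yield one record per placement.  Returns records in
    (page, content-stream order).
    """
    try:
        with open(path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise PdfError(f"cannot read {path}: {exc}") from exc
    doc = _Doc(data)
    records: list[PlacedImage] = []
    for pageno, (page, _) in enumerate(doc.pages(), start=1):
        media = doc.resolve(page.get("MediaBox")) or [0, 0, 612, 792]
        media = [float(doc.resolve(v)) for v in media]
        page_h = media[3] - media[1]
        resources = doc.resolve(page.get("Resources")) or {}
        xobjects = doc.resolve(resources.get("XObject")) or {}
        contents = page.get("Contents")
        chunks = []
        for c in contents if isinstance(contents, list) else [contents]:
            s = doc.stream_of(c)
            if s is None:
                continue
            cdict = doc.objects[c.num][0] if isinstance(c, _Ref) else {}
            if cdict.get("Filter") == "FlateDecode":
                try:
                    s = zlib.decompress(s)
                except zlib.error:
                    continue
            chunks.append(s)
        content = b"\n".join(chunks)
        decoded: dict[str, np.ndarray | None] = {}
        for name, bbox in _placements(content):
            ref = xobjects.get(name)
            if not isinstance(ref, _Ref):
                continue
            if name not in decoded:
                xdict, xstream = doc.objects.get(ref.num, ({}, None))
                decoded[name] = _decode_image(doc, xdict, xstream) if xstream else None
            pix = decoded[name]
            if pix is None:
                continue
            x0, y0, x1, y1 = bbox
            top_bbox = (x0 - media[0], page_h - (y1 - media[1]),
                        x1 - media[0], page_h - (y0 - media[1]))
            records.append(PlacedImage(page=pageno, bbox=top_bbox, pixels=pix))
    return records


# ---------------------------------------------------------------------------
# writing


class PdfImageWriter:
    """Write a PDF whose pages place 8-bit RGB images at given rectangles.

    Images are stored as FlateDecode DeviceRGB XObjects; pages default to US
    Letter (612 x 792 points).  Rectangles use a top-left origin in points.
    """

    def __init__(self, page_size: tuple[float, float] = (612.0, 792.0)):
        self.page_size = page_size
        self.pages: list[list[tuple[np.ndarray, tuple[float, float, float, float]]]] = []

    def add_page(self) -> int:
        self.pages.append([])
        return len(self.pages)

    def place_image(self, page: int, pixels: np.ndarray,
                    bbox: tuple[float, float, float, float]) -> None:
        """Place pixels on 1-based ``page`` at top-left-origin ``bbox``."""
        a = np.asarray(pixels, dtype=np.uint8)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3 uint8")
        x0, y0, x1, y1 = bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError("bbox must satisfy x0 < x1 and y0 < y1")
        while len(self.pages) < page:
            self.add_page()
        self.pages[page - 1].append((a, tuple(float(v) for v in bbox)))

    def save(self, path) -> None:
        w, h = self.page_size
        objects: list[bytes] = []  # bodies; object number = index + 1

        def add(body: bytes) -> int:
            objects.append(body)
            return len(objects)

        page_obj_nums = []
        pages_obj_num_placeholder = None
        image_entries = []
        for placements in self.pages:
            xobj_refs = []
            content_parts = []
            for pix, (x0, y0, x1, y1) in placements:
                ih, iw = pix.shape[:2]
                data = zlib.compress(pix.tobytes())
                img_num = add(
                    b"<< /Type /XObject /Subtype /Image /Width %d /Height %d"
                    b" /ColorSpace /DeviceRGB /BitsPerComponent 8 /Filter /FlateDecode"
                    b" /Length %d >>\nstream\n" % (iw, ih, len(data))
                    + data + b"\nendstream"
                )
                name = f"Im{img_num}"
                xobj_refs.append((name, img_num))
                # top-left bbox -> bottom-left placement matrix
                sw, sh = x1 - x0, y1 - y0
                ty = h - y1
                content_parts.append(
                    f"q {sw:.4f} 0 0 {sh:.4f} {x0:.4f} {ty:.4f} cm /{name} Do Q".encode()
                )
            content = b"\n".join(content_parts) + b"\n"
            content_num = add(b"<< /Length %d >>\nstream\n" % len(content)
                              + content + b"\nendstream")
            xdict = b" ".join(b"/%s %d 0 R" % (n.encode(), num) for n, num in xobj_refs)
            image_entries.append((content_num, xdict))
            page_obj_nums.append(None)  # filled below

        pages_num = len(objects) + len(self.pages) + 1  # after page objects
        for i, (content_num, xdict) in enumerate(image_entries):
            body = (
                b"<< /Type /Page /Parent %d 0 R /MediaBox [0 0 %.2f %.2f]"
                b" /Resources << /XObject << %s >> >> /Contents %d 0 R >>"
                % (pages_num, w, h, xdict, content_num)
            )
            page_obj_nums[i] = add(body)
        kids = b" ".join(b"%d 0 R" % n for n in page_obj_nums)
        pages_actual = add(b"<< /Type /Pages /Kids [%s] /Count %d >>"
                           % (kids, len(page_obj_nums)))
        assert pages_actual == pages_num
        catalog = add(b"<< /Type /Catalog /Pages %d 0 R >>" % pages_num)

        out = bytearray(b"%PDF-1.4\n%\xe2\xe3\xcf\xd3\n")
        offsets = [0]
        for i, body in enumerate(objects, start=1):
            offsets.append(len(out))
            out += b"%d 0 obj\n" % i + body + b"\nendobj\n"
        xref_pos = len(out)
        out += b"xref\n0 %d\n" % (len(objects) + 1)
        out += b"0000000000 65535 f \n"
        for off in offsets[1:]:
            out += b"%010d 00000 n \n" % off
        out += (b"trailer\n<< /Size %d /Root %d 0 R >>\nstartxref\n%d\n%%%%EOF\n"
                % (len(objects) + 1, catalog, xref_pos))
        with open(path, "wb") as fh:
            fh.write(bytes(out))
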