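"""Synthetic fixtures: skin photographs with known tone and masks,
non-skin figures, labeled datasets, and multi-image PDF documents.

The generator emulates the structure of dermatology educational figures
at a cartoon level: a skin-colored ellipse (the subject) with per-pixel
CIELAB jitter, an optional clothing rectangle and an optional darker
lesion blob, on a non-skin background.  Skin colors are sampled in CIELAB
within ranges chosen per tone class and rejection-resampled so that the
light class always has ITA > 10 degrees and the dark class ITA <= -30
degrees — the two classes are therefore ITA-separable by construction
(gap >= 40 degrees), which makes tone-recovery tests well-posed.

Non-skin figures come in three kinds mirroring what document extraction
actually encounters: line charts, text blocks, and histology-like pink
textures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.color import lab2rgb

from ._pdfmini import PdfImageWriter
from .features import ita_from_lab

__all__ = ["SyntheticSpec", "SyntheticDataset", "sample_skin_color",
           "gen_skin_image", "gen_nonskin_image", "gen_dataset", "gen_document"]

NONSKIN_KINDS = ("chart", "textblock", "histology")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for fixture generation.

    ``tone_mix`` is the proportion of dark (FST V-VI) images among the
    skin images; ``skin_frac`` the proportion of skin images overall.
    CIELAB sampling ranges per class keep light colors above ITA 10 and
    dark colors below ITA -30 (enforced by rejection).
    """

    seed: int = 0
    n_images: int = 100
    tone_mix: float = 0.3
    skin_frac: float = 0.6
    size: int = 128  # above the pipeline's default 100-px minimum dimension
    # per-class CIELAB sampling ranges: (L_lo, L_hi), (a_lo, a_hi), (b_lo, b_hi)
    light_L: tuple[float, float] = (60.0, 78.0)
    light_a: tuple[float, float] = (6.0, 16.0)
    light_b: tuple[float, float] = (12.0, 22.0)
    dark_L: tuple[float, float] = (28.0, 45.0)
    dark_a: tuple[float, float] = (4.0, 14.0)
    dark_b: tuple[float, float] = (4.0, 14.0)
    noise_sd: float = 2.0
    # layout: ellipse semi-axes as fractions of the image side
    ax_range: tuple[float, float] = (0.26, 0.40)
    ay_range: tuple[float, float] = (0.24, 0.36)
    clothing_prob: float = 0.3
    lesion_prob: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.tone_mix <= 1.0:
            raise ValueError("tone_mix must be in [0, 1]")
        if not 0.0 <= self.skin_frac <= 1.0:
            raise ValueError("skin_frac must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """Labeled fixture collection; masks/tone labels are None for non-skin."""

    images: list[np.ndarray]
    detection_labels: list[str]          # "skin" / "nonskin"
    masks: list[np.ndarray | None]
    tone_labels: list[str | None]        # "I-IV" / "V-VI" / None
    spec: SyntheticSpec


_BACKGROUNDS = (
    (246, 246, 246),   # near white
    (205, 205, 210),   # light gray
    (178, 198, 228),   # pale blue
    (198, 222, 200),   # pale green
)
_CLOTHING = ((60, 90, 160), (70, 140, 90), (120, 70, 150))


def _lab_to_rgb8(lab: np.ndarray) -> np.ndarray:
    rgb = lab2rgb(lab)
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


def sample_skin_color(tone_class: str, rng: np.random.Generator,
                      spec: SyntheticSpec | None = None) -> np.ndarray:
    """Draw a CIELAB skin color for "light" or "dark", rejection-resampled
    until its ITA satisfies the class invariant (>10 deg / <=-30 deg)."""
    spec = spec or SyntheticSpec()
    if tone_class == "light":
        ranges = (spec.light_L, spec.light_a, spec.light_b)
        ok = lambda ita: ita > 10.0
    elif tone_class == "dark":
        ranges = (spec.dark_L, spec.dark_a, spec.dark_b)
        ok = lambda ita: ita <= -30.0
    else:
        raise ValueError(f"tone_class must be 'light' or 'dark', got {tone_class!r}")
    for _ in range(1000):
        lab = np.array([rng.uniform(*r) for r in ranges])
        if ok(float(ita_from_lab(lab[0], lab[2]))):
            return lab
    raise RuntimeError("rejection sampling failed; check sampling ranges")


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def gen_skin_image(spec: SyntheticSpec, tone_class: str, seed: int
                   ) -> tuple[np.ndarray, np.ndarray, str]:
    """One synthetic skin photograph.

    Returns (image, true mask, tone label).  The truth mask is the skin
    ellipse including any lesion blob (segmentation is not expected to
    exclude lesions) and excluding any clothing that covers it.
    """
    rng = np.random.default_rng(seed)
    s = spec.size
    base_lab = sample_skin_color(tone_class, rng, spec)

    bg = np.asarray(_BACKGROUNDS[rng.integers(len(_BACKGROUNDS))], dtype=np.float64)
    img = np.broadcast_to(bg, (s, s, 3)).copy()

    cy = rng.uniform(0.40, 0.55) * s
    cx = rng.uniform(0.42, 0.58) * s
    ry = rng.uniform(*spec.ay_range) * s
    rx = rng.uniform(*spec.ax_range) * s
    ellipse = _ellipse_mask(s, cy, cx, ry, rx)

    skin_lab = np.broadcast_to(base_lab, (s, s, 3)).copy()
    skin_lab += rng.normal(0.0, spec.noise_sd, size=(s, s, 3))

    if rng.uniform() < spec.lesion_prob:
        lr = rng.uniform(0.06, 0.12) * s
        lcy = cy + rng.uniform(-0.3, 0.3) * ry
        lcx = cx + rng.uniform(-0.3, 0.3) * rx
        lesion = _ellipse_mask(s, lcy, lcx, lr, lr) & ellipse
        skin_lab[lesion] += np.array([-10.0, 6.0, -2.0])

    skin_rgb = _lab_to_rgb8(skin_lab).astype(np.float64)
    img[ellipse] = skin_rgb[ellipse]

    mask = ellipse.copy()
    if rng.uniform() < spec.clothing_prob:
        strip = int(rng.uniform(0.10, 0.18) * s)
        cloth = np.zeros((s, s), dtype=bool)
        cloth[s - strip:, :] = True
        img[cloth] = np.asarray(_CLOTHING[rng.integers(len(_CLOTHING))], dtype=np.float64)
        mask &= ~cloth

    label = "V-VI" if tone_class == "dark" else "I-IV"
    return img.round().astype(np.uint8), mask, label


def gen_nonskin_image(kind: str, seed: int, size: int = 96) -> np.ndarray:
    """A synthetic non-skin figure: chart, textblock or histology texture."""
    rng = np.random.default_rng(seed)
    s = size
    if kind == "chart":
        img = np.full((s, s, 3), 255, dtype=np.uint8)
        img[s - 8, 6:s - 4] = (40, 40, 40)        # x axis
        img[4:s - 7, 6] = (40, 40, 40)            # y axis
        palette = ((40, 90, 200), (30, 150, 70), (200, 40, 60), (140, 60, 190))
        for line in range(rng.integers(2, 4)):
            color = palette[line % len(palette)]
            y = rng.uniform(10, s - 14)
            for x in range(8, s - 5):
                y += rng.normal(0, 2.0)
                y = float(np.clip(y, 6, s - 10))
                img[int(y):int(y) + 2, x] = color
        return img
    if kind == "textblock":
        img = np.full((s, s, 3), 252, dtype=np.uint8)
        row = 6
        while row < s - 8:
            col = 5
            while col < s - 6:
                wlen = int(rng.integers(3, 10))
                shade = int(rng.integers(30, 90))
                img[row:row + 4, col:col + wlen] = shade
                col += wlen + int(rng.integers(2, 5))
            row += 8
        return img
    if kind == "histology":
        field_noise = rng.normal(0, 1, (s, s))
        from scipy.ndimage import gaussian_filter
        blobs = gaussian_filter(field_noise, sigma=4) > 0
        img = np.empty((s, s, 3), dtype=np.uint8)
        img[~blobs] = (245, 215, 232)   # eosin-pale pink
        img[blobs] = (198, 96, 160)     # hematoxylin-magenta
        jitter = rng.integers(-8, 9, size=(s, s, 3))
        return np.clip(img.astype(int) + jitter, 0, 255).astype(np.uint8)
    raise ValueError(f"unknown non-skin kind {kind!r}; choose from {NONSKIN_KINDS}")


def gen_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """A labeled mixture of skin and non-skin images per the spec's mixes.

    Class counts are deterministic rounding of the requested proportions
    (within one image of the exact mix); ordering is a seeded shuffle.
    """
    if spec.n_images < 2:
        raise ValueError("n_images must be >= 2")
    rng = np.random.default_rng(spec.seed)
    n_skin = int(round(spec.skin_frac * spec.n_images))
    n_dark = int(round(spec.tone_mix * n_skin))
    n_light = n_skin - n_dark
    n_nonskin = spec.n_images - n_skin

    entries = []
    for i in range(n_dark):
        entries.append(("skin", "dark"))
    for i in range(n_light):
        entries.append(("skin", "light"))
    for i in range(n_nonskin):
        entries.append(("nonskin", NONSKIN_KINDS[i % len(NONSKIN_KINDS)]))
    order = rng.permutation(len(entries))
    seeds = rng.integers(0, 2**31 - 1, size=len(entries))

    images, det, masks, tones = [], [], [], []
    for j, k in enumerate(order):
        cls, sub = entries[k]
        if cls == "skin":
            img, mask, tone = gen_skin_image(spec, sub, int(seeds[j]))
            images.append(img); det.append("skin"); masks.append(mask); tones.append(tone)
        else:
            images.append(gen_nonskin_image(sub, int(seeds[j]), spec.size))
            det.append("nonskin"); masks.append(None); tones.append(None)
    return SyntheticDataset(images, det, masks, tones, spec)


def gen_document(spec: SyntheticSpec, path: str | Path,
                 images_per_page: int = 4, tiny_count: int = 0
                 ) -> tuple[Path, Path]:
    """Write a PDF embedding a generated dataset, plus a truth manifest.

    Images are placed in a 2 x 2 grid per page at recorded bounding boxes;
    ``tiny_count`` extra 60 x 60-pixel images can be appended to exercise
    the minimum-dimension filter.  Returns (pdf_path, manifest_path); the
    manifest lists page, bbox (top-left origin, points) and truth labels
    in placement order.
    """
    path = Path(path)
    ds = gen_dataset(spec)
    images = list(ds.images)
    det = list(ds.detection_labels)
    tones = list(ds.tone_labels)
    tiny_spec = replace(spec, size=60)
    rng = np.random.default_rng(spec.seed + 1)
    for t in range(tiny_count):
        img, _, tone = gen_skin_image(tiny_spec, "light", int(rng.integers(2**31 - 1)))
        images.append(img); det.append("skin"); tones.append(tone)

    page_w, page_h = 612.0, 792.0
    cell_w, cell_h = (page_w - 3 * 36.0) / 2, (page_h - 3 * 36.0) / 2
    writer = PdfImageWriter((page_w, page_h))
    entries = []
    for i, img in enumerate(images):
        page = i // images_per_page + 1
        slot = i % images_per_page
        r, c = divmod(slot, 2)
        # display size proportional to pixel size so tiny stays tiny on page
        disp = min(cell_w, cell_h) * min(1.0, img.shape[1] / spec.size)
        x0 = 36.0 + c * (cell_w + 36.0)
        y0 = 36.0 + r * (cell_h + 36.0)
        bbox = (x0, y0, x0 + disp, y0 + disp)
        writer.place_image(page, img, bbox)
        entries.append({
            "page": page,
            "bbox": list(bbox),
            "detection_label": det[i],
            "tone_label": tones[i],
            "height_px": int(img.shape[0]),
            "width_px": int(img.shape[1]),
        })
    writer.save(path)
    manifest = {"doc_id": path.stem, "seed": spec.seed, "entries": entries}
    mpath = path.with_suffix(".truth.json")
    mpath.write_text(json.dumps(manifest, indent=2))
    return path, mpath
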