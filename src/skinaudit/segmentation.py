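"""Rule-based skin-pixel segmentation and its evaluation.

A pixel is a skin *candidate* when it falls inside published skin loci in
both HSV and YCbCr simultaneously.  The candidate mask is then refined by
morphological opening/closing, small-component removal, color-tolerance
region growing in CIELAB, and a gradient watershed that splits touching
regions.  Lesional skin is deliberately NOT excluded: the audit counts a
diseased-skin photograph as skin.

Evaluation follows the pixel-fraction convention: TP/TN/FP/FN are reported
as fractions of *all* pixels (so they sum to 1 and accuracy = tp + tn),
with skin the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv, rgb2ycbcr, rgb2lab
from skimage.morphology import opening, closing, disk, remove_small_objects
from skimage.segmentation import watershed
from skimage.measure import label as cc_label
from skimage.filters import sobel

from .features import _as_patch, to_lab

__all__ = [
    "SkinRanges",
    "RefineParams",
    "SegmentationMetrics",
    "pixel_rule_mask",
    "refine_mask",
    "segment_skin",
    "evaluate_segmentation",
    "evaluate_batch",
]


@dataclass(frozen=True)
class SkinRanges:
    """HSV and YCbCr skin loci; a pixel must satisfy both rules.

    Hue in degrees [0, 360); S and V in [0, 1]; Cb/Cr on the 8-bit BT.601
    scale.  Defaults are widely used published skin intervals.
    """

    h: tuple[float, float] = (0.0, 50.0)
    s: tuple[float, float] = (0.15, 0.70)
    v_min: float = 0.25
    cb: tuple[float, float] = (77.0, 127.0)
    cr: tuple[float, float] = (133.0, 173.0)

    def validate(self) -> None:
        for name in ("h", "s", "cb", "cr"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range {name!r} has lo > hi: {(lo, hi)}")


@dataclass(frozen=True)
class RefineParams:
    """Mask refinement knobs.

    min_area_frac is a fraction of the image's pixel count; grow_tol is a
    CIELAB Euclidean distance (approximately a just-noticeable-difference
    scale, ~2.3 per JND).
    """

    r_open: int = 3
    r_close: int = 3
    min_area_frac: float = 0.005
    grow_tol: float = 12.0
    grow_max_iter: int = 25


@dataclass(frozen=True)
class SegmentationMetrics:
    """Pixel-fraction confusion entries plus Jaccard and accuracy."""

    tp_frac: float
    tn_frac: float
    fp_frac: float
    fn_frac: float
    jaccard: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def pixel_rule_mask(patch: np.ndarray, ranges: SkinRanges | None = None) -> np.ndarray:
    """Boolean candidate-skin mask from joint HSV and YCbCr interval rules."""
    a = _as_patch(patch)
    ranges = ranges or SkinRanges()
    ranges.validate()
    rgb = a.astype(np.float64) / 255.0
    hsv = rgb2hsv(rgb)
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]
    ycc = rgb2ycbcr(rgb)
    cb = ycc[..., 1]
    cr = ycc[..., 2]
    return (
        (h >= ranges.h[0]) & (h <= ranges.h[1])
        & (s >= ranges.s[0]) & (s <= ranges.s[1])
        & (v >= ranges.v_min)
        & (cb >= ranges.cb[0]) & (cb <= ranges.cb[1])
        & (cr >= ranges.cr[0]) & (cr <= ranges.cr[1])
    )


def _min_area(shape: tuple[int, ...], params: RefineParams) -> int:
    return max(1, int(round(params.min_area_frac * shape[0] * shape[1])))


def _region_grow(lab: np.ndarray, mask: np.ndarray, params: RefineParams) -> np.ndarray:
    """Admit neighbors whose CIELAB color is within grow_tol of the seed
    component's mean color.  Component means are fixed at the start so the
    grown region cannot drift."""
    labels = cc_label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return mask
    means = np.array([lab[labels == i].mean(axis=0) for i in range(1, n + 1)])
    grown = mask.copy()
    owner = labels.copy()
    struct = np.ones((3, 3), bool)
    for _ in range(params.grow_max_iter):
        # propagate component ids one step outward
        dil = ndi.grey_dilation(owner, footprint=struct)
        frontier = (~grown) & (dil > 0)
        if not frontier.any():
            break
        cand_ids = dil[frontier]
        de = np.linalg.norm(lab[frontier] - means[cand_ids - 1], axis=1)
        ok = de <= params.grow_tol
        if not ok.any():
            break
        idx = np.flatnonzero(frontier.ravel())[ok]
        grown.ravel()[idx] = True
        owner.ravel()[idx] = cand_ids[ok]
    return grown


def _watershed_split(patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Split merged skin regions along gradient ridges.

    Markers are the eroded cores of each component; watershed lines (1 px)
    are removed from the mask, so the result is a subset of the input.
    """
    if not mask.any():
        return mask
    lum = rgb2lab(np.asarray(patch, dtype=np.float64) / 255.0)[..., 0]
    gradient = sobel(lum)
    cores = ndi.binary_erosion(mask, structure=disk(2), border_value=0)
    markers = cc_label(cores, connectivity=2)
    if markers.max() <= 1:
        return mask
    ws = watershed(gradient, markers=markers, mask=mask, watershed_line=True)
    return mask & (ws > 0)


def refine_mask(patch: np.ndarray, candidate: np.ndarray,
                params: RefineParams | None = None) -> np.ndarray:
    """Morphology -> area filter -> region growing -> watershed split.

    Idempotent on clean masks: a solid large component passes through
    unchanged.  The output never contains a component smaller than the
    minimum area.
    """
    a = _as_patch(patch)
    params = params or RefineParams()
    m = np.asarray(candidate, dtype=bool)
    if m.shape != a.shape[:2]:
        raise ValueError("candidate mask shape does not match image")
    if params.r_open > 0:
        m = opening(m, disk(params.r_open))
    if params.r_close > 0:
        m = closing(m, disk(params.r_close))
    min_area = _min_area(a.shape, params)
    # max_size semantics: removes components of size <= value
    m = remove_small_objects(m, max_size=min_area - 1, connectivity=2)
    if m.any() and params.grow_tol > 0:
        m = _region_grow(to_lab(a), m, params)
    m = _watershed_split(a, m)
    m = remove_small_objects(m, max_size=min_area - 1, connectivity=2)
    return m


def segment_skin(patch: np.ndarray, ranges: SkinRanges | None = None,
                 params: RefineParams | None = None) -> np.ndarray:
    """Full segmentation: color rules then refinement.  Deterministic."""
    return refine_mask(patch, pixel_rule_mask(patch, ranges), params)


def skin_fraction(mask: np.ndarray) -> float:
    m = np.asarray(mask, dtype=bool)
    return float(m.mean()) if m.size else 0.0


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegmentationMetrics:
    """Compare a predicted mask with ground truth in pixel fractions."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    n = p.size
    tp = float((p & t).sum()) / n
    tn = float((~p & ~t).sum()) / n
    fp = float((p & ~t).sum()) / n
    fn = float((~p & t).sum()) / n
    denom = tp + fp + fn
    jaccard = tp / denom if denom > 0 else 1.0
    return SegmentationMetrics(tp, tn, fp, fn, jaccard, tp + tn)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Persist a boolean mask as a 1-bit PNG alongside its source image."""
    from PIL import Image

    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(path)


def read_mask_png(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("1"), dtype=bool)


def write_metrics_csv(metrics: dict[str, "SegmentationMetrics"], path) -> None:
    """Batch metrics as CSV: image_id plus the six metric columns."""
    import csv

    cols = ["tp_frac", "tn_frac", "fp_frac", "fn_frac", "jaccard", "accuracy"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", *cols])
        for image_id, m in metrics.items():
            w.writerow([image_id, *(f"{getattr(m, c):.10g}" for c in cols)])


def evaluate_batch(preds: list[np.ndarray], truths: list[np.ndarray]
                   ) -> tuple[list[SegmentationMetrics], SegmentationMetrics]:
    """Per-image metrics and their arithmetic mean over a batch."""
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equal-length, non-empty mask lists")
    per = [evaluate_segmentation(p, t) for p, t in zip(preds, truths)]
    mean = SegmentationMetrics(*(float(np.mean([getattr(m, f) for m in per]))
                                 for f in ("tp_frac", "tn_frac", "fp_frac",
                                           "fn_frac", "jaccard", "accuracy")))
    return per, mean
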