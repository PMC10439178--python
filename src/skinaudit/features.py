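"""Image descriptors for skin detection and tone estimation.

Two feature vectors are built here, both 38-dimensional:

* the *detection* vector — a 32-bin global magnitude-weighted histogram of
  gradient directions (HOG) concatenated with the mean and standard deviation
  of the CIELAB L*, a*, b* channels — used to tell skin photographs apart
  from charts, text blocks and histology figures;
* the *tone* vector — the same HOG computed over the masked skin region,
  plus L*/b* statistics and individual-typology-angle (ITA) statistics over
  skin pixels only — used to classify Fitzpatrick I-IV vs V-VI.

The HOG here is a single global histogram, not the cell/block descriptor of
object-detection pipelines: every interior pixel contributes its gradient
magnitude to the direction bin nearest to arctan(Gy/Gx).
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2lab

__all__ = [
    "image_gradients",
    "hog_descriptor",
    "lab_stats",
    "detection_features",
    "ita_map",
    "ita_from_lab",
    "tone_features",
    "pca_project",
    "DETECTION_DIM",
    "HOG_BINS",
]

HOG_BINS = 32
DETECTION_DIM = 38


def _as_patch(pixels: np.ndarray) -> np.ndarray:
    a = np.asarray(pixels)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 sRGB array, got shape {a.shape}")
    if a.shape[0] == 0 or a.shape[1] == 0:
        raise ValueError("empty image")
    return a


def to_lab(pixels: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB patch to CIELAB (D65, 2-degree observer)."""
    a = _as_patch(pixels)
    return rgb2lab(a.astype(np.float64) / 255.0)


def intensity(pixels: np.ndarray) -> np.ndarray:
    """Scalar pixel intensity I(r, c): Rec.601 luma of the raw sRGB values.

    A linear combination of R, G, B is used (rather than CIELAB L*) so
    that gradients — and hence the HOG — are exactly invariant to adding
    a constant to all pixel intensities, and a grayscale ramp
    I(r, c) = c has central-difference gradient exactly 2.
    """
    a = _as_patch(pixels).astype(np.float64)
    return 0.299 * a[..., 0] + 0.587 * a[..., 1] + 0.114 * a[..., 2]


def image_gradients(patch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients of the intensity image.

    Gx(r, c) = I(r, c+1) - I(r, c-1) and Gy(r, c) = I(r+1, c) - I(r-1, c),
    evaluated at interior pixels only, so the output arrays are
    (H-2) x (W-2) for an H x W input.
    """
    a = _as_patch(patch)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for central differences")
    lum = intensity(a)
    gx = lum[1:-1, 2:] - lum[1:-1, :-2]
    gy = lum[2:, 1:-1] - lum[:-2, 1:-1]
    return gx, gy


def _gradient_angles(gx: np.ndarray, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel direction theta in (-pi/2, pi/2] and magnitude M.

    theta = arctan(Gy/Gx), the two-quadrant arctangent; vertical gradients
    (Gx = 0, Gy != 0) map to +pi/2 since -pi/2 is excluded from the range.
    Pixels with zero gradient get theta = 0 but carry zero magnitude.
    """
    mag = np.hypot(gx, gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arctan(np.divide(gy, gx, out=np.zeros_like(gy), where=gx != 0))
    theta = np.where((gx == 0) & (gy != 0), np.pi / 2, theta)
    return theta, mag


def hog_descriptor(patch: np.ndarray, bins: int = HOG_BINS) -> np.ndarray:
    """Global magnitude-weighted histogram of gradient directions.

    Directions span (-pi/2, pi/2] split into ``bins`` equal-width bins; each
    interior pixel adds its gradient magnitude to the bin whose center is
    nearest its direction (boundary ties go to the lower-index bin).  The
    histogram is L1-normalized when the total magnitude is positive,
    otherwise all zeros (e.g. for a constant image).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    gx, gy = image_gradients(patch)
    theta, mag = _gradient_angles(gx, gy)
    width = np.pi / bins
    # nearest-center assignment on equal bins == interval (-pi/2+i*w, -pi/2+(i+1)*w]
    idx = np.ceil((theta + np.pi / 2) / width).astype(int) - 1
    idx = np.clip(idx, 0, bins - 1)
    hist = np.bincount(idx.ravel(), weights=mag.ravel(), minlength=bins).astype(np.float64)
    total = hist.sum()
    if total > 0:
        hist /= total
    return hist


def lab_stats(patch: np.ndarray) -> np.ndarray:
    """[mu_L, mu_a, mu_b, sigma_L, sigma_a, sigma_b] over all pixels.

    Standard deviations are population (divide by N) values.
    """
    lab = to_lab(patch).reshape(-1, 3)
    return np.concatenate([lab.mean(axis=0), lab.std(axis=0)])


def detection_features(patch: np.ndarray, bins: int = HOG_BINS) -> np.ndarray:
    """The 38-dim skin/non-skin descriptor: HOG(32) ++ CIELAB stats(6)."""
    return np.concatenate([hog_descriptor(patch, bins), lab_stats(patch)])


def ita_from_lab(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Individual typology angle in degrees: arctan((L - 50) / b) * 180/pi.

    Higher ITA means lighter skin.  b = 0 is resolved to +-90 degrees by the
    sign of (L - 50), and to 0 degrees when additionally L = 50.
    """
    L = np.asarray(L, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ita = np.degrees(np.arctan(np.divide(L - 50.0, b, out=np.zeros_like(L), where=b != 0)))
    ita = np.where(b == 0, np.sign(L - 50.0) * 90.0, ita)
    return ita


def ita_map(patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-pixel ITA (degrees) over the masked skin pixels, as a 1-D array."""
    a = _as_patch(patch)
    m = np.asarray(mask, dtype=bool)
    if m.shape != a.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not m.any():
        raise ValueError("no skin pixels: mask is empty")
    lab = to_lab(a)
    return ita_from_lab(lab[..., 0][m], lab[..., 2][m])


def tone_features(patch: np.ndarray, mask: np.ndarray, bins: int = HOG_BINS,
                  ita_mean_only: bool = False) -> np.ndarray:
    """Tone descriptor over the skin mask.

    Concatenation of (i) the HOG of the mask's bounding box with non-skin
    pixels zeroed, (ii) [mu_L, sigma_L, mu_b, sigma_b] over masked pixels and
    (iii) [mean, std] of per-pixel ITA (mean only when ``ita_mean_only``,
    giving a 37-dim vector).  Length is 38 by default.
    """
    a = _as_patch(patch)
    m = np.asarray(mask, dtype=bool)
    if m.shape != a.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not m.any():
        raise ValueError("no skin pixels: mask is empty")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = a[r0:r1, c0:c1].copy()
    crop[~m[r0:r1, c0:c1]] = 0
    if crop.shape[0] < 3 or crop.shape[1] < 3:
        # degenerate sliver of skin: no interior pixels for gradients
        hog = np.zeros(bins)
    else:
        hog = hog_descriptor(crop, bins)
    lab = to_lab(a)
    Lm = lab[..., 0][m]
    bm = lab[..., 2][m]
    stats = np.array([Lm.mean(), Lm.std(), bm.mean(), bm.std()])
    ita = ita_from_lab(Lm, bm)
    ita_stats = np.array([ita.mean()]) if ita_mean_only else np.array([ita.mean(), ita.std()])
    return np.concatenate([hog, stats, ita_stats])


FEATURE_CSV_HEADER = ([f"h{i:02d}" for i in range(HOG_BINS)]
                      + ["muL", "mua", "mub", "sdL", "sda", "sdb"])


def write_feature_csv(vectors: np.ndarray, path, ids=None) -> None:
    """Write detection feature vectors as CSV, one row per image."""
    import csv

    X = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if X.shape[1] != DETECTION_DIM:
        raise ValueError(f"expected {DETECTION_DIM}-dim vectors")
    ids = ids if ids is not None else range(len(X))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", *FEATURE_CSV_HEADER])
        for i, row in zip(ids, X):
            w.writerow([i, *(f"{v:.10g}" for v in row)])


def pca_project(vectors: np.ndarray, k: int = 2) -> np.ndarray:
    """Centered projection of feature vectors onto their top-k principal axes.

    Used for quality-control visualization of the skin/non-skin feature
    space.  Component signs are fixed so that the largest-magnitude loading
    of each axis is positive, making the projection deterministic.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array of feature vectors")
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} vectors for a {k}-component projection")
    Xc = X - X.mean(axis=0)
    # SVD of the centered matrix gives the principal axes directly
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    axes = vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return Xc @ axes.T
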