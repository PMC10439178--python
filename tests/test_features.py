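"""Descriptor math checked against naive per-pixel reference implementations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skinaudit.features import (detection_features, hog_descriptor,
                                image_gradients, ita_from_lab, ita_map,
                                lab_stats, pca_project, tone_features)
from skimage.color import rgb2lab

from conftest import random_patch


# ---------------------------------------------------------------------------
# independent reference implementations (plain loops, no shared code paths)

def _luma(img):
    return (0.299 * img[..., 0].astype(float)
            + 0.587 * img[..., 1].astype(float)
            + 0.114 * img[..., 2].astype(float))


def gradients_oracle(img):
    lum = _luma(img)
    h, w = lum.shape
    gx = np.zeros((h - 2, w - 2))
    gy = np.zeros((h - 2, w - 2))
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            gx[r - 1, c - 1] = lum[r, c + 1] - lum[r, c - 1]
            gy[r - 1, c - 1] = lum[r + 1, c] - lum[r - 1, c]
    return gx, gy


def hog_oracle(img, bins=32):
    gx, gy = gradients_oracle(img)
    hist = np.zeros(bins)
    width = math.pi / bins
    for r in range(gx.shape[0]):
        for c in range(gx.shape[1]):
            x, y = gx[r, c], gy[r, c]
            mag = math.hypot(x, y)
            if x == 0:
                theta = math.pi / 2 if y != 0 else 0.0
            else:
                theta = math.atan(y / x)
            # nearest of `bins` equal-width centers on (-pi/2, pi/2],
            # boundary ties to the lower-index bin
            idx = math.ceil((theta + math.pi / 2) / width) - 1
            idx = min(max(idx, 0), bins - 1)
            hist[idx] += mag
    s = hist.sum()
    return hist / s if s > 0 else hist


def lab_stats_oracle(img):
    lab = rgb2lab(img.astype(float) / 255.0).reshape(-1, 3)
    return np.array([*lab.mean(axis=0), *lab.std(axis=0)])


# ---------------------------------------------------------------------------
# gradients

def test_gradients_constant_image_are_zero():
    img = np.full((5, 7, 3), 113, dtype=np.uint8)
    gx, gy = image_gradients(img)
    assert gx.shape == (3, 5)
    np.testing.assert_array_equal(gx, 0)
    np.testing.assert_array_equal(gy, 0)


def test_gradients_horizontal_ramp_closed_form():
    # grayscale ramp I(r, c) = c: central difference is exactly 2
    col = np.arange(10, dtype=np.uint8)
    img = np.stack([np.tile(col, (6, 1))] * 3, axis=-1)
    gx, gy = image_gradients(img)
    np.testing.assert_allclose(gx, 2.0, atol=1e-12)
    np.testing.assert_allclose(gy, 0.0, atol=1e-12)


def test_gradients_match_loop_oracle(rng):
    for _ in range(20):
        img = random_patch(rng)
        gx, gy = image_gradients(img)
        ox, oy = gradients_oracle(img)
        np.testing.assert_allclose(gx, ox, atol=1e-9)
        np.testing.assert_allclose(gy, oy, atol=1e-9)


def test_gradients_reject_tiny_images():
    with pytest.raises(ValueError):
        image_gradients(np.zeros((2, 5, 3), dtype=np.uint8))


# ---------------------------------------------------------------------------
# HOG

def test_hog_constant_image_is_all_zero():
    img = np.full((6, 6, 3), 40, dtype=np.uint8)
    assert not hog_descriptor(img).any()


def test_hog_vertical_step_edge_mass_in_theta_zero_bin():
    img = np.zeros((8, 8, 3), dtype=np.uint8)
    img[:, 4:] = 255
    h = hog_descriptor(img, bins=32)
    # theta = 0 lies in bin 15 of 32 over (-pi/2, pi/2]
    assert h[15] == pytest.approx(1.0)
    assert h.sum() == pytest.approx(1.0)


def test_hog_matches_loop_oracle(rng):
    for _ in range(20):
        img = random_patch(rng, 10, 10)
        np.testing.assert_allclose(hog_descriptor(img), hog_oracle(img), atol=1e-9)


def test_hog_rejects_bad_bins():
    with pytest.raises(ValueError):
        hog_descriptor(np.zeros((5, 5, 3), dtype=np.uint8), bins=1)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.integers(1, 60))
def test_hog_invariant_to_intensity_shift(seed, shift):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 196, size=(7, 7, 3), dtype=np.uint8)
    shifted = (img.astype(int) + shift).astype(np.uint8)
    np.testing.assert_allclose(hog_descriptor(img), hog_descriptor(shifted),
                               atol=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_hog_is_a_distribution_when_nonflat(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(6, 9, 3), dtype=np.uint8)
    h = hog_descriptor(img)
    assert (h >= 0).all()
    if h.any():
        assert h.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# CIELAB stats + combined vector

def test_lab_stats_pure_white_is_white_point():
    img = np.full((4, 4, 3), 255, dtype=np.uint8)
    mu_l, mu_a, mu_b, sd_l, sd_a, sd_b = lab_stats(img)
    assert mu_l == pytest.approx(100.0, abs=1e-3)
    assert abs(mu_a) < 0.02 and abs(mu_b) < 0.02
    assert sd_l == sd_a == sd_b == 0.0


def test_lab_stats_checkerboard_two_value_oracle():
    c1, c2 = (200, 30, 60), (10, 180, 90)
    img = np.empty((4, 4, 3), dtype=np.uint8)
    img[::2, ::2] = img[1::2, 1::2] = c1
    img[::2, 1::2] = img[1::2, ::2] = c2
    lab1 = rgb2lab(np.array(c1, dtype=float).reshape(1, 1, 3) / 255).ravel()
    lab2 = rgb2lab(np.array(c2, dtype=float).reshape(1, 1, 3) / 255).ravel()
    got = lab_stats(img)
    np.testing.assert_allclose(got[:3], (lab1 + lab2) / 2, atol=1e-9)
    np.testing.assert_allclose(got[3:], np.abs(lab1 - lab2) / 2, atol=1e-9)


def test_lab_stats_matches_oracle(rng):
    for _ in range(20):
        img = random_patch(rng, 6, 5)
        np.testing.assert_allclose(lab_stats(img), lab_stats_oracle(img), atol=1e-9)


def test_detection_features_is_38_and_concatenation(rng):
    for h, w in [(3, 3), (10, 15), (64, 48)]:
        img = random_patch(rng, h, w)
        v = detection_features(img)
        assert v.shape == (38,)
        np.testing.assert_array_equal(v[:32], hog_descriptor(img))
        np.testing.assert_array_equal(v[32:], lab_stats(img))


def test_detection_features_uniform_gray_zero_entries():
    img = np.full((5, 5, 3), 128, dtype=np.uint8)
    v = detection_features(img)
    assert not v[:32].any()
    np.testing.assert_allclose(v[35:], 0, atol=1e-12)  # sigma entries


# ---------------------------------------------------------------------------
# ITA

@pytest.mark.parametrize("L,b,expected", [
    (50.0, 15.0, 0.0),
    (70.0, 20.0, 45.0),
    (30.0, 20.0, -45.0),
    (70.0, 0.0, 90.0),
    (30.0, 0.0, -90.0),
    (50.0, 0.0, 0.0),
])
def test_ita_closed_forms(L, b, expected):
    assert float(ita_from_lab(L, b)) == pytest.approx(expected, abs=1e-9)


def test_ita_monotone_in_L_and_b():
    Ls = np.linspace(20, 90, 40)
    itas = ita_from_lab(Ls, np.full_like(Ls, 12.0))
    assert (np.diff(itas) > 0).all()  # increasing in L at fixed b > 0
    bs = np.linspace(2, 40, 40)
    itas_b = ita_from_lab(np.full_like(bs, 70.0), bs)
    assert (np.diff(itas_b) < 0).all()  # decreasing in b at fixed L > 50


def test_ita_map_requires_nonempty_mask(rng):
    img = random_patch(rng, 5, 5)
    with pytest.raises(ValueError, match="no skin pixels"):
        ita_map(img, np.zeros((5, 5), dtype=bool))


# ---------------------------------------------------------------------------
# tone features

def test_tone_features_uniform_patch_full_mask():
    img = np.full((8, 8, 3), (224, 172, 105), dtype=np.uint8)
    mask = np.ones((8, 8), dtype=bool)
    v = tone_features(img, mask)
    assert v.shape == (38,)
    assert v[33] == pytest.approx(0.0)   # sigma_L
    assert v[35] == pytest.approx(0.0)   # sigma_b
    assert v[37] == pytest.approx(0.0)   # sigma_ITA
    # full mask is a no-op relative to itself
    np.testing.assert_array_equal(v, tone_features(img, mask))


def test_tone_features_half_mask_two_value_oracle():
    img = np.empty((6, 6, 3), dtype=np.uint8)
    img[:, :3] = (224, 172, 105)
    img[:, 3:] = (92, 60, 45)
    mask = np.zeros((6, 6), dtype=bool)
    mask[:, :3] = True
    v = tone_features(img, mask)
    lab = rgb2lab(np.array([(224, 172, 105)], dtype=float).reshape(1, 1, 3) / 255).ravel()
    assert v[32] == pytest.approx(lab[0], abs=1e-9)  # mu_L over masked half
    assert v[34] == pytest.approx(lab[2], abs=1e-9)  # mu_b
    ita = float(ita_from_lab(lab[0], lab[2]))
    assert v[36] == pytest.approx(ita, abs=1e-9)
    assert v[33] == pytest.approx(0.0) and v[37] == pytest.approx(0.0)


def test_tone_features_mean_only_mode_is_37_dim(rng):
    img = random_patch(rng, 8, 8)
    mask = np.ones((8, 8), dtype=bool)
    assert tone_features(img, mask, ita_mean_only=True).shape == (37,)


# ---------------------------------------------------------------------------
# PCA projection

def test_pca_collinear_points_have_zero_second_component(rng):
    base = rng.normal(size=38)
    ts = np.linspace(-2, 2, 12)
    X = np.outer(ts, base)
    proj = pca_project(X, k=2)
    np.testing.assert_allclose(proj[:, 1], 0, atol=1e-9)


def test_pca_identical_vectors_project_to_zero():
    X = np.tile(np.arange(38.0), (5, 1))
    np.testing.assert_allclose(pca_project(X, k=2), 0, atol=1e-9)


def test_pca_variances_equal_top_eigenvalues(rng):
    X = rng.normal(size=(50, 38))
    proj = pca_project(X, k=2)
    cov = np.cov(X.T, bias=True)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(proj.var(axis=0), eig[:2], rtol=1e-9)


def test_pca_rejects_too_few_vectors(rng):
    with pytest.raises(ValueError):
        pca_project(rng.normal(size=(2, 38)), k=2)


def test_feature_csv_roundtrip(tmp_path, rng):
    import csv
    from skinaudit.features import write_feature_csv, FEATURE_CSV_HEADER
    X = np.array([detection_features(random_patch(rng)) for _ in range(3)])
    path = tmp_path / "features.csv"
    write_feature_csv(X, path, ids=["a", "b", "c"])
    rows = list(csv.reader(path.open()))
    assert rows[0] == ["image_id", *FEATURE_CSV_HEADER]
    back = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    np.testing.assert_allclose(back, X, rtol=1e-9)
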