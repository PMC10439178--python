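"""Tone estimation: ITA table lookup, ensembles, weighted metrics, splits."""

import numpy as np
import pytest

from skimage.color import lab2rgb

from skinaudit.features import tone_features
from skinaudit.tone import (DEFAULT_ITA_TABLE, EmptyMaskError, ItaFstTable,
                            ToneLabel, classify_tone_ita, ita_to_fst,
                            predict_tone, train_tone_ensemble,
                            train_val_test_split, weighted_metrics,
                            ENSEMBLE_KINDS)


def _lab_patch(L, a, b, h=10, w=10):
    lab = np.tile(np.array([L, a, b], dtype=float), (h, w, 1))
    return (np.clip(lab2rgb(lab), 0, 1) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# ITA -> FST table

@pytest.mark.parametrize("ita,index,binary", [
    (60.0, "I", "I-IV"),
    (48.0, "II", "I-IV"),
    (30.0, "III", "I-IV"),
    (15.0, "IV", "I-IV"),
    (0.0, "V", "V-VI"),
    (-45.0, "VI", "V-VI"),
])
def test_ita_to_fst_default_table(ita, index, binary):
    label = ita_to_fst(ita)
    assert label.fst_index == index
    assert label.fst_class == binary


@pytest.mark.parametrize("boundary,lighter", [
    (55.0, "I"), (41.0, "II"), (28.0, "III"), (10.0, "IV"), (-30.0, "V"),
])
def test_ita_boundaries_go_to_lighter_class(boundary, lighter):
    assert ita_to_fst(boundary).fst_index == lighter


def test_ita_to_fst_monotone_nonincreasing_index():
    order = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}
    itas = np.linspace(89.0, -89.0, 200)
    idx = [order[ita_to_fst(v).fst_index] for v in itas]
    assert all(a <= b for a, b in zip(idx, idx[1:]))


def test_ita_out_of_range_rejected():
    for bad in (-90.0, 95.0, float("nan")):
        with pytest.raises(ValueError):
            ita_to_fst(bad)


def test_custom_table_must_be_decreasing():
    with pytest.raises(ValueError):
        ItaFstTable((55.0, 41.0, 41.0, 10.0, -30.0))


# ---------------------------------------------------------------------------
# ITA classification of patches

def test_classify_ita_light_patch():
    patch = _lab_patch(70, 10, 20)   # ITA = 45 deg
    label = classify_tone_ita(patch, np.ones((10, 10), bool))
    assert label.fst_class == "I-IV"
    assert label.mean_ita == pytest.approx(45.0, abs=1.5)  # 8-bit quantization


def test_classify_ita_dark_patch():
    patch = _lab_patch(35, 8, 8)     # ITA ~ -61.9 deg
    label = classify_tone_ita(patch, np.ones((10, 10), bool))
    assert label.fst_index == "VI"
    assert label.fst_class == "V-VI"


def test_classify_ita_mean_of_two_tones():
    light = _lab_patch(70, 10, 20, 10, 5)
    dark = _lab_patch(35, 8, 8, 10, 5)
    patch = np.concatenate([light, dark], axis=1)
    mask = np.ones((10, 10), bool)
    from skinaudit.features import ita_map
    per_pixel = ita_map(patch, mask)
    label = classify_tone_ita(patch, mask)
    assert label.mean_ita == pytest.approx(float(per_pixel.mean()), abs=1e-9)


def test_classify_ita_invariant_to_uniform_patch_size():
    small = classify_tone_ita(_lab_patch(70, 10, 20, 6, 6), np.ones((6, 6), bool))
    big = classify_tone_ita(_lab_patch(70, 10, 20, 40, 40), np.ones((40, 40), bool))
    assert small.fst_index == big.fst_index
    assert small.mean_ita == pytest.approx(big.mean_ita, abs=1e-9)


def test_classify_ita_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        classify_tone_ita(_lab_patch(70, 10, 20), np.zeros((10, 10), bool))


def test_tone_label_consistency_enforced():
    with pytest.raises(ValueError):
        ToneLabel(fst_class="I-IV", score=0.9, fst_index="V")


# ---------------------------------------------------------------------------
# ensembles on tone features

@pytest.fixture(scope="module")
def tone_matrix(skin_subset):
    images, masks, y = skin_subset
    X = np.array([tone_features(img, m) for img, m in zip(images, masks)])
    return X, y


@pytest.mark.parametrize("kind", ENSEMBLE_KINDS)
def test_every_ensemble_kind_recovers_separable_tones(tone_matrix, kind):
    X, y = tone_matrix
    tr, va, te = train_val_test_split(np.arange(len(y)), y, seed=0)
    model = train_tone_ensemble(X[tr], y[tr], kind, seed=0)
    metrics = weighted_metrics(y[te], model.predict_proba(X[te]))
    assert metrics["f1"] >= 0.9


def test_permuted_tone_labels_near_chance(tone_matrix):
    X, y = tone_matrix
    rng = np.random.default_rng(0)
    yp = rng.permutation(y)
    tr, va, te = train_val_test_split(np.arange(len(yp)), yp, seed=0)
    model = train_tone_ensemble(X[tr], yp[tr], "random-forest", seed=0)
    metrics = weighted_metrics(yp[te], model.predict_proba(X[te]))
    assert 0.2 <= metrics["auroc"] <= 0.8


def test_balanced_forest_beats_plain_on_imbalanced_recall():
    """On a hard 9:1 problem, class reweighting should lift minority recall."""
    rng = np.random.default_rng(7)
    n_maj, n_min = 270, 30
    # heavily overlapping Gaussians so the plain forest can starve the minority
    X = np.vstack([rng.normal(0.0, 2.0, size=(n_maj, 38)),
                   rng.normal(1.0, 2.0, size=(n_min, 38))])
    y = np.array([0] * n_maj + [1] * n_min)
    tr, va, te = train_val_test_split(np.arange(len(y)), y, seed=1)
    from sklearn.metrics import recall_score
    recalls = {}
    for kind in ("random-forest", "balanced-random-forest"):
        model = train_tone_ensemble(X[tr], y[tr], kind, seed=0)
        pred = model.predict_proba(X[te]) >= 0.5
        recalls[kind] = recall_score(y[te], pred.astype(int))
    assert recalls["balanced-random-forest"] >= recalls["random-forest"]


def test_single_tone_class_rejected():
    X = np.zeros((10, 38))
    with pytest.raises(ValueError, match="both tone classes"):
        train_tone_ensemble(X, np.zeros(10, dtype=int))


def test_predict_tone_ensemble_path(skin_subset):
    images, masks, y = skin_subset
    X = np.array([tone_features(img, m) for img, m in zip(images, masks)])
    model = train_tone_ensemble(X, y, "random-forest", seed=0)
    label = predict_tone(model, images[0], masks[0])
    assert label.fst_class == ("V-VI" if y[0] else "I-IV")
    again = predict_tone(model, images[0], masks[0])
    assert label.score == again.score
    with pytest.raises(EmptyMaskError, match="no skin"):
        predict_tone(model, images[0], np.zeros_like(masks[0]))


# ---------------------------------------------------------------------------
# weighted metrics

def test_weighted_metrics_perfect():
    y = np.array([0, 0, 1, 1])
    m = weighted_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))
    assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1", "auroc"))


def test_weighted_equals_macro_on_balanced_classes():
    from sklearn.metrics import f1_score
    y = np.array([0, 0, 0, 1, 1, 1])
    scores = np.array([0.1, 0.6, 0.2, 0.9, 0.4, 0.8])
    m = weighted_metrics(y, scores)
    macro = f1_score(y, (scores >= 0.5).astype(int), average="macro")
    assert m["f1"] == pytest.approx(macro)


def test_weighted_metrics_hand_confusion():
    # 7 negatives, 3 positives; one error each way:
    # TP=2 FN=1 FP=1 TN=6 -> per-class F1 = 2/3 and 6/7; weights 0.3/0.7
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    scores = np.array([0.9, 0.8, 0.1, 0.7, 0.2, 0.1, 0.3, 0.2, 0.1, 0.0])
    m = weighted_metrics(y, scores)
    assert m["accuracy"] == pytest.approx(0.8)
    assert m["f1"] == pytest.approx(0.3 * (2 / 3) + 0.7 * (6 / 7))
    assert m["precision"] == pytest.approx(0.3 * (2 / 3) + 0.7 * (6 / 7))
    assert m["recall"] == pytest.approx(0.8)


def test_weighted_metrics_single_class_auroc_nan():
    m = weighted_metrics(np.array([1, 1, 1]), np.array([0.9, 0.8, 0.7]))
    assert np.isnan(m["auroc"])
    assert m["accuracy"] == 1.0


# ---------------------------------------------------------------------------
# split helper

def test_split_reproduces_70_10_20_with_stratification():
    y = np.array([0] * 80 + [1] * 20)
    X = np.arange(100)
    tr, va, te = train_val_test_split(X, y, seed=0)
    assert abs(len(tr) - 70) <= 1 and abs(len(va) - 10) <= 1 and abs(len(te) - 20) <= 1
    assert sorted(np.concatenate([tr, va, te])) == list(range(100))
    for part, frac in ((tr, 0.7), (va, 0.1), (te, 0.2)):
        n_pos = int(y[part].sum())
        assert abs(n_pos - 20 * frac) <= 1
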