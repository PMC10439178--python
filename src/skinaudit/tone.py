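"""Skin tone classification: Fitzpatrick I-IV (light) vs V-VI (dark).

Three routes are provided, matching how the audit was validated:

* **ITA thresholding** — the mean individual typology angle over the skin
  mask is looked up in an ITA -> Fitzpatrick table (lighting-sensitive but
  training-free);
* **ensembles** — random forest, balanced random forest, extremely
  randomized trees, AdaBoost and gradient boosting on the 38-dim tone
  feature vector;
* **CNN** — the 18-layer residual network applied to the masked image
  (non-skin pixels zeroed), fine-tuned with class-weighted cross-entropy.

FST V-VI is the positive class everywhere, and evaluation metrics are
weighted by true class frequency to respect the heavy class imbalance of
real educational materials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier, RandomForestClassifier)
from sklearn.metrics import (accuracy_score, precision_recall_fscore_support,
                             roc_auc_score)
from sklearn.model_selection import train_test_split

from .features import ita_map, tone_features
from .nn import ResNet18, sgd_train, softmax

__all__ = [
    "ToneLabel", "ItaFstTable", "DEFAULT_ITA_TABLE", "ita_to_fst",
    "classify_tone_ita", "EnsembleToneModel", "train_tone_ensemble",
    "CnnToneModel", "build_cnn", "finetune_cnn", "predict_tone",
    "weighted_metrics", "train_val_test_split", "EmptyMaskError",
    "ENSEMBLE_KINDS",
]

LIGHT, DARK = "I-IV", "V-VI"
_ROMAN = ("I", "II", "III", "IV", "V", "VI")

ENSEMBLE_KINDS = ("random-forest", "balanced-random-forest",
                  "extremely-randomized-trees", "adaboost",
                  "gradient-boosting")


class EmptyMaskError(ValueError):
    """No skin detected: the image is excluded from tone counts."""


@dataclass(frozen=True)
class ToneLabel:
    """Binary tone call; fst_index is populated only by the ITA route."""

    fst_class: str                 # "I-IV" or "V-VI"
    score: float                   # probability of V-VI
    fst_index: str | None = None   # "I".."VI"
    mean_ita: float | None = None  # degrees, ITA route only

    def __post_init__(self):
        if self.fst_class not in (LIGHT, DARK):
            raise ValueError(f"bad fst_class {self.fst_class!r}")
        if self.fst_index is not None:
            dark = self.fst_index in ("V", "VI")
            if dark != (self.fst_class == DARK):
                raise ValueError("fst_index inconsistent with fst_class")


@dataclass(frozen=True)
class ItaFstTable:
    """Strictly decreasing ITA thresholds t1..t5 (degrees) separating the
    six Fitzpatrick categories.  An ITA above t1 is type I; below t5 is
    type VI.  A value exactly on a boundary goes to the *lighter* type.
    """

    thresholds: tuple[float, float, float, float, float] = (55.0, 41.0, 28.0, 10.0, -30.0)

    def __post_init__(self):
        t = self.thresholds
        if len(t) != 5 or any(t[i] <= t[i + 1] for i in range(4)):
            raise ValueError("thresholds must be 5 strictly decreasing values")

    def lookup(self, ita: float) -> str:
        for i, t in enumerate(self.thresholds):
            if ita >= t:
                return _ROMAN[i]
        return _ROMAN[5]


DEFAULT_ITA_TABLE = ItaFstTable()


def ita_to_fst(ita: float, table: ItaFstTable = DEFAULT_ITA_TABLE) -> ToneLabel:
    """Map an ITA value (degrees) to a Fitzpatrick index and binary class."""
    if not (-90.0 < ita <= 90.0) or not np.isfinite(ita):
        raise ValueError(f"ITA {ita} outside (-90, 90]")
    idx = table.lookup(float(ita))
    dark = idx in ("V", "VI")
    return ToneLabel(fst_class=DARK if dark else LIGHT,
                     score=1.0 if dark else 0.0, fst_index=idx,
                     mean_ita=float(ita))


def classify_tone_ita(patch: np.ndarray, mask: np.ndarray,
                      table: ItaFstTable = DEFAULT_ITA_TABLE) -> ToneLabel:
    """ITA route: mean per-pixel ITA over the mask, then table lookup."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyMaskError("no skin detected")
    return ita_to_fst(float(ita_map(patch, m).mean()), table)


# ---------------------------------------------------------------------------
# ensemble route


@dataclass
class EnsembleToneModel:
    kind: str
    estimator: object
    feature_dim: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.feature_dim:
            raise ValueError(f"expected {self.feature_dim}-dim tone features, "
                             f"got {X.shape[1]}")
        return self.estimator.predict_proba(X)[:, 1]


def _make_ensemble(kind: str, seed: int):
    if kind == "random-forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if kind == "balanced-random-forest":
        # class_weight balanced per bootstrap: the sklearn counterpart of a
        # balanced random forest
        return RandomForestClassifier(n_estimators=200, random_state=seed,
                                      class_weight="balanced_subsample", n_jobs=1)
    if kind == "extremely-randomized-trees":
        return ExtraTreesClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if kind == "adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    if kind == "gradient-boosting":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown ensemble kind {kind!r}; choose from {ENSEMBLE_KINDS}")


def train_tone_ensemble(X, y, kind: str = "random-forest",
                        seed: int = 0) -> EnsembleToneModel:
    """Fit an ensemble on tone feature vectors; y is 1 for FST V-VI."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both tone classes in the training labels")
    est = _make_ensemble(kind, seed)
    est.fit(X, y)
    return EnsembleToneModel(kind=kind, estimator=est, feature_dim=X.shape[1])


# ---------------------------------------------------------------------------
# CNN route


@dataclass
class CnnToneModel:
    net: ResNet18
    input_size: int

    def preprocess(self, images: list[np.ndarray]) -> np.ndarray:
        """Resize to the network input, scale to zero mean / unit-ish scale."""
        out = np.empty((len(images), 3, self.input_size, self.input_size),
                       dtype=np.float32)
        for i, img in enumerate(images):
            r = resize(np.asarray(img, dtype=np.float64) / 255.0,
                       (self.input_size, self.input_size, 3),
                       order=1, anti_aliasing=True, preserve_range=True)
            out[i] = ((r - 0.5) / 0.25).transpose(2, 0, 1)
        return out

    def predict_proba(self, images: list[np.ndarray],
                      batch_size: int = 32) -> np.ndarray:
        x = self.preprocess(images)
        probs = []
        for start in range(0, len(x), batch_size):
            logits = self.net.forward(x[start:start + batch_size], train=False)
            probs.append(softmax(logits)[:, 1])
        return np.concatenate(probs)


def build_cnn(num_classes: int = 2, input_size: int = 224,
              seed: int = 0, weights: list[np.ndarray] | None = None) -> CnnToneModel:
    """Construct the 18-layer residual classifier.

    With ``num_classes=1000`` the trainable parameter count is 11,689,512;
    the 2-class head used for tone estimation has 11,177,538.  A backbone
    weights list (from :meth:`ResNet18.state_arrays`) may be supplied;
    otherwise initialization is random (seeded).
    """
    net = ResNet18(num_classes=num_classes, input_size=input_size, seed=seed)
    if weights is not None:
        net.load_state_arrays(weights)
    return CnnToneModel(net=net, input_size=input_size)


def finetune_cnn(model: CnnToneModel, images: list[np.ndarray], labels,
                 epochs: int = 20, lr: float = 1e-3, batch_size: int = 32,
                 class_weights=None, seed: int = 0) -> list[float]:
    """Fine-tune with SGD on class-weighted cross-entropy.

    The learning rate decays linearly from ``lr`` to 0 across epochs.
    Returns the per-epoch mean training loss.
    """
    y = np.asarray(labels).astype(int)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("need both tone classes for fine-tuning")
    x = model.preprocess(images)
    cw = None if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    return sgd_train(model.net, x, y, epochs=epochs, lr=lr,
                     batch_size=batch_size, class_weights=cw, seed=seed)


# ---------------------------------------------------------------------------
# unified prediction + metrics


def predict_tone(model, patch: np.ndarray, mask: np.ndarray,
                 threshold: float = 0.5) -> ToneLabel:
    """Classify one masked image with either route's fitted model.

    Ensemble models consume the tone feature vector; CNN models consume
    the masked image with non-skin pixels zeroed.  An empty mask raises
    :class:`EmptyMaskError` ("no skin detected").
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyMaskError("no skin detected")
    if isinstance(model, EnsembleToneModel):
        feats = tone_features(patch, m)
        p = float(model.predict_proba(feats[None, :])[0])
    elif isinstance(model, CnnToneModel):
        masked = np.asarray(patch, dtype=np.uint8).copy()
        masked[~m] = 0
        p = float(model.predict_proba([masked])[0])
    else:
        raise TypeError(f"unsupported tone model {type(model).__name__}")
    return ToneLabel(fst_class=DARK if p >= threshold else LIGHT, score=p)


def weighted_metrics(y_true, y_score, threshold: float = 0.5) -> dict[str, float]:
    """Frequency-weighted accuracy/precision/recall/F1 plus AUROC.

    Per-class binary metrics are averaged with weights equal to each
    class's frequency in ``y_true`` (V-VI = 1 is the positive class).
    AUROC is threshold-free and requires both classes; with a single
    class it is returned as NaN.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=np.float64)
    y_pred = (y_score >= threshold).astype(int)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0)
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
    }
    if len(np.unique(y_true)) < 2:
        out["auroc"] = float("nan")
    else:
        out["auroc"] = float(roc_auc_score(y_true, y_score))
    return out


def train_val_test_split(X, y, fractions=(0.7, 0.1, 0.2), seed: int = 0):
    """Stratified 70/10/20 split returning (train, val, test) index arrays."""
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = np.asarray(y)
    idx = np.arange(len(y))
    tr, rest = train_test_split(idx, test_size=f_val + f_test,
                                stratify=y, random_state=seed)
    val, te = train_test_split(rest, test_size=f_test / (f_val + f_test),
                               stratify=y[rest], random_state=seed)
    return tr, val, te
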