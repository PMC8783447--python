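"""The two small CNN classifiers: vesicle selection and phase state.

Two tasks share one architecture family (conv->BN->ReLU blocks, two 2x2
stride-2 max-pools, FC + softmax on 50x50 zerocenter-normalized inputs):

* the 4-class *selection* filter (16/32/64 filters, FC output 4) sorts
  vesicle sections into C1 typical unilamellar, C2 multilamellar,
  C3 overlapping, C4 hazy/unclear — only C1 passes;
* the 2-class *state* classifier (8/16/32 filters, FC output 2) decides
  homogeneous vs domain-separated sections on background-thresholded
  patches.

Training uses stochastic gradient descent with momentum at the fixed
configuration: initial learning rate 0.01, at most 4 epochs, validation
every 30 iterations.  The estimator surface is scikit-learn style
(``fit`` / ``predict`` / ``predict_proba`` with trailing-underscore fitted
attributes), so it composes with sklearn model-selection tooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin

from ._raster import resample_bilinear
from .nn import SmallCnn, sgdm_train
from .segment import CircleDetection
from .simulate import (
    PATCH_SIZE,
    SELECTION_CLASSES,
    STATE_CLASSES,
    LabeledPatchSet,
    zero_background,
)

DEFAULT_PATCH_MARGIN = 1.2


@dataclass(frozen=True)
class CnnSpec:
    """Architecture description, auditable layer by layer."""

    kind: str
    conv_filters: tuple[int, int, int]
    fc_output: int
    input_size: int = PATCH_SIZE
    class_names: tuple[str, ...] = ()


@dataclass
class TrainConfig:
    """SGDM training configuration (defaults are the fixed recipe)."""

    initial_lr: float = 0.01
    max_epochs: int = 4
    validation_frequency: int = 30
    momentum: float = 0.9
    batch_size: int = 32
    loss: str = "cross_entropy"  # or "mse" (MSE between softmax and one-hot)
    rng_seed: int = 0


def build_cnn(kind: str) -> CnnSpec:
    """Architecture spec for one of the two classifier kinds."""
    if kind == "selection":
        return CnnSpec(
            kind=kind,
            conv_filters=(16, 32, 64),
            fc_output=4,
            class_names=tuple(SELECTION_CLASSES),
        )
    if kind == "state":
        return CnnSpec(
            kind=kind,
            conv_filters=(8, 16, 32),
            fc_output=2,
            class_names=tuple(STATE_CLASSES),
        )
    raise ValueError(f"unknown CNN kind: {kind!r}")


def prepare_patch(
    image: np.ndarray,
    circle: CircleDetection,
    margin: float = DEFAULT_PATCH_MARGIN,
    zero_bg: bool = False,
) -> np.ndarray:
    """Crop a detected vesicle and resample it to a 50x50 patch.

    The source crop is the square of side ``2 * margin * r`` centered on the
    circle, clamped to the image bounds, resampled bilinearly.  With
    ``zero_bg`` (the state classifier's preprocessing) pixels at or below
    the section's triangle threshold are zeroed before cropping.
    """
    if circle.r < 1:
        raise ValueError("degenerate circle: radius below 1 px")
    image = np.asarray(image, dtype=float)
    if zero_bg:
        image = zero_background(image)
    half = margin * circle.r
    h, w = image.shape
    y0 = max(int(round(circle.cy - half)), 0)
    y1 = min(int(round(circle.cy + half)) + 1, h)
    x0 = max(int(round(circle.cx - half)), 0)
    x1 = min(int(round(circle.cx + half)) + 1, w)
    crop = image[y0:y1, x0:x1]
    return resample_bilinear(crop, (PATCH_SIZE, PATCH_SIZE)).astype(np.float32)


def augment(
    patch_set: LabeledPatchSet,
    scale_range: tuple[float, float] = (0.9, 1.1),
    shift_range: tuple[float, float] = (-3.0, 3.0),
    multiplier: int = 2,
    rng: np.random.Generator | None = None,
) -> LabeledPatchSet:
    """Augment by image scaling and position shifting; labels are preserved.

    Each output patch applies one random (scale, shift) drawn from the
    ranges, which must contain the identity (scale 1, shift 0); degenerate
    identity ranges therefore reproduce the inputs exactly.  The output
    holds ``multiplier`` transformed copies of every input patch.
    """
    if not scale_range[0] <= 1.0 <= scale_range[1]:
        raise ValueError("scale_range must contain the identity scale 1")
    if not shift_range[0] <= 0.0 <= shift_range[1]:
        raise ValueError("shift_range must contain the identity shift 0")
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    out_patches = []
    out_labels = []
    center = (PATCH_SIZE - 1) / 2.0
    base_yy, base_xx = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE].astype(float)
    for _ in range(multiplier):
        for patch, label in zip(patch_set.patches, patch_set.labels):
            s = _maybe_uniform(rng, scale_range)
            dy = _maybe_uniform(rng, shift_range)
            dx = _maybe_uniform(rng, shift_range)
            if s == 1.0 and dy == 0.0 and dx == 0.0:
                out = np.asarray(patch, dtype=np.float32)
            else:
                yy = center + (base_yy - center) / s - dy
                xx = center + (base_xx - center) / s - dx
                out = ndimage.map_coordinates(
                    patch, [yy, xx], order=1, mode="nearest"
                ).astype(np.float32)
            out_patches.append(out)
            out_labels.append(label)
    return LabeledPatchSet(
        np.asarray(out_patches, dtype=np.float32),
        np.asarray(out_labels, dtype=int),
        list(patch_set.class_names),
    )


def _maybe_uniform(rng: np.random.Generator, rang: tuple[float, float]) -> float:
    lo, hi = rang
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


class PatchClassifier(BaseEstimator, ClassifierMixin):
    """Small-CNN patch classifier with a scikit-learn estimator surface.

    Parameters
    ----------
    kind : {"selection", "state"}
        Architecture family: 16/32/64 filters with 4 outputs, or 8/16/32
        with 2 outputs.
    learning_rate, max_epochs, validation_frequency, momentum, batch_size
        SGDM training configuration; defaults are the fixed recipe.
    loss : {"cross_entropy", "mse"}
        Training criterion on the softmax outputs.
    val_fraction : float
        Held-out fraction used for the periodic validation checkpoints
        when ``fit`` is not given an explicit validation set.
    random_state : int
        Seed for weight initialization and shuffling; fixed seed plus
        single-threaded execution gives an identical training history.

    Attributes (after fit)
    ----------------------
    spec_ : CnnSpec
    network_ : SmallCnn
    classes_ : ndarray of class names
    mean_image_ : ndarray, the zerocenter statistic (training-set mean image)
    history_ : list of TrainRecord
    val_accuracy_ : float, final held-out accuracy
    """

    def __init__(
        self,
        kind: str = "state",
        learning_rate: float = 0.01,
        max_epochs: int = 4,
        validation_frequency: int = 30,
        momentum: float = 0.9,
        batch_size: int = 32,
        loss: str = "cross_entropy",
        val_fraction: float = 0.15,
        random_state: int = 0,
    ):
        self.kind = kind
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.validation_frequency = validation_frequency
        self.momentum = momentum
        self.batch_size = batch_size
        self.loss = loss
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (n, 50, 50) patches with integer or class-name labels."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"X must be (n, {PATCH_SIZE}, {PATCH_SIZE})")
        spec = build_cnn(self.kind)
        y = self._encode_labels(np.asarray(y), spec)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain at least 2 classes")
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            n_val = max(int(round(self.val_fraction * len(X))), 1)
            order = rng.permutation(len(X))
            val_idx, train_idx = order[:n_val], order[n_val:]
            X, X_val = X[train_idx], X[val_idx]
            y, y_val = y[train_idx], y[val_idx]
        else:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = self._encode_labels(np.asarray(y_val), spec)

        # zerocenter: subtract the training-set mean image everywhere
        self.mean_image_ = X.mean(axis=0)
        xt = (X - self.mean_image_)[:, None, :, :]
        xv = (X_val - self.mean_image_)[:, None, :, :]

        self.spec_ = spec
        self.classes_ = np.asarray(spec.class_names)
        self.network_ = SmallCnn(
            spec.conv_filters, spec.fc_output, input_size=spec.input_size, rng=rng
        )
        self.history_ = sgdm_train(
            self.network_,
            xt,
            y,
            xv,
            y_val,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            validation_frequency=self.validation_frequency,
            loss=self.loss,
            rng=rng,
        )
        # the trainer returns the best-validation checkpoint, so score the
        # delivered network rather than the last SGD iterate
        probs = self.network_.predict_proba(xv)
        self.val_accuracy_ = float((probs.argmax(axis=1) == y_val).mean())
        return self

    def _encode_labels(self, y: np.ndarray, spec: CnnSpec) -> np.ndarray:
        if y.dtype.kind in "UO":
            lut = {name: i for i, name in enumerate(spec.class_names)}
            return np.asarray([lut[v] for v in y], dtype=int)
        return y.astype(int)

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patches must be {PATCH_SIZE}x{PATCH_SIZE}")
        xc = (X - self.mean_image_)[:, None, :, :]
        probs = self.network_.predict_proba(xc)
        return probs[0] if single else probs

    def predict(self, X) -> np.ndarray:
        probs = np.atleast_2d(self.predict_proba(X))
        idx = probs.argmax(axis=1)
        out = self.classes_[idx]
        return out[0] if np.asarray(X).ndim == 2 else out

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: .npz weight store plus a JSON sidecar."""
        path = Path(path)
        arrays = {"mean_image": self.mean_image_}
        for i, layer in enumerate(self.network_.layers):
            for name in ("weight", "bias", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, name):
                    arrays[f"layer{i}_{name}"] = getattr(layer, name)
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "kind": self.kind,
            "spec": asdict(self.spec_),
            "class_names": list(self.classes_),
            "params": self.get_params(),
            "history": [asdict(h) for h in self.history_],
            "val_accuracy": self.val_accuracy_,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "PatchClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        clf = cls(**sidecar["params"])
        spec = build_cnn(sidecar["kind"])
        clf.spec_ = spec
        clf.classes_ = np.asarray(sidecar["class_names"])
        clf.network_ = SmallCnn(spec.conv_filters, spec.fc_output, spec.input_size)
        data = np.load(path.with_suffix(".npz"))
        clf.mean_image_ = data["mean_image"]
        for i, layer in enumerate(clf.network_.layers):
            for name in ("weight", "bias", "gamma", "beta", "running_mean", "running_var"):
                key = f"layer{i}_{name}"
                if key in data:
                    getattr(layer, name)[...] = data[key]
        clf.history_ = sidecar["history"]
        clf.val_accuracy_ = sidecar["val_accuracy"]
        return clf


# -- functional wrappers ----------------------------------------------------


def train(
    spec: CnnSpec,
    train_set: LabeledPatchSet,
    val_set: LabeledPatchSet,
    config: TrainConfig | None = None,
) -> PatchClassifier:
    """Train a classifier for ``spec`` on explicit train/validation sets."""
    config = config or TrainConfig()
    clf = PatchClassifier(
        kind=spec.kind,
        learning_rate=config.initial_lr,
        max_epochs=config.max_epochs,
        validation_frequency=config.validation_frequency,
        momentum=config.momentum,
        batch_size=config.batch_size,
        loss=config.loss,
        random_state=config.rng_seed,
    )
    return clf.fit(
        train_set.patches, train_set.labels, val_set.patches, val_set.labels
    )


def classify(classifier: PatchClassifier, patch: np.ndarray) -> tuple[str, np.ndarray]:
    """Classify one 50x50 patch: (class name, probability vector)."""
    probs = classifier.predict_proba(patch)
    return str(classifier.classes_[int(np.argmax(probs))]), probs


def cnn_selection_filter(
    entities,
    stack,
    classifier: PatchClassifier,
    margin: float = DEFAULT_PATCH_MARGIN,
    min_sections: int = 3,
):
    """Keep only sections the 4-class CNN calls C1, then re-check entities.

    Each section circle is cropped to a 50x50 patch and classified; the
    class and its probabilities are recorded on the entity.  Sections not
    classified C1 are dropped, and entities that fall below
    ``min_sections`` surviving sections are rejected.
    """
    if len(classifier.classes_) != 4:
        raise ValueError("selection filter needs a 4-class classifier")
    from .assemble import filter_min_sections  # local import avoids a cycle

    for entity in entities:
        kept = []
        metrics = []
        for circ in entity.sections:
            patch = prepare_patch(stack[circ.z_index], circ, margin=margin)
            cls, probs = classify(classifier, patch)
            metrics.append({"z_index": circ.z_index, "class": cls, "probs": probs})
            if cls == "C1":
                kept.append(circ)
        entity.per_section_metrics = metrics
        entity.sections = kept or entity.sections
        if not kept:
            entity.status = "rejected:no-C1-sections"
    return filter_min_sections([e for e in entities if e.accepted], min_sections)
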