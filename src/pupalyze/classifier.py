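"""Frame-wise movement classification from sliding 25-frame windows.

Each training example is a window of 25 consecutive movie frames (12
before, the center, 12 after) labeled with the movement class of the
center frame, one of nine classes (the eight canonical movements plus
Rest).  The desk-scale model is a small gradient-trained multilayer
perceptron over block-pooled window pixels, optimized with Adam on
categorical cross-entropy and early-stopped when the validation loss has
not improved for ``patience`` consecutive epochs; the windowing, loss,
early stopping, and per-frame argmax decoding are the contract, not the
network architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, log_loss, precision_recall_fscore_support
from sklearn.neural_network import MLPClassifier

from .errors import (
    DegenerateTrainingError,
    InsufficientDataError,
    InvalidConfigError,
    ValidationError,
)
from .syllabary import MOVEMENT_CLASSES

WINDOW = 25
HALF = WINDOW // 2


@dataclass
class WindowDataset:
    """Sliding windows (n, 25, H, W) with center-frame labels."""

    windows: np.ndarray
    labels: np.ndarray
    animal_ids: np.ndarray
    classes: tuple[str, ...] = MOVEMENT_CLASSES

    def __post_init__(self) -> None:
        if self.windows.ndim != 4 or self.windows.shape[1] != WINDOW:
            raise ValidationError("windows must have shape (n, 25, H, W)")
        if len(self.labels) != len(self.windows) or len(self.animal_ids) != len(self.windows):
            raise ValidationError("labels/animal_ids must match window count")

    def __len__(self) -> int:
        return len(self.windows)

    def concat(self, other: "WindowDataset") -> "WindowDataset":
        return WindowDataset(
            np.concatenate([self.windows, other.windows]),
            np.concatenate([self.labels, other.labels]),
            np.concatenate([self.animal_ids, other.animal_ids]),
            self.classes,
        )


@dataclass
class ClassifierConfig:
    learning_rate: float = 1e-4
    patience: int = 10
    max_epochs: int = 150
    hidden_layer_sizes: tuple[int, ...] = (64,)
    pool: tuple[int, int] = (4, 4)     # block-mean pooling factors (rows, cols)
    time_stride: int = 4               # keep every k-th frame of the window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning rate must be > 0")
        if self.patience < 1:
            raise InvalidConfigError("patience must be >= 1")


def make_windows(stack: np.ndarray, frame_labels, animal_id: str = "A0") -> WindowDataset:
    """All overlapping 25-frame windows of an (N, H, W) stack.

    One window per valid center frame t in [12, N-13], labeled with
    ``frame_labels[t]``; the window count is N - 24.
    """
    stack = np.asarray(stack)
    n = stack.shape[0]
    labels = np.asarray(frame_labels)
    if labels.shape[0] != n:
        raise ValidationError("frame_labels must cover all frames")
    if n < WINDOW:
        raise InsufficientDataError(f"need >= {WINDOW} frames, got {n}")
    centers = np.arange(HALF, n - HALF)
    windows = np.stack([stack[c - HALF:c + HALF + 1] for c in centers])
    return WindowDataset(
        windows.astype(np.float32),
        labels[centers].astype(object),
        np.full(len(centers), animal_id, dtype=object),
    )


def _features(windows: np.ndarray, pool: tuple[int, int], time_stride: int) -> np.ndarray:
    """Block-mean pool each frame and subsample the time axis, then flatten."""
    w = windows[:, ::time_stride]
    n, t, h, wd = w.shape
    pr, pc = pool
    h2, w2 = h - h % pr, wd - wd % pc
    w = w[:, :, :h2, :w2].reshape(n, t, h2 // pr, pr, w2 // pc, pc).mean(axis=(3, 5))
    flat = w.reshape(n, -1)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True) + 1e-6
    return (flat - mu) / sd


@dataclass
class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement."""

    patience: int
    best: float = np.inf
    bad_epochs: int = 0

    def update(self, value: float) -> bool:
        """Record an epoch's validation objective; True means stop now."""
        if value < self.best - 1e-12:
            self.best = value
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


@dataclass
class TrainedModel:
    mlp: MLPClassifier
    config: ClassifierConfig
    classes: tuple[str, ...]
    training_log: list[dict] = field(default_factory=list)


def train_classifier(
    dataset: WindowDataset,
    config: ClassifierConfig | None = None,
    validation_animals: list[str] | None = None,
    validation_fraction: float = 0.2,
) -> TrainedModel:
    """Train the window classifier with animal-held-out early stopping.

    Validation windows come from ``validation_animals`` when given;
    otherwise from the last ``validation_fraction`` of animals (at least
    one).  Training runs epoch-by-epoch (Adam, cross-entropy) and stops
    when the validation loss fails to improve ``patience`` epochs running.
    """
    config = config or ClassifierConfig()
    present = np.unique(dataset.labels)
    if len(present) < 2:
        raise DegenerateTrainingError("dataset contains a single class")
    animals = sorted(set(dataset.animal_ids))
    if validation_animals is None:
        n_val = max(1, int(round(validation_fraction * len(animals))))
        validation_animals = animals[-n_val:] if len(animals) > 1 else []
    val_mask = np.isin(dataset.animal_ids, validation_animals)
    if len(animals) > 1 and not val_mask.any():
        raise ValidationError("validation animals contribute no windows")
    if val_mask.all():
        raise ValidationError("no training windows left")
    x = _features(dataset.windows, config.pool, config.time_stride)
    y = dataset.labels.astype(str)
    classes = np.array(sorted(dataset.classes))
    x_tr, y_tr = x[~val_mask], y[~val_mask]
    x_va, y_va = x[val_mask], y[val_mask]
    if x_va.shape[0] == 0:  # single-animal fallback: random tail split
        k = max(1, int(round(validation_fraction * len(x_tr))))
        x_va, y_va = x_tr[-k:], y_tr[-k:]
        x_tr, y_tr = x_tr[:-k], y_tr[:-k]
    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_layer_sizes,
        solver="adam",
        learning_rate_init=config.learning_rate,
        random_state=config.seed,
        max_iter=1,
        warm_start=False,
    )
    stopper = EarlyStopping(config.patience)
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    best_coefs = None
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        mlp.partial_fit(x_tr[order], y_tr[order], classes=classes)
        val_loss = log_loss(y_va, mlp.predict_proba(x_va), labels=classes)
        log.append({"epoch": epoch, "val_loss": float(val_loss)})
        if val_loss < stopper.best:
            best_coefs = ([c.copy() for c in mlp.coefs_],
                          [b.copy() for b in mlp.intercepts_])
        if stopper.update(val_loss):
            break
    if best_coefs is not None:
        mlp.coefs_, mlp.intercepts_ = best_coefs
    return TrainedModel(mlp, config, tuple(classes), log)


def predict_movements(model: TrainedModel, stack: np.ndarray) -> pd.DataFrame:
    """Per-frame class probabilities and argmax labels for a movie.

    Edge frames (the first and last 12) take the prediction of the nearest
    valid window center.  Probabilities per frame sum to one.
    """
    stack = np.asarray(stack)
    n = stack.shape[0]
    if n < WINDOW:
        raise InsufficientDataError(f"stack shorter than {WINDOW} frames")
    ds = make_windows(stack, np.full(n, "Rest", dtype=object))
    x = _features(ds.windows, model.config.pool, model.config.time_stride)
    proba = model.mlp.predict_proba(x)
    full = np.empty((n, proba.shape[1]))
    full[HALF:n - HALF] = proba
    full[:HALF] = proba[0]
    full[n - HALF:] = proba[-1]
    labels = np.array(model.classes)[full.argmax(axis=1)]
    out = pd.DataFrame(full, columns=list(model.classes))
    out.insert(0, "frame", np.arange(n))
    out["label"] = labels
    out["max_probability"] = full.max(axis=1)
    return out


@dataclass
class Evaluation:
    accuracy: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame
    durations: pd.DataFrame


def evaluate_predictions(
    pred_labels, truth_labels, fps: float = 2.0,
    classes: tuple[str, ...] = MOVEMENT_CLASSES,
) -> Evaluation:
    """Per-frame accuracy, per-class precision/recall, confusion counts, and
    a per-class duration table (frame counts / fps, in seconds)."""
    pred = np.asarray(pred_labels, dtype=object)
    truth = np.asarray(truth_labels, dtype=object)
    if pred.shape != truth.shape:
        raise ValidationError("prediction/truth length mismatch")
    labels = sorted(classes)
    acc = float(np.mean(pred == truth))
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, pred, labels=labels, zero_division=0
    )
    per_class = pd.DataFrame(
        {"class": labels, "precision": prec, "recall": rec, "f1": f1, "support": support}
    )
    conf = pd.DataFrame(
        confusion_matrix(truth, pred, labels=labels), index=labels, columns=labels
    )
    durations = pd.DataFrame({
        "class": labels,
        "pred_duration_s": [float((pred == c).sum() / fps) for c in labels],
        "true_duration_s": [float((truth == c).sum() / fps) for c in labels],
    })
    return Evaluation(acc, per_class, conf, durations)
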