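"""MLP vigilance-state classifier: splitting, oversampling, training,
prediction, and evaluation.

The network is a fully connected 210-512-3 perceptron (ReLU hidden layer,
softmax output) trained with cross-entropy via Adam on minibatches.
Features are z-scored with statistics fitted on the training split only.
Training monitors log-loss on a held-out validation split and stops when
it has not improved for ``patience`` consecutive checks (one check per
pass over the training data); the best-validation weights are restored.

Class imbalance (NREM/wake dominate, REM is rare) is handled by random
oversampling with replacement of the minority classes in the training
split only, up to the majority-class count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from ratpsg.core import N_STATES, Hypnogram, ValidationError
from ratpsg.features import N_WINDOW_FEATURES, WINDOW_EPOCHS, WindowSample, window_matrix

CLASSES = np.arange(N_STATES)


@dataclass
class ClassifierConfig:
    input_size: int = N_WINDOW_FEATURES
    hidden_size: int = 512
    output_size: int = N_STATES
    split_fractions: tuple = (0.64, 0.16, 0.20)
    oversample: bool = True
    patience: int = 10
    max_iterations: int = 60
    learning_rate: float = 1e-3
    batch_size: int = 256
    min_improvement: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValidationError(f"split fractions must sum to 1: {self.split_fractions}")
        if min(self.input_size, self.hidden_size, self.output_size) <= 0:
            raise ValidationError("layer sizes must be positive")


@dataclass
class EvaluationReport:
    accuracy: float
    f1_per_class: np.ndarray
    macro_f1: float
    confusion: np.ndarray  # rows = true, cols = predicted
    n_test: int


@dataclass
class TrainedClassifier:
    """Weights, standardization constants and training history.

    Prediction is an explicit forward pass (ReLU then softmax) over the
    stored weights, so a deserialized model scores identically to the
    in-memory one.
    """

    w_hidden: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    config: ClassifierConfig
    history: dict = field(default_factory=dict)
    feature_settings: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.w_hidden.shape[0]:
            raise ValidationError(
                f"expected {self.w_hidden.shape[0]} features, got shape {X.shape}"
            )
        Z = (X - self.scaler_mean) / self.scaler_scale
        H = np.maximum(Z @ self.w_hidden + self.b_hidden, 0.0)
        logits = H @ self.w_out + self.b_out
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict_classes(self, X: np.ndarray) -> np.ndarray:
        # argmax takes the lowest class index on exact probability ties
        return self.predict_proba(X).argmax(axis=1).astype(np.int8)


def _round_split_sizes(n: int, fractions) -> tuple[int, int, int]:
    """Validation/test sizes round to nearest; the remainder goes to training."""
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValidationError(f"cannot split {n} samples into {fractions}")
    return n_train, n_val, n_test


def split_dataset(
    samples: list[WindowSample],
    fractions=(0.64, 0.16, 0.20),
    seed: int = 0,
) -> tuple[list[WindowSample], list[WindowSample], list[WindowSample]]:
    """Seeded, stratified train/validation/test partition.

    The split is exhaustive and disjoint. Within each class the allocation
    follows the same nearest-integer rule as the global one, so overall
    sizes match the fractions while class proportions are approximately
    preserved.
    """
    if len(samples) < WINDOW_EPOCHS:
        raise ValidationError(f"need at least {WINDOW_EPOCHS} samples, got {len(samples)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1: {fractions}")
    labels = np.array(
        [s.label if s.label is not None else -1 for s in samples], dtype=int
    )
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        _, n_val, n_test = _round_split_sizes(idx.size, fractions)
        val_idx.extend(idx[:n_val])
        test_idx.extend(idx[n_val : n_val + n_test])
        train_idx.extend(idx[n_val + n_test :])
    for name, part in (("train", train_idx), ("validation", val_idx), ("test", test_idx)):
        got = set(labels[part])
        for cls in np.unique(labels):
            if np.sum(labels == cls) >= 50 and cls not in got:
                raise ValidationError(
                    f"class {cls} (n={np.sum(labels == cls)}) missing from the "
                    f"{name} split; stratification failed"
                )
    pick = lambda idx: [samples[i] for i in sorted(idx)]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def oversample_training(
    train: list[WindowSample], seed: int = 0
) -> list[WindowSample]:
    """Random oversampling with replacement to the majority-class count.

    Only ever applied to the training split; validation and test data are
    the caller's responsibility to leave untouched.
    """
    labels = np.array([s.label for s in train], dtype=object)
    if any(l is None for l in labels):
        raise ValidationError("oversampling requires labeled samples")
    labels = labels.astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 1:
        raise ValidationError("every class must have at least one training sample")
    majority = counts.max()
    rng = np.random.default_rng(seed)
    out = list(train)
    for cls, cnt in zip(classes, counts):
        if cnt < majority:
            idx = np.flatnonzero(labels == cls)
            extra = rng.choice(idx, size=majority - cnt, replace=True)
            out.extend(train[i] for i in extra)
    return out


def train(
    train_samples: list[WindowSample],
    validation_samples: list[WindowSample],
    config: ClassifierConfig | None = None,
) -> TrainedClassifier:
    """Fit the MLP with validation-loss early stopping.

    One "iteration" is a full pass over the (shuffled) training minibatches
    followed by a validation log-loss check. Training stops after
    ``config.patience`` checks without an improvement of at least
    ``config.min_improvement``, or at ``config.max_iterations``; the
    weights of the best check are kept.
    """
    config = config if config is not None else ClassifierConfig()
    X_tr, y_tr, _ = window_matrix(train_samples)
    X_val, y_val, _ = window_matrix(validation_samples)
    if y_tr is None or y_val is None:
        raise ValidationError("training and validation samples must be labeled")
    if X_tr.shape[1] != config.input_size:
        raise ValidationError(
            f"config expects {config.input_size} features, samples have {X_tr.shape[1]}"
        )

    scaler = StandardScaler().fit(X_tr)
    scaler.scale_[scaler.scale_ == 0] = 1.0  # constant features pass through as 0
    Xs_tr = scaler.transform(X_tr).astype(np.float32)
    Xs_val = scaler.transform(X_val).astype(np.float32)

    mlp = MLPClassifier(
        hidden_layer_sizes=(config.hidden_size,),
        activation="relu",
        solver="adam",
        batch_size=min(config.batch_size, len(train_samples)),
        learning_rate_init=config.learning_rate,
        random_state=config.seed,
        max_iter=1,
        shuffle=True,
    )
    best_loss = np.inf
    best_weights = None
    stale = 0
    losses = []
    for it in range(config.max_iterations):
        mlp.partial_fit(Xs_tr, y_tr, classes=CLASSES)
        val_loss = log_loss(y_val, mlp.predict_proba(Xs_val), labels=CLASSES)
        if not np.isfinite(val_loss):
            raise RuntimeError(
                f"non-finite validation loss at iteration {it}; "
                f"history so far: {losses}"
            )
        losses.append(float(val_loss))
        if val_loss < best_loss - config.min_improvement:
            best_loss = val_loss
            best_weights = (
                [c.copy() for c in mlp.coefs_],
                [b.copy() for b in mlp.intercepts_],
            )
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_weights is None:  # never improved past the first check
        best_weights = (mlp.coefs_, mlp.intercepts_)
    coefs, intercepts = best_weights
    return TrainedClassifier(
        w_hidden=np.asarray(coefs[0], dtype=np.float64),
        b_hidden=np.asarray(intercepts[0], dtype=np.float64),
        w_out=np.asarray(coefs[1], dtype=np.float64),
        b_out=np.asarray(intercepts[1], dtype=np.float64),
        scaler_mean=scaler.mean_.astype(np.float64),
        scaler_scale=scaler.scale_.astype(np.float64),
        config=config,
        history={"val_loss": losses, "n_iterations": len(losses), "best_val_loss": float(best_loss)},
    )


def predict(
    model: TrainedClassifier,
    samples: list[WindowSample],
    n_epochs: int | None = None,
    start_zt: float = 0.0,
) -> Hypnogram:
    """Score windows and assemble a per-epoch hypnogram.

    Each epoch takes the label of the window centered on it; the first and
    last two epochs, which have no centered window, inherit the nearest
    window's label.
    """
    X, _, centers = window_matrix(samples)
    win_labels = model.predict_classes(X)
    if n_epochs is None:
        n_epochs = int(centers.max()) + WINDOW_EPOCHS // 2 + 1
    labels = np.empty(n_epochs, dtype=np.int8)
    order = np.argsort(centers)
    centers, win_labels = centers[order], win_labels[order]
    labels[centers] = win_labels
    labels[: centers[0]] = win_labels[0]
    labels[centers[-1] + 1 :] = win_labels[-1]
    return Hypnogram(labels=labels, start_zt=start_zt)


def evaluate(model: TrainedClassifier, test_samples: list[WindowSample]) -> EvaluationReport:
    """Accuracy, per-class and macro F1, and the 3x3 confusion matrix."""
    if not test_samples:
        raise ValidationError("test set is empty")
    X, y, _ = window_matrix(test_samples)
    if y is None:
        raise ValidationError("test samples must be labeled")
    pred = model.predict_classes(X)
    return EvaluationReport(
        accuracy=float(accuracy_score(y, pred)),
        f1_per_class=f1_score(y, pred, labels=CLASSES, average=None, zero_division=0.0),
        macro_f1=float(f1_score(y, pred, labels=CLASSES, average="macro", zero_division=0.0)),
        confusion=confusion_matrix(y, pred, labels=CLASSES),
        n_test=len(test_samples),
    )
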