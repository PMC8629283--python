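"""The optimal-punch classifier: an all-sigmoid multilayer perceptron.

Architecture 600 -> 512 -> 256 -> 128 -> 64 -> 2 with a sigmoid on every
layer (including the two-node best / not-best output head), per-node binary
cross-entropy loss, and Adam (learning_rate 0.001, beta_1 0.9, beta_2 0.999).
Implemented directly on NumPy with seeded Glorot-uniform initialization.

Class convention: output node 0 = "not best", node 1 = "best"; targets are
one-hot pairs.  The 5 % positive-class imbalance is handled by weighting
samples inversely to class frequency.  Inputs are standardized per feature
inside :func:`train` (the statistics are stored with the model); the punch
windows themselves remain raw sensor values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

DEFAULT_LAYER_SIZES = (600, 512, 256, 128, 64, 2)


@dataclass(frozen=True)
class MlpConfig:
    """Architecture and training hyperparameters of the best-punch model."""

    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    learning_rate: float = 0.001
    beta_1: float = 0.9
    beta_2: float = 0.999
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2 or any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be >=2 positive widths")
        if self.layer_sizes[-1] != 2:
            raise ValueError("output layer must have 2 nodes (best / not best)")
        if min(self.learning_rate, self.beta_1, self.beta_2) <= 0:
            raise ValueError("optimizer hyperparameters must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >=0 and batch_size >=1")


def parameter_count(layer_sizes) -> int:
    """Analytic trainable-parameter count: sum of n_in*n_out + n_out."""
    sizes = list(layer_sizes)
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainingHistory:
    losses: list[float] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)


@dataclass
class ClassificationScores:
    """Confusion counts and precision / recall / F1 for the best-punch class."""

    TP: int
    FP: int
    FN: int
    TN: int
    PR: float
    RC: float
    F1: float


class TrainedModel:
    """Weights, optimizer state and input scaler of the MLP."""

    def __init__(self, config: MlpConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        sizes = config.layer_sizes
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, (n_in, n_out)))
            self.biases.append(np.zeros(n_out))
        self.scaler_mean: np.ndarray | None = None
        self.scaler_std: np.ndarray | None = None
        self.trained = False

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size + b.size for w, b in zip(self.weights, self.biases)))

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.layer_sizes[0]:
            raise ValueError(
                f"input width {X.shape[1]} != model input layer "
                f"{self.config.layer_sizes[0]}"
            )
        return X

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            return X
        return (X - self.scaler_mean) / self.scaler_std

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Return activations of every layer (input first), sigmoid throughout."""
        acts = [X]
        for w, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ w + b))
        return acts

    def predict_proba(self, X) -> np.ndarray:
        """Two-node sigmoid outputs (not a softmax; rows need not sum to 1)."""
        X = self._scale(self._check_input(X))
        return self._forward(X)[-1]

    def predict(self, X) -> np.ndarray:
        """Predicted class per row: argmax over the two output nodes (1 = best)."""
        return np.argmax(self.predict_proba(X), axis=1)


def build_model(config: MlpConfig | None = None) -> TrainedModel:
    """Build an untrained MLP with seeded Glorot-uniform weights."""
    return TrainedModel(config or MlpConfig())


def _bce(p: np.ndarray, y: np.ndarray, sample_w: np.ndarray) -> float:
    eps = 1e-12
    per_sample = -np.mean(
        y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps), axis=1
    )
    return float(np.sum(sample_w * per_sample) / np.sum(sample_w))


def train(
    model: TrainedModel,
    X,
    y,
    config: MlpConfig | None = None,
) -> TrainingHistory:
    """Train the model with Adam on per-node binary cross-entropy.

    ``y`` holds two-class one-hot rows (column 1 = best punch).  Sample
    weights inversely proportional to class frequency counter the 5 %
    positive-class imbalance.  Returns per-epoch loss and accuracy on the
    training set; with ``epochs == 0`` the model is untouched and the
    history empty.
    """
    cfg = config or model.config
    X = model._check_input(X)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape != (X.shape[0], 2):
        raise ValueError("y must be n x 2 one-hot pairs")
    classes = np.argmax(y, axis=1)
    counts = np.bincount(classes, minlength=2)
    if np.any(counts == 0):
        raise ValueError("training data contains a single class; binary task undefined")

    history = TrainingHistory()
    if cfg.epochs == 0:
        return history

    if model.scaler_mean is None:
        model.scaler_mean = X.mean(axis=0)
        std = X.std(axis=0)
        model.scaler_std = np.where(std < 1e-12, 1.0, std)
    Xs = model._scale(X)

    n = X.shape[0]
    sample_w = (n / (2.0 * counts))[classes]
    batch = min(cfg.batch_size, n)
    if batch < cfg.batch_size:
        logger.debug("batch_size clipped to n=%d", n)

    rng = np.random.default_rng(cfg.seed + 1)
    # Adam state
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    step = 0
    eps = 1e-7

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch):
            idx = order[lo : lo + batch]
            xb, yb, wb = Xs[idx], y[idx], sample_w[idx]
            acts = model._forward(xb)
            p = acts[-1]
            # d(mean BCE)/dz at a sigmoid output is (p - y); weight and
            # normalize over batch and the 2 output nodes.
            delta = (p - yb) * wb[:, None] / (2.0 * np.sum(wb))
            grads_w, grads_b = [], []
            for layer in range(len(model.weights) - 1, -1, -1):
                a_prev = acts[layer]
                grads_w.append(a_prev.T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ model.weights[layer].T) * a_prev * (1 - a_prev)
            grads_w.reverse()
            grads_b.reverse()
            step += 1
            b1c = 1 - cfg.beta_1**step
            b2c = 1 - cfg.beta_2**step
            for i in range(len(model.weights)):
                for g, mm, vv, param in (
                    (grads_w[i], m_w[i], v_w[i], model.weights[i]),
                    (grads_b[i], m_b[i], v_b[i], model.biases[i]),
                ):
                    mm *= cfg.beta_1
                    mm += (1 - cfg.beta_1) * g
                    vv *= cfg.beta_2
                    vv += (1 - cfg.beta_2) * g * g
                    param -= cfg.learning_rate * (mm / b1c) / (np.sqrt(vv / b2c) + eps)
        p_full = model._forward(Xs)[-1]
        history.losses.append(_bce(p_full, y, sample_w))
        acc = float(np.mean(np.argmax(p_full, axis=1) == classes))
        history.accuracies.append(acc)
    model.trained = True
    return history


def scores_from_counts(TP: int, FP: int, FN: int, TN: int = 0) -> ClassificationScores:
    """Precision, recall and F1 from confusion counts.

    Degenerate conventions: PR (or RC) is 0 when its denominator is 0, and
    F1 is 0 when PR + RC is 0 (logged).
    """
    PR = TP / (TP + FP) if TP + FP > 0 else 0.0
    RC = TP / (TP + FN) if TP + FN > 0 else 0.0
    if PR + RC > 0:
        F1 = 2.0 * PR * RC / (PR + RC)
    else:
        logger.warning("PR + RC = 0; defining F1 = 0")
        F1 = 0.0
    return ClassificationScores(TP=TP, FP=FP, FN=FN, TN=TN, PR=PR, RC=RC, F1=F1)


def evaluate(model: TrainedModel, X, y_true) -> ClassificationScores:
    """Confusion counts and PR/RC/F1 of argmax predictions ('best' positive)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    truth = np.argmax(y_true, axis=1)
    pred = model.predict(X)
    TP = int(np.sum((pred == 1) & (truth == 1)))
    FP = int(np.sum((pred == 1) & (truth == 0)))
    FN = int(np.sum((pred == 0) & (truth == 1)))
    TN = int(np.sum((pred == 0) & (truth == 0)))
    return scores_from_counts(TP, FP, FN, TN)


@dataclass
class CvResult:
    """Per-fold losses/accuracies of the k-fold cross-validation protocol."""

    k: int
    fold_losses: list[float]
    fold_accuracies: list[float]
    fold_test_indices: list[np.ndarray]
    summary: dict[str, float]


def kfold_cv(X, y, k: int, config: MlpConfig | None = None, seed: int = 0) -> CvResult:
    """k-fold cross-validation exactly as the study protocol prescribes.

    The data are shuffled once (seeded) and split into k groups; each group
    in turn is the test set while a freshly initialized model is trained on
    the rest; the test loss and accuracy of every fold are recorded and
    summarized by mean and standard deviation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    cfg = config or MlpConfig()
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    losses, accs, test_idx = [], [], []
    for fold, (tr, te) in enumerate(splitter.split(X)):
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        model = build_model(fold_cfg)
        train(model, X[tr], y[tr], fold_cfg)
        p = model.predict_proba(X[te])
        truth = np.argmax(y[te], axis=1)
        w = np.ones(len(te))
        losses.append(_bce(p, y[te], w))
        accs.append(float(np.mean(np.argmax(p, axis=1) == truth)))
        test_idx.append(te)
    summary = {
        "loss_mean": float(np.mean(losses)),
        "loss_sd": float(np.std(losses)),
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_sd": float(np.std(accs)),
    }
    return CvResult(
        k=k,
        fold_losses=losses,
        fold_accuracies=accs,
        fold_test_indices=test_idx,
        summary=summary,
    )


def conformance_score(model: TrainedModel, window) -> float | np.ndarray:
    """Degree of coincidence of a punch with the optimal-punch model.

    The two sigmoid outputs are normalized against each other:
    ``score = s_best / (s_best + s_not_best)``, with 0.5 when both vanish.
    Accepts one window (returns a float) or a stack of windows.
    """
    if not model.trained:
        raise RuntimeError("conformance_score requires a trained model")
    w = np.asarray(window, dtype=float)
    single = w.ndim == 1
    p = model.predict_proba(w)
    s_not, s_best = p[:, 0], p[:, 1]
    total = s_not + s_best
    score = np.where(total > 0, s_best / np.where(total > 0, total, 1.0), 0.5)
    return float(score[0]) if single else score
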