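"""Reflux detection (SVM, balanced 10-fold CV) and severity grading (BPNN).

Metric conventions follow the study design: the *non-LPR* class is the
positive class, so sensitivity is the non-LPR recall and the false positive
rate counts LPR samples predicted as non-LPR.  Severity classes are derived
from the reflux symptom index (RSI): 13-20 primary, 21-30 intermediate,
31-45 severe.  The severity classifier is a 5-input, single-hidden-layer
(4 sigmoid units) back-propagation network trained by batch gradient
descent with momentum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InvalidInputError
from .phantom import LPR_LABEL, NON_LPR_LABEL

SEVERITY_CLASSES = ("primary", "intermediate", "severe")
SEVERITY_BINS = {"primary": (13, 20), "intermediate": (21, 30), "severe": (31, 45)}


@dataclass
class Metrics:
    """Confusion counts and derived percentages (positive = non-LPR)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / total if total else 0.0

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def false_positive_rate(self) -> float:
        denom = self.fp + self.tn
        return 100.0 * self.fp / denom if denom else 0.0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "false_positive_rate": self.false_positive_rate,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
        }


def balanced_subsample(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Indices of a 1:1 class-balanced subset (majority class downsampled).

    Sampling is without replacement and deterministic per seed; minority
    samples are all kept.  Index order follows the original array.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() == 0:
        raise InvalidInputError("both classes must be present")
    rng = np.random.default_rng(seed)
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def compute_metrics(
    predicted: np.ndarray,
    truth: np.ndarray,
    positive_label=NON_LPR_LABEL,
) -> Metrics:
    """Confusion metrics with the (unconventional) non-LPR positive class."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise InvalidInputError("prediction/truth length mismatch")
    pos_p = predicted == positive_label
    pos_t = truth == positive_label
    return Metrics(
        tp=int(np.sum(pos_p & pos_t)),
        tn=int(np.sum(~pos_p & ~pos_t)),
        fp=int(np.sum(pos_p & ~pos_t)),
        fn=int(np.sum(~pos_p & pos_t)),
    )


def _rbf_gamma(x: np.ndarray) -> float:
    """Median-pairwise-distance bandwidth heuristic: gamma = 1 / (2 m^2)."""
    n = len(x)
    if n > 200:  # subsample for the median; deterministic
        x = x[:: max(n // 200, 1)]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    med = np.median(d[np.triu_indices_from(d, k=1)])
    if med <= 0:
        return 1.0
    return float(1.0 / (2.0 * med**2))


def svm_cv(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[Metrics, list[Metrics]]:
    """Seeded stratified k-fold SVM evaluation.

    Features are standardized with training-fold statistics only; the RBF
    bandwidth uses the median pairwise distance of the training fold.
    Returns pooled confusion counts plus the per-fold metrics.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise InvalidInputError("two classes required")
    if counts.min() < k:
        raise InvalidInputError(f"need at least {k} samples per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[Metrics] = []
    total = Metrics(0, 0, 0, 0)
    for train_idx, test_idx in skf.split(features, labels):
        x_tr, x_te = features[train_idx], features[test_idx]
        mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0)
        sd[sd == 0] = 1.0
        x_tr = (x_tr - mu) / sd
        x_te = (x_te - mu) / sd
        clf = SVC(C=C, kernel="rbf", gamma=_rbf_gamma(x_tr))
        clf.fit(x_tr, labels[train_idx])
        m = compute_metrics(clf.predict(x_te), labels[test_idx])
        folds.append(m)
        total = Metrics(
            total.tp + m.tp, total.tn + m.tn, total.fp + m.fp, total.fn + m.fn
        )
    return total, folds


def rsi_to_severity(rsi: int) -> str:
    """Map an RSI score in [13, 45] to primary / intermediate / severe."""
    if not 13 <= rsi <= 45:
        raise InvalidInputError(f"RSI {rsi} outside the LPR range [13, 45]")
    for name, (lo, hi) in SEVERITY_BINS.items():
        if lo <= rsi <= hi:
            return name
    raise AssertionError("unreachable: bins partition [13, 45]")


@dataclass
class SeverityConfig:
    """BPNN architecture and training hyper-parameters."""

    hidden_units: int = 4
    epochs: int = 1000
    learning_rate: float = 0.65
    momentum: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise InvalidInputError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidInputError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise InvalidInputError("momentum must be in [0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class BpnnModel:
    """Trained fully connected sigmoid network with input standardization."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    classes: tuple
    mu: np.ndarray
    sd: np.ndarray
    loss_history: list[float] = field(default_factory=list, repr=False)

    def _forward(self, x: np.ndarray):
        h = _sigmoid(x @ self.w1 + self.b1)
        o = _sigmoid(h @ self.w2 + self.b2)
        return h, o

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = (np.asarray(features, dtype=np.float64) - self.mu) / self.sd
        _, o = self._forward(x)
        return np.asarray(self.classes)[o.argmax(axis=1)]


def bpnn_train(
    features: np.ndarray,
    class_labels: np.ndarray,
    config: SeverityConfig | None = None,
) -> BpnnModel:
    """Train the momentum back-propagation network on one-hot targets.

    Weights start uniform in [-0.5, 0.5] (seeded); training runs exactly
    ``config.epochs`` full-batch epochs minimizing mean squared error.
    """
    config = config or SeverityConfig()
    x = np.asarray(features, dtype=np.float64)
    labels = np.asarray(class_labels)
    classes = tuple(np.unique(labels))
    if len(classes) < 2:
        raise InvalidInputError("need at least 2 classes")
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    x = (x - mu) / sd
    t = np.zeros((len(labels), len(classes)))
    for i, cls in enumerate(classes):
        t[labels == cls, i] = 1.0

    rng = np.random.default_rng(config.seed)
    n_in, n_hid, n_out = x.shape[1], config.hidden_units, len(classes)
    w1 = rng.uniform(-0.5, 0.5, size=(n_in, n_hid))
    b1 = rng.uniform(-0.5, 0.5, size=n_hid)
    w2 = rng.uniform(-0.5, 0.5, size=(n_hid, n_out))
    b2 = rng.uniform(-0.5, 0.5, size=n_out)
    v = [np.zeros_like(w) for w in (w1, b1, w2, b2)]
    lr, mom = config.learning_rate, config.momentum
    n = len(x)
    history: list[float] = []

    for _ in range(config.epochs):
        h = _sigmoid(x @ w1 + b1)
        o = _sigmoid(h @ w2 + b2)
        err = o - t
        history.append(float((err**2).mean()))
        delta_o = err * o * (1 - o)
        delta_h = (delta_o @ w2.T) * h * (1 - h)
        grads = (
            x.T @ delta_h / n,
            delta_h.mean(axis=0),
            h.T @ delta_o / n,
            delta_o.mean(axis=0),
        )
        params = [w1, b1, w2, b2]
        for i, (p, g) in enumerate(zip(params, grads)):
            v[i] = mom * v[i] - lr * g
            p += v[i]

    return BpnnModel(
        w1=w1, b1=b1, w2=w2, b2=b2, classes=classes, mu=mu, sd=sd,
        loss_history=history,
    )


def stratified_cv(
    features: np.ndarray,
    class_labels: np.ndarray,
    config: SeverityConfig | None = None,
    k: int = 10,
) -> tuple[list[float], float]:
    """Stratified k-fold BPNN accuracies (percent) and their mean.

    If the rarest class has fewer than ``k`` members the fold count is
    reduced to that size (graceful degradation, documented behaviour).
    """
    config = config or SeverityConfig()
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(class_labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise InvalidInputError("every class needs at least 2 samples")
    k_eff = min(k, int(counts.min()))
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=config.seed)
    accs: list[float] = []
    for train_idx, test_idx in skf.split(features, labels):
        model = bpnn_train(features[train_idx], labels[train_idx], config)
        pred = model.predict(features[test_idx])
        accs.append(100.0 * float(np.mean(pred == labels[test_idx])))
    return accs, float(np.mean(accs))
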