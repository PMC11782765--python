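"""Training loop, splits, cross-validation, reduction curve and metrics.

The metric report derives eleven quantities from a 4x4 confusion matrix
(rows = true labels, columns = predicted labels) via one-vs-rest
TP/TN/FP/FN per class, then macro-averages them. Per-class values with
a zero denominator become NaN sentinels and are excluded from the macro
mean with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn.losses import get_loss
from .nn.optim import make_optimizer
from .occt import OCCT, OCCTConfig, build_occt
from .phantom import CLASSES


class EvalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _round_nearest(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SplitPlan:
    """Per-class train/test accounting plus seeded membership indices."""

    test_frac: float
    seed: int
    train_counts: dict[str, int]
    test_counts: dict[str, int]
    test_indices: dict[str, np.ndarray]  # per class, indices into 0..n_c-1

    @property
    def train_total(self) -> int:
        return sum(self.train_counts.values())

    @property
    def test_total(self) -> int:
        return sum(self.test_counts.values())


def stratified_split(class_counts: dict[str, int], test_frac: float = 0.3,
                     seed: int = 0) -> SplitPlan:
    """Per class: test count = round-to-nearest(frac * count), rest to train;
    membership drawn uniformly under the seed."""
    if not 0 < test_frac < 1:
        raise EvalError("test_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_counts, test_counts, test_indices = {}, {}, {}
    for label in class_counts:
        n = int(class_counts[label])
        if n < 1:
            raise EvalError(f"class {label} must have at least one image")
        n_test = _round_nearest(test_frac * n)
        perm = rng.permutation(n)
        test_indices[label] = np.sort(perm[:n_test])
        test_counts[label] = n_test
        train_counts[label] = n - n_test
    return SplitPlan(test_frac, seed, train_counts, test_counts, test_indices)


def split_arrays(X: np.ndarray, y: np.ndarray, test_frac: float = 0.3,
                 seed: int = 0):
    """Apply :func:`stratified_split` to labeled arrays.

    Returns (X_train, y_train, X_test, y_test)."""
    y = np.asarray(y)
    counts = {CLASSES[c]: int((y == c).sum()) for c in np.unique(y)}
    plan = stratified_split(counts, test_frac, seed)
    test_mask = np.zeros(len(y), dtype=bool)
    for label, idx in plan.test_indices.items():
        cls_positions = np.flatnonzero(y == CLASSES.index(label))
        test_mask[cls_positions[idx]] = True
    return X[~test_mask], y[~test_mask], X[test_mask], y[test_mask]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 0.001
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise EvalError("hyperparameters must be positive")


def prepare_inputs(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W) or (N, H, W, 3) -> float32 (N, 3, H, W) in [0, 1]."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    if x.ndim == 3:
        x = np.repeat(x[:, None], 3, axis=1)
    elif x.ndim == 4:
        x = x.transpose(0, 3, 1, 2)
    else:
        raise EvalError("expected (N, H, W) or (N, H, W, 3) images")
    return x


def one_hot(y: np.ndarray, n_classes: int = 4) -> np.ndarray:
    out = np.zeros((len(y), n_classes), dtype=np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


def train_classifier(model: OCCT, X: np.ndarray, y: np.ndarray,
                     cfg: TrainConfig = TrainConfig()) -> dict:
    """Fixed-epoch training; returns per-epoch loss/accuracy history.

    ``X``: float32 (N, 3, S, S) in [0, 1] (see :func:`prepare_inputs`);
    ``y``: integer labels. Final-epoch weights are kept (no best-epoch
    selection), matching a fixed-epoch protocol.
    """
    n = len(X)
    if n == 0:
        raise EvalError("empty training set")
    loss_fn = get_loss(cfg.loss)
    opt = make_optimizer(cfg.optimizer, model.parameters(), cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    onehot = one_hot(y, model.cfg.n_classes)
    history = {"loss": [], "accuracy": []}
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs = model.forward(X[idx])
            loss = loss_fn(probs, onehot[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            correct += int((probs.data.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(sum(losses) / n)
        history["accuracy"].append(correct / n)
    model.eval()
    return history


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix4:
    counts: np.ndarray  # (4, 4), rows = true, cols = predicted
    labels: tuple = CLASSES

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.labels),) * 2 or (c < 0).any():
            raise EvalError("confusion matrix must be KxK with counts >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)


def evaluate(model: OCCT, X: np.ndarray, y: np.ndarray) -> ConfusionMatrix4:
    """Tally argmax predictions into the true x predicted grid."""
    y = np.asarray(y)
    if len(X) != len(y):
        raise EvalError("every evaluated image needs a label")
    preds = model.predict(X)
    k = model.cfg.n_classes
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y, preds), 1)
    return ConfusionMatrix4(cm, CLASSES[:k])


_RATE_METRICS = ("precision", "recall", "f1", "specificity", "sensitivity",
                 "npv", "fpr", "fnr", "fdr", "mcc")


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    weighted: dict[str, float]

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "per_class": self.per_class,
                "macro": self.macro, "weighted": self.weighted}


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix4) -> MetricsReport:
    """One-vs-rest metric suite with macro (and weighted) averaging."""
    counts = np.asarray(cm.counts, dtype=np.float64)
    total = counts.sum()
    if total == 0:
        raise EvalError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    support = counts.sum(axis=1)
    for i, label in enumerate(cm.labels):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        specificity = _safe_div(tn, tn + fp)
        npv = _safe_div(tn, tn + fn)
        f1 = _safe_div(2 * precision * recall, precision + recall) \
            if np.isfinite(precision) and np.isfinite(recall) else float("nan")
        mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_div(tp * tn - fp * fn, mcc_den)
        per_class[label] = {
            "precision": precision, "recall": recall, "f1": f1,
            "specificity": specificity, "sensitivity": recall,
            "npv": npv,
            "fpr": 1.0 - specificity if np.isfinite(specificity) else float("nan"),
            "fnr": 1.0 - recall if np.isfinite(recall) else float("nan"),
            "fdr": 1.0 - precision if np.isfinite(precision) else float("nan"),
            "mcc": mcc,
        }
    macro, weighted = {}, {}
    for m in _RATE_METRICS:
        vals = np.array([per_class[lb][m] for lb in cm.labels])
        ok = np.isfinite(vals)
        if not ok.all():
            bad = [lb for lb, f in zip(cm.labels, ok) if not f]
            warnings.warn(f"metric {m!r} undefined for class(es) {bad}; "
                          f"excluded from the macro mean")
        macro[m] = float(vals[ok].mean()) if ok.any() else float("nan")
        w = support[ok]
        weighted[m] = float((vals[ok] * w).sum() / w.sum()) if ok.any() \
            else float("nan")
    return MetricsReport(accuracy=cm.accuracy, per_class=per_class,
                         macro=macro, weighted=weighted)


# ---------------------------------------------------------------------------
# K-fold cross-validation
# ---------------------------------------------------------------------------

def stratified_fold_indices(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint, exhaustive, stratified folds (per-class counts differ by <= 1)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    offset = 0  # rotates so per-class remainders spread over all folds
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        base, extra = divmod(len(idx), k)
        pos = 0
        for f in range(k):
            size = base + (1 if f < extra else 0)
            folds[(f + offset) % k].extend(idx[pos:pos + size])
            pos += size
        offset = (offset + extra) % k
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def kfold_cv(model_cfg: OCCTConfig, train_cfg: TrainConfig, X: np.ndarray,
             y: np.ndarray, k: int = 10, seed: int = 0) -> list[float]:
    """Train a fresh model per fold; return the k held-out accuracies."""
    if k < 2:
        raise EvalError("k must be >= 2")
    if len(X) < k:
        raise EvalError("dataset smaller than k")
    folds = stratified_fold_indices(y, k, seed)
    accuracies = []
    for f, test_idx in enumerate(folds):
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        model = build_occt(model_cfg, seed=seed + f)
        train_classifier(model, X[~mask], y[~mask], train_cfg)
        accuracies.append(evaluate(model, X[mask], y[mask]).accuracy)
    return accuracies


# ---------------------------------------------------------------------------
# Reduction-curve experiment
# ---------------------------------------------------------------------------

def reduction_sizes(start: int, factor: float = 0.75, steps: int = 13) -> list[int]:
    """size_{i+1} = round(factor * size_i); step 1 is the full dataset."""
    sizes = [int(start)]
    for _ in range(steps - 1):
        sizes.append(_round_nearest(factor * sizes[-1]))
    return sizes


def _allocate_per_class(class_sizes: np.ndarray, target: int) -> np.ndarray:
    """Proportional allocation (largest remainder) summing exactly to target."""
    quota = class_sizes * (target / class_sizes.sum())
    alloc = np.floor(quota).astype(int)
    remainder = target - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:remainder]] += 1
    return np.minimum(alloc, class_sizes)


def reduction_curve(model_cfg: OCCTConfig, train_cfg: TrainConfig,
                    X: np.ndarray, y: np.ndarray, factor: float = 0.75,
                    steps: int = 13, seed: int = 0,
                    test_frac: float = 0.3) -> tuple[list[int], list[float]]:
    """Repeatedly shrink the dataset and retrain from scratch.

    Subsamples are stratified and nested (each step's images are a subset
    of the previous step's). Returns (sizes, accuracies). The schedule is
    truncated with a warning once a step cannot fill one training batch.
    """
    y = np.asarray(y)
    sizes = reduction_sizes(len(y), factor, steps)
    rng = np.random.default_rng(seed)
    # nested subsets: shuffle within class once, then take prefixes
    class_order = {c: rng.permutation(np.flatnonzero(y == c))
                   for c in np.unique(y)}
    class_labels = sorted(class_order)
    accuracies, used_sizes = [], []
    for step, size in enumerate(sizes):
        if size * (1 - test_frac) < train_cfg.batch_size:
            warnings.warn(f"truncating reduction schedule at step {step + 1}: "
                          f"size {size} cannot fill one batch")
            break
        counts = np.array([len(class_order[c]) for c in class_labels])
        alloc = _allocate_per_class(counts, size)
        keep = np.concatenate([class_order[c][:a]
                               for c, a in zip(class_labels, alloc)])
        Xs, ys = X[keep], y[keep]
        Xtr, ytr, Xte, yte = split_arrays(Xs, ys, test_frac, seed + step)
        model = build_occt(model_cfg, seed=seed + step)
        train_classifier(model, Xtr, ytr, train_cfg)
        accuracies.append(evaluate(model, Xte, yte).accuracy)
        used_sizes.append(size)
    return used_sizes, accuracies
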