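import numpy as np
import pytest

from occtkit.occt import OCCTConfig, build_occt
from occtkit.traineval import (ConfusionMatrix4, EvalError, TrainConfig,
                               compute_metrics, evaluate, kfold_cv, one_hot,
                               prepare_inputs, reduction_curve,
                               reduction_sizes, split_arrays,
                               stratified_fold_indices, stratified_split,
                               train_classifier)

PAPER_COUNTS = {"CNV": 37_206, "DME": 11_349, "DRUSEN": 8_617,
                "NORMAL": 51_140}

# a deliberately tiny-but-trainable configuration for harness tests
TINY_TRAIN = TrainConfig(epochs=1, batch_size=32, seed=0)


def tiny_dataset(rng, n_per_class=12, side=32):
    """Linearly separable fake image classes (distinct mean intensities)."""
    X, y = [], []
    for c in range(4):
        base = 0.2 * c + 0.1
        X.append(rng.normal(base, 0.03, (n_per_class, 3, side, side)))
        y.extend([c] * n_per_class)
    return (np.concatenate(X).astype(np.float32).clip(0, 1),
            np.asarray(y, dtype=np.int64))


class TestStratifiedSplit:
    def test_published_class_counts(self):
        plan = stratified_split(PAPER_COUNTS, test_frac=0.3, seed=0)
        assert plan.test_counts == {"CNV": 11_162, "DME": 3_405,
                                    "DRUSEN": 2_585, "NORMAL": 15_342}
        assert plan.test_total == 32_494
        assert plan.train_total + plan.test_total == sum(PAPER_COUNTS.values())

    def test_small_count_rounding(self):
        plan = stratified_split({"CNV": 10}, test_frac=0.3, seed=1)
        assert plan.test_counts["CNV"] == 3
        assert plan.train_counts["CNV"] == 7

    def test_deterministic_membership(self):
        p1 = stratified_split(PAPER_COUNTS, 0.3, seed=7)
        p2 = stratified_split(PAPER_COUNTS, 0.3, seed=7)
        for label in PAPER_COUNTS:
            np.testing.assert_array_equal(p1.test_indices[label],
                                          p2.test_indices[label])

    def test_invalid_fraction_rejected(self):
        for frac in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(EvalError, match="test_frac"):
                stratified_split({"CNV": 10}, frac, 0)

    def test_split_arrays_partition(self, rng):
        X, y = tiny_dataset(rng, n_per_class=10, side=8)
        Xtr, ytr, Xte, yte = split_arrays(X, y, 0.3, seed=2)
        assert len(Xtr) + len(Xte) == len(X)
        assert len(yte) == 12  # 3 per class
        for c in range(4):
            assert (yte == c).sum() == 3


class TestTrainClassifier:
    def test_history_length(self, rng):
        X, y = tiny_dataset(rng, n_per_class=8)
        model = build_occt(seed=0)
        hist = train_classifier(model, X, y,
                                TrainConfig(epochs=2, batch_size=32, seed=0))
        assert len(hist["loss"]) == 2
        assert len(hist["accuracy"]) == 2

    def test_loss_decreases_on_separable_toy(self, rng):
        X, y = tiny_dataset(rng, n_per_class=8)
        model = build_occt(OCCTConfig(dropout=0.0), seed=0)
        hist = train_classifier(model, X, y,
                                TrainConfig(epochs=6, batch_size=32, seed=0))
        assert hist["loss"][-1] < hist["loss"][0]

    def test_empty_training_set_rejected(self):
        model = build_occt(seed=0)
        with pytest.raises(EvalError, match="empty"):
            train_classifier(model, np.zeros((0, 3, 32, 32), np.float32),
                             np.zeros(0, np.int64), TINY_TRAIN)

    def test_seeded_rerun_identical(self, rng):
        X, y = tiny_dataset(rng, n_per_class=8)
        h1 = train_classifier(build_occt(seed=3), X, y, TINY_TRAIN)
        h2 = train_classifier(build_occt(seed=3), X, y, TINY_TRAIN)
        assert h1 == h2

    def test_prepare_inputs_shapes(self, rng):
        gray = rng.integers(0, 256, (5, 16, 16)).astype(np.uint8)
        x = prepare_inputs(gray)
        assert x.shape == (5, 3, 16, 16)
        assert 0 <= x.min() and x.max() <= 1
        rgb = rng.integers(0, 256, (5, 16, 16, 3)).astype(np.uint8)
        assert prepare_inputs(rgb).shape == (5, 3, 16, 16)

    def test_one_hot(self):
        oh = one_hot(np.array([0, 2]), 4)
        np.testing.assert_array_equal(oh, [[1, 0, 0, 0], [0, 0, 1, 0]])


class _OraclePredictor:
    """Stand-in with the same ``predict``/``cfg`` surface as the model."""

    class cfg:
        n_classes = 4

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        return self.fn(X)


class TestEvaluate:
    def test_perfect_predictor_diagonal(self, rng):
        X, y = tiny_dataset(rng, n_per_class=5, side=8)
        model = _OraclePredictor(lambda X_: y)
        cm = evaluate(model, X, y)
        assert (cm.counts == np.diag([5, 5, 5, 5])).all()

    def test_constant_predictor_single_column(self, rng):
        X, y = tiny_dataset(rng, n_per_class=5, side=8)
        model = _OraclePredictor(lambda X_: np.zeros(len(X_), np.int64))
        cm = evaluate(model, X, y)
        assert (cm.counts[:, 1:] == 0).all()
        assert (cm.counts[:, 0] == 5).all()

    def test_total_equals_test_size(self, rng):
        X, y = tiny_dataset(rng, n_per_class=6, side=8)
        model = _OraclePredictor(
            lambda X_: np.asarray(rng.integers(0, 4, len(X_))))
        assert evaluate(model, X, y).total == len(y)


def brute_force_metrics(counts):
    """Independent loop-based one-vs-rest metric computation."""
    counts = np.asarray(counts, float)
    k = counts.shape[0]
    out = {}
    for c in range(k):
        tp = counts[c, c]
        fn = sum(counts[c, j] for j in range(k) if j != c)
        fp = sum(counts[i, c] for i in range(k) if i != c)
        tn = counts.sum() - tp - fn - fp
        div = lambda a, b: a / b if b > 0 else float("nan")
        pre = div(tp, tp + fp)
        rec = div(tp, tp + fn)
        spe = div(tn, tn + fp)
        out[c] = {
            "precision": pre, "recall": rec,
            "f1": div(2 * pre * rec, pre + rec),
            "specificity": spe, "sensitivity": rec,
            "npv": div(tn, tn + fn), "fpr": div(fp, fp + tn),
            "fnr": div(fn, fn + tp), "fdr": div(fp, fp + tp),
            "mcc": div(tp * tn - fp * fn,
                       np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))),
        }
    return out


class TestComputeMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix4(np.diag([10, 10, 10, 10]))
        rep = compute_metrics(cm)
        assert rep.accuracy == 1.0
        for m in ("fpr", "fnr", "fdr"):
            assert rep.macro[m] == 0.0
        assert rep.macro["mcc"] == 1.0

    def test_single_error_hand_tally(self):
        counts = np.diag([9, 10, 10, 10])
        counts[0, 1] = 1  # one CNV predicted as DME
        rep = compute_metrics(ConfusionMatrix4(counts))
        assert rep.accuracy == pytest.approx(39 / 40)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, (4, 4))
            counts[np.diag_indices(4)] += 1  # avoid degenerate zero rows
            rep = compute_metrics(ConfusionMatrix4(counts))
            ref = brute_force_metrics(counts)
            for ci, label in enumerate(("CNV", "DME", "DRUSEN", "NORMAL")):
                for m, v in ref[ci].items():
                    got = rep.per_class[label][m]
                    if np.isnan(v):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(v, abs=1e-9)

    def test_metric_identities_exact(self, rng):
        counts = rng.integers(1, 40, (4, 4))
        rep = compute_metrics(ConfusionMatrix4(counts))
        for label, mm in rep.per_class.items():
            assert mm["fpr"] + mm["specificity"] == pytest.approx(1.0, abs=0)
            assert mm["fdr"] + mm["precision"] == pytest.approx(1.0, abs=0)
            assert mm["fnr"] + mm["sensitivity"] == pytest.approx(1.0, abs=0)

    def test_zero_denominator_sentinel_and_warning(self):
        counts = np.zeros((4, 4), int)
        counts[0, 0] = 5
        counts[1, 0] = 3  # nothing ever predicted as DRUSEN/NORMAL
        with pytest.warns(UserWarning, match="undefined"):
            rep = compute_metrics(ConfusionMatrix4(counts))
        assert np.isnan(rep.per_class["DRUSEN"]["precision"])
        assert np.isfinite(rep.macro["precision"])

    def test_negative_counts_rejected(self):
        with pytest.raises(EvalError):
            ConfusionMatrix4(np.full((4, 4), -1))


class TestKFold:
    def test_fold_geometry_and_partition(self, rng):
        y = np.repeat([0, 1, 2, 3], 25)
        folds = stratified_fold_indices(y, 10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 10 for f in folds)
        joined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(joined, np.arange(100))

    def test_folds_stratify_within_one(self, rng):
        y = rng.integers(0, 4, 103)
        folds = stratified_fold_indices(y, 5, seed=1)
        for c in range(4):
            per_fold = [np.sum(y[f] == c) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1

    def test_seeded_fold_assignment_stable(self):
        y = np.repeat([0, 1, 2, 3], 10)
        f1 = stratified_fold_indices(y, 4, seed=9)
        f2 = stratified_fold_indices(y, 4, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_kfold_cv_runs_and_validates(self, rng):
        X, y = tiny_dataset(rng, n_per_class=10, side=32)
        accs = kfold_cv(OCCTConfig(), TINY_TRAIN, X, y, k=4, seed=0)
        assert len(accs) == 4
        assert all(0.0 <= a <= 1.0 for a in accs)

    def test_small_k_rejected(self, rng):
        X, y = tiny_dataset(rng, n_per_class=3, side=8)
        with pytest.raises(EvalError, match="k must be"):
            kfold_cv(OCCTConfig(), TINY_TRAIN, X, y, k=1)


class TestReduction:
    def test_published_second_step(self):
        assert reduction_sizes(130_649, 0.75, 2) == [130_649, 97_987]

    def test_round_to_nearest_recursion(self):
        assert reduction_sizes(1_000, 0.75, 3) == [1_000, 750, 563]

    def test_factor_one_constant(self):
        assert reduction_sizes(500, 1.0, 4) == [500] * 4

    def test_thirteen_step_schedule_monotone(self):
        sizes = reduction_sizes(130_649, 0.75, 13)
        assert len(sizes) == 13
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 4_139  # matches the published endpoint

    def test_curve_runs_with_truncation(self, rng):
        X, y = tiny_dataset(rng, n_per_class=20, side=32)
        cfg = TrainConfig(epochs=1, batch_size=16, seed=0)
        with pytest.warns(UserWarning, match="truncating"):
            sizes, accs = reduction_curve(OCCTConfig(), cfg, X, y,
                                          factor=0.5, steps=5, seed=0)
        assert len(sizes) == len(accs) < 5
        assert sizes[0] == len(y)
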