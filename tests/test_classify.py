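import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from histodense import classify as clf, nnet


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

def test_scnn_layer_inventory_and_output_contract():
    model = clf.build_scnn(clf.SCNNConfig(width_scale=0.25, seed=0), input_hw=(32, 32))
    kinds = [type(l).__name__ for l in model.layers]
    assert kinds.count("Conv2D") == 6
    assert kinds.count("MaxPool2D") == 3
    assert kinds.count("BatchNorm2D") == 2
    assert kinds.count("Dropout") == 3
    x = np.random.default_rng(0).random((3, 32, 32, 3))
    proba = clf.predict_proba(model, x)
    assert proba.shape == (3, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)


def test_dcnn_layer_inventory():
    model = clf.build_dcnn(clf.DCNNConfig(width_scale=0.25, seed=0), input_hw=(64, 64))
    kinds = [type(l).__name__ for l in model.layers]
    assert kinds.count("DepthwiseConv2D") == 13
    pointwise = [l for l in model.layers if type(l).__name__ == "Conv2D" and l.k == 1]
    assert len(pointwise) == 13
    assert kinds.count("BatchNorm2D") == 26
    assert kinds.count("ReLU") == 27
    assert kinds.count("ZeroPad2D") == 4


def test_dcnn_width_scale_shrinks_parameters():
    full = clf.build_dcnn(clf.DCNNConfig(seed=0), input_hw=(64, 64))
    quarter = clf.build_dcnn(clf.DCNNConfig(width_scale=0.25, seed=0), input_hw=(64, 64))
    assert quarter.n_params() < full.n_params()


def test_dcnn_requires_13_blocks():
    with pytest.raises(ValueError):
        clf.DCNNConfig(block_channels=(64, 128))


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------

def test_lr_schedule_reference_points():
    assert clf.lr_schedule(0, 1e-4, 0.8, 1e-8) == 1e-4
    assert clf.lr_schedule(2, 1e-4, 0.8, 1e-8) == pytest.approx(6.4e-5)
    assert clf.lr_schedule(1000, 1e-4, 0.8, 1e-8) == 1e-8


def test_lr_schedule_monotone_and_floored():
    lrs = [clf.lr_schedule(e, 1e-3, 0.8, 1e-7) for e in range(100)]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))
    assert min(lrs) == 1e-7


def test_lr_schedule_rejects_bad_decay():
    with pytest.raises(ValueError):
        clf.lr_schedule(1, 1e-3, 1.5, 1e-8)


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

def test_reference_confusion_cell_gives_099_precision_recall():
    report = clf.metrics_from_confusion(clf.ConfusionMatrix(tp=415, tn=416, fp=4, fn=4))
    assert round(report.precision, 2) == 0.99
    assert round(report.recall, 2) == 0.99


def test_perfect_two_sample_confusion():
    r = clf.metrics_from_confusion(clf.ConfusionMatrix(tp=1, tn=1, fp=0, fn=0))
    assert (r.precision, r.recall, r.f1, r.accuracy, r.specificity, r.auc_eq15) == (
        1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
    )


def test_hand_evaluated_confusion():
    r = clf.metrics_from_confusion(clf.ConfusionMatrix(tp=50, tn=90, fp=10, fn=50))
    assert r.precision == pytest.approx(50 / 60)
    assert r.recall == pytest.approx(0.5)
    assert r.f1 == pytest.approx(0.625)
    assert r.auc_eq15 == pytest.approx(0.7)
    assert r.accuracy == pytest.approx(140 / 200)
    assert r.specificity == pytest.approx(0.9)


def test_zero_denominators_reported_as_undefined():
    r = clf.metrics_from_confusion(clf.ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
    assert r.precision is None and r.recall is None
    assert "precision" in r.undefined and "recall" in r.undefined
    assert r.specificity == 1.0


def test_literal_debug_specificity_available_behind_flag():
    r = clf.metrics_from_confusion(
        clf.ConfusionMatrix(tp=8, tn=2, fp=2, fn=2), debug_literal_specificity=True
    )
    assert r.specificity == pytest.approx(0.5)  # standard TN/(TN+FP)
    assert r.specificity_literal_debug == pytest.approx(2.0)  # TP/(FP+FN)


def test_metrics_agree_with_sklearn_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.integers(0, 2, 60)
        p = rng.integers(0, 2, 60)
        cm = clf.confusion_from_predictions(y, p)
        r = clf.metrics_from_confusion(cm)
        if r.precision is not None:
            assert r.precision == pytest.approx(precision_score(y, p, zero_division=np.nan))
        if r.recall is not None:
            assert r.recall == pytest.approx(recall_score(y, p, zero_division=np.nan))


def test_f1_is_harmonic_mean_of_reported_precision_recall():
    rng = np.random.default_rng(1)
    for _ in range(50):
        tp, tn, fp, fn = rng.integers(1, 200, 4)
        r = clf.metrics_from_confusion(clf.ConfusionMatrix(int(tp), int(tn), int(fp), int(fn)))
        assert abs(r.f1 - 2 * r.precision * r.recall / (r.precision + r.recall)) < 1e-12


# ---------------------------------------------------------------------------
# ROC AUC
# ---------------------------------------------------------------------------

def pairwise_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_auc_reference_cases():
    assert clf.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert clf.roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
    assert clf.roc_auc([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0]) == 0.75


def test_roc_auc_one_class_rejected():
    with pytest.raises(ValueError):
        clf.roc_auc([0.1, 0.9], [1, 1])


def test_roc_auc_matches_pairwise_enumeration_and_sklearn():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n = rng.integers(4, 50)
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        ours = clf.roc_auc(scores, labels)
        assert ours == pytest.approx(pairwise_auc(scores, labels))
        assert ours == pytest.approx(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Training loop and evaluation plumbing
# ---------------------------------------------------------------------------

class _FixedModel:
    """Duck-typed stand-in emitting preset logits (for evaluation plumbing)."""

    def __init__(self, fn):
        self.fn = fn

    def forward(self, x, training=False):
        return self.fn(x)


def test_oracle_model_scores_all_ones():
    x = np.random.default_rng(3).random((10, 4, 4, 3))
    y = np.arange(10) % 2
    model = _FixedModel(lambda b: np.stack([1.0 - 10 * (np.arange(len(b)) % 2), 10.0 * (np.arange(len(b)) % 2)], axis=1))
    # feed samples in original order so the preset logits match labels
    r = clf.evaluate(model, x, y)
    assert (r.precision, r.recall, r.accuracy) == (1.0, 1.0, 1.0)


def test_constant_positive_model_recall_one_specificity_zero():
    x = np.zeros((8, 2, 2, 3))
    y = np.array([0, 1] * 4)
    model = _FixedModel(lambda b: np.tile([0.0, 5.0], (len(b), 1)))
    r = clf.evaluate(model, x, y)
    assert r.recall == 1.0 and r.specificity == 0.0


def test_evaluate_empty_split_rejected():
    with pytest.raises(ValueError):
        clf.evaluate(_FixedModel(lambda b: b), np.zeros((0, 2, 2, 3)), np.zeros(0))


def _tiny_training_setup(seed=0):
    rng = np.random.default_rng(seed)
    # separable 8x8 images: class 1 is brighter
    x0 = rng.random((20, 8, 8, 3)) * 0.4
    x1 = rng.random((20, 8, 8, 3)) * 0.4 + 0.5
    x = np.concatenate([x0, x1])
    y = np.array([0] * 20 + [1] * 20)
    cfg = clf.SCNNConfig(width_scale=0.1, initial_lr=1e-3, decay=0.9, epochs=3, batch_size=8, seed=seed)
    return x, y, cfg


def test_single_class_training_rejected():
    x, y, cfg = _tiny_training_setup()
    model = clf.build_scnn(cfg, input_hw=(8, 8))
    with pytest.raises(ValueError):
        clf.train_classifier(model, x[:20], y[:20], x, y, cfg)


def test_patience_zero_stops_at_first_non_improving_epoch():
    x, y, cfg = _tiny_training_setup()
    cfg = clf.SCNNConfig(
        width_scale=0.1, initial_lr=1e-9, lr_floor=1e-12, decay=0.9, epochs=10,
        batch_size=8, early_stopping_min_delta=10.0, early_stopping_patience=0, seed=0,
    )
    model = clf.build_scnn(cfg, input_hw=(8, 8))
    history = clf.train_classifier(model, x, y, x, y, cfg)
    assert len(history) == 2  # epoch 0 trivially improves from +inf, epoch 1 cannot


def test_training_history_deterministic_given_seed():
    x, y, cfg = _tiny_training_setup()
    m1 = clf.build_scnn(cfg, input_hw=(8, 8))
    h1 = clf.train_classifier(m1, x, y, x, y, cfg)
    m2 = clf.build_scnn(cfg, input_hw=(8, 8))
    h2 = clf.train_classifier(m2, x, y, x, y, cfg)
    assert h1 == h2
    assert all(np.array_equal(p, q) for p, q in zip(m1.params, m2.params))


def test_history_records_scheduled_lr():
    x, y, cfg = _tiny_training_setup()
    model = clf.build_scnn(cfg, input_hw=(8, 8))
    history = clf.train_classifier(model, x, y, x, y, cfg)
    for row in history:
        assert row["lr"] == clf.lr_schedule(row["epoch"], cfg.initial_lr, cfg.decay, cfg.lr_floor)
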