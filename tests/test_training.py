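"""Training protocol: hybrid loss arithmetic, augmentation policy,
preprocessing, TTA, schedule and loop determinism."""

import numpy as np
import pytest

from egunet._tensor import Tensor
from egunet.backbone import BackboneConfig
from egunet.errors import ConfigError, ShapeError
from egunet.model import ModelConfig, SegmentationNet
from egunet.optim import cosine_lr
from egunet.synthetic import SegmentationSample, SyntheticSpec, make_dataset
from egunet.training import (AugmentPolicy, TrainConfig, augment, hybrid_loss,
                             preprocess, train, tta_predict)


# -- hybrid loss -------------------------------------------------------------

def test_cross_entropy_component_matches_hand_computation():
    """alpha=1, beta=0 on a 2x2 single-pixel-per-class example, against
    manual log-softmax arithmetic."""
    logits = np.array([[[[1.0, -0.5], [0.2, 0.0]],
                        [[0.3, 1.5], [-1.0, 0.0]]]])  # [1,2,2,2]
    labels = np.array([[[0, 1], [1, 0]]])
    z = logits[0]
    lse = np.log(np.exp(z[0]) + np.exp(z[1]))
    logp0, logp1 = z[0] - lse, z[1] - lse
    expected = -(logp0[0, 0] + logp1[0, 1] + logp1[1, 0] + logp0[1, 1]) / 4
    loss = hybrid_loss(Tensor(logits), labels, alpha=1.0, beta=0.0)
    assert float(loss.data) == pytest.approx(expected, rel=1e-6)


def test_hybrid_is_linear_combination(rng):
    logits = Tensor(rng.normal(size=(2, 3, 4, 4)))
    labels = rng.integers(0, 3, size=(2, 4, 4))
    ce = float(hybrid_loss(logits, labels, 1.0, 0.0).data)
    dice = float(hybrid_loss(logits, labels, 0.0, 1.0).data)
    both = float(hybrid_loss(logits, labels, 0.5, 0.5).data)
    assert both == pytest.approx(0.5 * (ce + dice), rel=1e-6)


def test_loss_vanishes_for_confident_correct_prediction(rng):
    labels = rng.integers(0, 3, size=(1, 6, 6))
    logits = np.full((1, 3, 6, 6), -50.0)
    np.put_along_axis(logits, labels[:, None], 50.0, axis=1)
    loss = float(hybrid_loss(Tensor(logits), labels, 0.5, 0.5).data)
    assert 0.0 <= loss < 1e-4


def test_loss_nonnegative_random(rng):
    for _ in range(10):
        logits = Tensor(rng.normal(scale=3, size=(2, 4, 5, 5)))
        labels = rng.integers(0, 4, size=(2, 5, 5))
        assert float(hybrid_loss(logits, labels).data) >= 0.0


def test_out_of_range_label_rejected(rng):
    logits = Tensor(rng.normal(size=(1, 3, 4, 4)))
    labels = np.full((1, 4, 4), 3)
    with pytest.raises(ValueError):
        hybrid_loss(logits, labels)


# -- augmentation ------------------------------------------------------------

def _coord_sample(rng):
    lab = rng.integers(0, 4, size=(16, 16))
    return SegmentationSample(lab[None].astype(np.float32), lab.copy())


def test_rightangle_branch_preserves_class_counts():
    rng = np.random.default_rng(0)
    policy = AugmentPolicy()
    found = 0
    for _ in range(40):
        s = _coord_sample(rng)
        out = augment(s, policy, rng)
        if out.meta["augment"] == "rightangle":
            found += 1
            for k in range(4):
                assert (out.label == k).sum() == (s.label == k).sum()
    assert found > 5


def test_geometry_identical_for_image_and_label():
    """The image encodes its own labels, so any exact (right-angle or
    identity) transform must keep image == label elementwise."""
    rng = np.random.default_rng(1)
    policy = AugmentPolicy()
    for _ in range(40):
        s = _coord_sample(rng)
        out = augment(s, policy, rng)
        if out.meta["augment"] in ("rightangle", "identity"):
            np.testing.assert_array_equal(out.image[0].astype(int), out.label)
        else:  # continuous rotation: nearest label keeps the class vocabulary
            assert set(np.unique(out.label)) <= set(np.unique(s.label))
            assert out.image.shape == s.image.shape


def test_augment_deterministic_given_seed():
    s = _coord_sample(np.random.default_rng(2))
    a = augment(s, AugmentPolicy(), np.random.default_rng(77))
    b = augment(s, AugmentPolicy(), np.random.default_rng(77))
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.label, b.label)
    assert a.meta["augment"] == b.meta["augment"]


def test_branch_frequencies_within_binomial_bounds():
    """10^4 draws: P(rightangle) = 0.5, P(small rotation) = 0.5*0.25 = 0.125,
    P(identity) = 0.375, each within 3 sigma."""
    rng = np.random.default_rng(123)
    policy = AugmentPolicy()
    s = _coord_sample(np.random.default_rng(3))
    n = 10_000
    counts = {"rightangle": 0, "small_rotation": 0, "identity": 0}
    for _ in range(n):
        counts[augment(s, policy, rng).meta["augment"]] += 1
    for branch, p in (("rightangle", 0.5), ("small_rotation", 0.125),
                      ("identity", 0.375)):
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts[branch] - n * p) <= 3 * sigma, (branch, counts)


# -- preprocessing -----------------------------------------------------------

def test_label_resize_never_invents_classes(rng):
    lab = rng.integers(0, 4, size=(3, 20, 20))
    vol = lab.astype(float)
    out = preprocess(vol, lab, target_size=48, image_interp="bicubic")
    for s in out:
        assert set(np.unique(s.label)) <= set(np.unique(lab))
        assert s.label.shape == (48, 48)


def test_constant_image_stays_constant():
    vol = np.full((2, 10, 10), 0.7)
    lab = np.zeros((2, 10, 10), int)
    for interp in ("bicubic", "nearest"):
        out = preprocess(vol, lab, target_size=32, image_interp=interp)
        np.testing.assert_allclose(out[0].image, 0.7, atol=1e-6)


def test_checkerboard_nearest_upsample_exact_blocks():
    board = np.array([[0, 1], [2, 3]])
    out = preprocess(board.astype(float)[None], board[None], target_size=4,
                     image_interp="nearest")
    expected = np.repeat(np.repeat(board, 2, axis=0), 2, axis=1)
    np.testing.assert_array_equal(out[0].label, expected)
    np.testing.assert_array_equal(out[0].image[0].astype(int), expected)


def test_preprocess_mode_selection_and_errors(rng):
    vol = rng.random((1, 8, 8))
    lab = np.zeros((1, 8, 8), int)
    assert preprocess(vol, lab, 16, dataset_mode="cardiac-mr")[0].image.shape == (1, 16, 16)
    with pytest.raises(ConfigError):
        preprocess(vol, lab, 16, dataset_mode="pet")
    with pytest.raises(ShapeError):
        preprocess(vol, np.zeros((2, 8, 8), int), 16)


# -- TTA ---------------------------------------------------------------------

class _CountingStub:
    """Stand-in model whose output ignores the input (fully symmetric)."""

    def __init__(self, k=3):
        self.calls = 0
        self.k = k

    def predict_proba(self, x):
        self.calls += 1
        n, _, h, w = np.asarray(x).shape
        p = np.full((n, self.k, h, w), 1.0 / self.k)
        return p


def test_tta_pass_counts():
    stub = _CountingStub()
    tta_predict(stub, np.zeros((1, 1, 8, 8), np.float32), mode="flip")
    assert stub.calls == 2
    stub = _CountingStub()
    tta_predict(stub, np.zeros((1, 1, 8, 8), np.float32), mode="flip+rot90")
    assert stub.calls == 8


def test_tta_symmetric_model_equals_single_pass():
    stub = _CountingStub()
    out = tta_predict(stub, np.zeros((2, 1, 8, 8), np.float32), mode="flip+rot90")
    np.testing.assert_allclose(out, 1.0 / 3)


def test_tta_probabilities_sum_to_one(tiny_model):
    x = np.random.default_rng(0).normal(size=(1, 1, 32, 32)).astype(np.float32)
    out = tta_predict(tiny_model, x, mode="flip")
    assert out.shape[1] == tiny_model.config.num_classes
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)


def test_tta_unknown_mode_rejected(tiny_model):
    with pytest.raises(ConfigError):
        tta_predict(tiny_model, np.zeros((1, 1, 32, 32), np.float32), mode="zoom")


# -- schedule and loop -------------------------------------------------------

def test_cosine_schedule_endpoints_and_midpoint():
    assert cosine_lr(0, 30, 1e-3) == pytest.approx(1e-3)
    assert cosine_lr(30, 30, 1e-3) == pytest.approx(0.0)
    assert cosine_lr(15, 30, 1e-3) == pytest.approx(5e-4)
    assert cosine_lr(5, 10, 2e-3, 4e-4) == pytest.approx((2e-3 + 4e-4) / 2)


def _tiny_run(seed=1234, epochs=2):
    spec = SyntheticSpec(image_size=32, n_train=24, n_val=6, n_test=0, seed=7)
    data = make_dataset(spec)
    cfg = ModelConfig(backbone=BackboneConfig(stage_channels=(4, 8, 8, 16)),
                      num_classes=4, decoder_channels=(8, 8, 4, 4), gn_groups=4)
    model = SegmentationNet(cfg, seed=seed)
    tc = TrainConfig(epochs=epochs, base_lr=2e-3, batch_size=12, input_size=32,
                     seed=seed)
    return train(model, data, tc)


def test_training_deterministic_and_history_complete():
    _, h1 = _tiny_run()
    _, h2 = _tiny_run()
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["val_dsc"] == h2["val_dsc"]
    assert len(h1["epoch"]) == len(h1["lr"]) == 2


def test_loss_decreases_on_learnable_toy():
    spec = SyntheticSpec(image_size=32, n_train=48, n_val=6, n_test=0, seed=5)
    data = make_dataset(spec)
    cfg = ModelConfig(backbone=BackboneConfig(stage_channels=(4, 8, 8, 16)),
                      num_classes=4, decoder_channels=(8, 8, 4, 4), gn_groups=4)
    model = SegmentationNet(cfg, seed=0)
    tc = TrainConfig(epochs=5, base_lr=3e-3, batch_size=12, input_size=32, seed=0)
    _, hist = train(model, data, tc)
    losses = hist["train_loss"]
    assert losses[-1] < losses[0]
    assert all(np.isfinite(losses))


def test_nonfinite_loss_aborts():
    spec = SyntheticSpec(image_size=32, n_train=12, n_val=2, n_test=0, seed=9)
    data = make_dataset(spec)
    cfg = ModelConfig(backbone=BackboneConfig(stage_channels=(4, 8, 8, 16)),
                      num_classes=4, decoder_channels=(8, 8, 4, 4), gn_groups=4)
    model = SegmentationNet(cfg, seed=0)
    model.head.weight.data[...] = np.nan  # poison the classification head
    with pytest.raises(RuntimeError, match="non-finite"):
        train(model, data, TrainConfig(epochs=1, batch_size=12, input_size=32))
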