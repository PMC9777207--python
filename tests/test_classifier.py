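"""Classifier: balancing arithmetic, dihedral augmentation, model structure,
two-step training behaviour."""

import numpy as np
import pytest

from fibropath.backbones import BackboneSpec, UnknownBackboneError
from fibropath.classifier import (
    AugmentationPlan,
    CnnTrainConfig,
    DIHEDRAL_TRANSFORMS,
    HeadSpec,
    apply_dihedral,
    balance_factor,
    build_classifier,
    expand_with_dihedral,
    finetune_on_real,
    predict_patch_prob,
    pretrain_on_generated,
)


def two_class_images(n_per_class, edge=16, seed=0):
    """Well-separated toy image classes: dark-speckled vs plain bright."""
    rng = np.random.default_rng(seed)
    imgs, labels = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            img = rng.integers(180, 230, size=(edge, edge, 3))
            if cls == 1:
                mask = rng.uniform(size=(edge, edge)) < 0.25
                img[mask] = rng.integers(20, 80, size=(int(mask.sum()), 3))
            imgs.append(img.astype(np.uint8))
            labels.append(cls)
    return np.stack(imgs), np.array(labels)


class TestBalanceArithmetic:
    def test_reference_counts_give_factor_three(self):
        assert balance_factor(23142, 7817) == 3

    def test_balanced_classes_keep_factor_one(self):
        assert balance_factor(100, 100) == 1

    def test_factor_clips_at_eight(self):
        assert balance_factor(1000, 90) == 8

    @pytest.mark.parametrize("maj,mino", [(0, 1), (5, 0), (3, 7)])
    def test_invalid_counts_rejected(self, maj, mino):
        with pytest.raises(ValueError):
            balance_factor(maj, mino)

    def test_expansion_reproduces_reference_count(self):
        items = expand_with_dihedral(list(range(7817)), 3)
        assert len(items) == 23451

    def test_factor_one_is_identity(self):
        records = ["a", "b", "c"]
        items = expand_with_dihedral(records, 1)
        assert [i.record for i in items] == records
        assert all(i.transform == "r0" for i in items)

    def test_factor_eight_enumerates_the_whole_group(self):
        items = expand_with_dihedral(list(range(10)), 8)
        assert len(items) == 80
        for rec in range(10):
            got = {i.transform for i in items if i.record == rec}
            assert got == set(DIHEDRAL_TRANSFORMS)

    def test_balanced_plan_bounds_residual_imbalance(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n_min = int(rng.integers(10, 500))
            n_maj = int(rng.integers(n_min, 8 * n_min))
            plan = AugmentationPlan.balanced({0: n_maj, 1: n_min})
            f = plan.factor_for(1)
            assert plan.factor_for(0) == 1
            if f < 8:  # unclipped: rounding leaves at most half the minority
                assert abs(f * n_min - n_maj) <= n_min / 2


class TestDihedral:
    def test_transforms_are_distinct_and_invertible(self):
        img = np.arange(27).reshape(3, 3, 3).astype(np.uint8)
        outs = [apply_dihedral(img, t).tobytes() for t in DIHEDRAL_TRANSFORMS]
        assert len(set(outs)) == 8
        assert np.array_equal(apply_dihedral(img, "r0"), img)


class TestModelStructure:
    def test_head_widths_are_1024_and_2(self):
        model = build_classifier(input_edge=16)
        assert model.head_hidden.weight.shape[1] == 1024
        assert model.head_out.weight.shape == (1024, 2)

    def test_softmax_output_normalised_and_finite(self):
        model = build_classifier(input_edge=16)
        probs = model.predict_proba(np.zeros((3, 16, 16, 3), dtype=np.uint8))
        assert np.all(np.isfinite(probs))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(UnknownBackboneError):
            build_classifier(BackboneSpec(name="alexnet"))

    def test_tiny_cnn_cannot_claim_imagenet(self):
        with pytest.raises(ValueError):
            BackboneSpec(name="tiny_cnn", pretrained_imagenet=True).validate()

    def test_pretrained_request_records_random_fallback(self):
        model = build_classifier(
            BackboneSpec(name="vgg16", pretrained_imagenet=True), input_edge=32
        )
        assert model.weights_used == "random"

    @pytest.mark.parametrize(
        "name", ["vgg19", "resnet50", "densenet121", "inception_v3"]
    )
    def test_big_backbones_forward(self, name):
        model = build_classifier(BackboneSpec(name=name), input_edge=64, seed=1)
        probs = model.predict_proba(
            np.random.default_rng(0).integers(0, 255, (1, 64, 64, 3), dtype=np.uint8)
        )
        assert np.all(np.isfinite(probs))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestTwoStepTraining:
    def test_pretrain_learns_separable_classes(self):
        imgs, labels = two_class_images(100, seed=5)
        model = build_classifier(input_edge=16, seed=2)
        cfg = CnnTrainConfig(lr=2e-3, epochs=3, batch_size=16, seed=0, input_edge=16)
        pretrain_on_generated(model, imgs, labels, cfg)
        pred = model.predict_proba(imgs).argmax(axis=1)
        assert (pred == labels).mean() >= 0.9

    def test_single_class_rejected(self):
        imgs, labels = two_class_images(10)
        model = build_classifier(input_edge=16)
        cfg = CnnTrainConfig(lr=1e-3, epochs=1, input_edge=16)
        with pytest.raises(ValueError):
            pretrain_on_generated(model, imgs[labels == 0], labels[labels == 0], cfg)

    def test_training_is_deterministic_under_seed(self):
        imgs, labels = two_class_images(20, seed=1)
        cfg = CnnTrainConfig(lr=1e-3, epochs=1, batch_size=8, seed=3, input_edge=16)
        losses = []
        for _ in range(2):
            model = build_classifier(input_edge=16, seed=4)
            pretrain_on_generated(model, imgs, labels, cfg)
            losses.append([e["loss"] for e in model.train_log])
        assert losses[0] == losses[1]

    def test_finetune_expands_counts_and_keeps_step_purity(self):
        gen_imgs, gen_labels = two_class_images(16, seed=6)
        real_imgs, real_labels = two_class_images(8, seed=7)
        # imbalance: drop half of class 0
        keep = np.concatenate([np.flatnonzero(real_labels == 0)[:4],
                               np.flatnonzero(real_labels == 1)])
        real_imgs, real_labels = real_imgs[keep], real_labels[keep]

        model = build_classifier(input_edge=16, seed=8)
        cfg = CnnTrainConfig(lr=1e-3, epochs=1, batch_size=4, seed=0, input_edge=16)
        pretrain_on_generated(model, gen_imgs, gen_labels, cfg)
        plan = AugmentationPlan.balanced({0: 4, 1: 8})
        assert plan.factor_for(0) == 2  # minority expanded toward majority
        finetune_on_real(model, real_imgs, real_labels, plan, cfg)

        phases = [e["phase"] for e in model.train_log]
        switch = phases.index("finetune")
        assert all(p == "pretrain" for p in phases[:switch])
        assert all(p == "finetune" for p in phases[switch:])

    def test_factor_one_plan_keeps_raw_counts(self):
        imgs, labels = two_class_images(6, seed=9)
        model = build_classifier(input_edge=16, seed=1)
        cfg = CnnTrainConfig(lr=1e-3, epochs=1, batch_size=3, seed=0, input_edge=16)
        finetune_on_real(
            model, imgs, labels, AugmentationPlan(factors={0: 1, 1: 1}), cfg
        )
        n_steps = len([e for e in model.train_log if e["phase"] == "finetune"])
        assert n_steps == int(np.ceil(len(imgs) / 3))


class TestPrediction:
    def test_probability_complement_and_repeatability(self):
        model = build_classifier(input_edge=16, seed=0)
        patch = np.random.default_rng(1).integers(0, 255, (16, 16, 3), dtype=np.uint8)
        p1 = predict_patch_prob(model, patch)
        p2 = predict_patch_prob(model, patch)
        assert p1 == p2
        probs = model.predict_proba(patch[None])[0]
        assert probs[0] + probs[1] == pytest.approx(1.0, abs=1e-9)
        assert p1 == pytest.approx(probs[1])

    def test_wrong_input_size_rejected(self):
        model = build_classifier(input_edge=16)
        with pytest.raises(ValueError):
            predict_patch_prob(model, np.zeros((32, 32, 3), dtype=np.uint8))
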