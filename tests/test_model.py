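"""Split arithmetic, loss/IoU definitions, and segmenter training behavior."""

from __future__ import annotations

import numpy as np
import pytest

from peridermtk import model as md
from peridermtk import synthetic_data as sd
from peridermtk.io_formats import LabelMask
from peridermtk.tiling import TilingConfig


class TestSplitPatches:
    def test_canonical_dataset_split_sizes(self):
        train, val, test = md.split_patches(list(range(1471)), (0.6, 0.2, 0.2), seed=0)
        assert (len(train), len(val), len(test)) == (883, 294, 294)

    def test_small_dataset_split(self):
        train, val, test = md.split_patches(list(range(10)), (0.6, 0.2, 0.2), seed=1)
        assert (len(train), len(val), len(test)) == (6, 2, 2)

    def test_disjoint_and_complete(self):
        items = list(range(50))
        parts = md.split_patches(items, (0.6, 0.2, 0.2), seed=3)
        joined = sorted(parts[0] + parts[1] + parts[2])
        assert joined == items
        assert not (set(parts[0]) & set(parts[1]) & set(parts[2]))

    def test_same_seed_reproduces_different_seed_permutes(self):
        items = list(range(40))
        a = md.split_patches(items, (0.6, 0.2, 0.2), seed=7)
        b = md.split_patches(items, (0.6, 0.2, 0.2), seed=7)
        c = md.split_patches(items, (0.6, 0.2, 0.2), seed=8)
        assert a == b
        assert a != c
        assert [len(x) for x in a] == [len(x) for x in c]

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="3"):
            md.split_patches([1, 2], (0.6, 0.2, 0.2), seed=0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            md.split_patches(list(range(10)), (0.5, 0.2, 0.2), seed=0)


class TestCompositeLoss:
    def test_confident_correct_prediction_approaches_zero(self):
        target = np.array([[0, 1], [2, 3]], dtype=np.uint8)
        logits = np.full((2, 2, 4), -50.0)
        for i in range(2):
            for j in range(2):
                logits[i, j, target[i, j]] = 50.0
        loss = md.composite_loss(logits, target)
        assert loss.total == pytest.approx(0.0, abs=1e-6)

    def test_uniform_logits_cross_entropy_is_ln4(self):
        target = np.zeros((5, 5), dtype=np.uint8)
        target[0, :] = 1
        loss = md.composite_loss(np.zeros((5, 5, 4)), target)
        assert loss.cross_entropy == pytest.approx(np.log(4))

    def test_swapped_classes_dice_term_is_one(self):
        # two-class toy: prediction and target swap classes 1 and 2 everywhere
        target = np.concatenate([np.full(50, 1), np.full(50, 2)]).astype(np.uint8)
        logits = np.full((100, 4), -50.0)
        logits[:50, 2] = 50.0  # predicts 2 where truth is 1
        logits[50:, 1] = 50.0
        loss = md.composite_loss(logits, target)
        assert loss.dice == pytest.approx(1.0, abs=1e-6)

    def test_loss_is_non_negative(self):
        rng = np.random.default_rng(0)
        loss = md.composite_loss(rng.normal(size=(10, 10, 4)),
                                 rng.integers(0, 4, (10, 10)).astype(np.uint8))
        assert loss.total >= 0 and loss.cross_entropy >= 0 and loss.dice >= 0

    def test_target_class_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            md.composite_loss(np.zeros((2, 2, 4)), np.full((2, 2), 5, dtype=np.uint8))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            md.composite_loss(np.zeros((2, 3, 4)), np.zeros((2, 2), dtype=np.uint8))


class TestIouScore:
    def test_identical_masks_score_one(self):
        m = np.random.default_rng(1).integers(0, 4, (20, 20)).astype(np.uint8)
        m[0, 0] = 1  # at least one non-background pixel
        assert md.iou_score(m, m) == 1.0

    def test_disjoint_equal_areas_score_zero(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros((10, 10), dtype=np.uint8)
        a[:5] = 1
        b[5:] = 1
        assert md.iou_score(a, b) == 0.0

    def test_half_coverage_scores_half(self):
        target = np.zeros((10, 10), dtype=np.uint8)
        target[:, :10] = 1  # 100 px
        pred = np.zeros((10, 10), dtype=np.uint8)
        pred[:5, :] = 1  # covers 50, no false positives
        assert md.iou_score(pred, target) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, (15, 15)).astype(np.uint8)
        b = rng.integers(0, 4, (15, 15)).astype(np.uint8)
        assert md.iou_score(a, b) == pytest.approx(md.iou_score(b, a))

    def test_accepts_label_mask_objects(self):
        m = LabelMask(np.ones((4, 4), dtype=np.uint8))
        assert md.iou_score(m, m) == 1.0


class TestTraining:
    def test_history_and_best_epoch_single_epoch(self, small_slide):
        patches, masks = sd.make_patch_dataset([small_slide], patch_size=256)
        _, history = md.train(
            patches[:12], masks[:12],
            md.ModelConfig(hidden_layer_sizes=(8,)),
            md.TrainConfig(epochs=1, seed=0, samples_per_patch=300, val_sample_size=2000),
        )
        assert len(history.records) == 1
        assert history.best_epoch == 1

    def test_same_seed_reproduces_history(self, small_slide):
        patches, masks = sd.make_patch_dataset([small_slide], patch_size=256)
        kwargs = dict(
            model_config=md.ModelConfig(hidden_layer_sizes=(8,)),
            train_config=md.TrainConfig(epochs=3, seed=5, samples_per_patch=300,
                                        val_sample_size=2000),
        )
        _, h1 = md.train(patches[:12], masks[:12], **kwargs)
        _, h2 = md.train(patches[:12], masks[:12], **kwargs)
        assert h1.records == h2.records
        assert h1.best_epoch == h2.best_epoch

    def test_best_epoch_attains_maximum_val_iou(self, trained_fixture_model):
        _, history = trained_fixture_model
        ious = [r["val_iou"] for r in history.records]
        assert history.records[history.best_epoch - 1]["val_iou"] == max(ious)

    def test_overfit_sanity_high_val_iou_on_training_distribution(self):
        # a tiny model trained on a lateral-free slide should fit its own
        # distribution almost perfectly
        slide = sd.generate_slide(
            n_roots=2,
            specs=[
                sd.SyntheticRootSpec(total_length=2000, width=50, periderm_fraction=0.5,
                                     curvature_amplitude=50, lateral_root_count=0, seed=s)
                for s in (41, 42)
            ],
            seed=40, canvas=(2400, 1200), slide_id="overfit",
        )
        patches, masks = sd.make_patch_dataset([slide], patch_size=256)
        keep = [i for i, m in enumerate(masks) if (m != 0).any()]
        patches = [patches[i] for i in keep]
        masks = [masks[i] for i in keep]
        _, history = md.train(
            patches, masks,
            md.ModelConfig(hidden_layer_sizes=(16,)),
            md.TrainConfig(epochs=30, seed=0, val_sample_size=20000),
        )
        assert history.records[history.best_epoch - 1]["val_iou"] >= 0.90

    def test_train_loss_decreases_overall(self, trained_fixture_model):
        _, history = trained_fixture_model
        losses = [r["train_loss"] for r in history.records]
        assert losses[-1] < losses[0]

    def test_mismatched_patch_mask_pairing_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            md.train([np.zeros((32, 32, 3), dtype=np.uint8)], [])


class TestPredictSlide:
    def test_single_patch_path_equals_direct_patch_prediction(
        self, trained_fixture_model, small_slide
    ):
        model, _ = trained_fixture_model
        patch = small_slide.image.pixels[:256, :256]
        direct = model.predict_patch(patch)
        via_slide = md.predict_slide(model, patch, TilingConfig(patch_size=256))
        np.testing.assert_array_equal(direct, via_slide.labels)

    def test_all_background_image_predicted_mostly_background(self, trained_fixture_model):
        model, _ = trained_fixture_model
        rng = np.random.default_rng(0)
        dark = rng.normal(8, 4, size=(256, 256, 3)).clip(0, 255).astype(np.uint8)
        pred = md.predict_slide(model, dark, TilingConfig(patch_size=256))
        assert (pred.labels == 0).mean() >= 0.99

    def test_output_matches_input_dimensions_and_vocabulary(
        self, trained_fixture_model, small_slide
    ):
        model, _ = trained_fixture_model
        crop = small_slide.image.pixels[:500, :700]
        pred = md.predict_slide(model, crop, TilingConfig(patch_size=256))
        assert pred.labels.shape == (500, 700)
        assert set(np.unique(pred.labels)) <= {0, 1, 2, 3}

    def test_per_class_iou_against_truth_with_fixture_model(
        self, trained_fixture_model, small_slide
    ):
        model, _ = trained_fixture_model
        pred = md.predict_slide(model, small_slide.image, TilingConfig(patch_size=256))
        for code in (1, 2):
            p = pred.labels == code
            t = small_slide.truth_mask.labels == code
            iou = (p & t).sum() / (p | t).sum()
            assert iou >= 0.8, f"class {code} IoU {iou:.3f}"

    def test_wrong_channel_count_rejected(self, trained_fixture_model):
        model, _ = trained_fixture_model
        with pytest.raises(ValueError, match="HxWx3"):
            md.predict_slide(model, np.zeros((64, 64), dtype=np.uint8))


class TestCheckpointRoundTrip:
    def test_save_load_predicts_identically(self, trained_fixture_model, small_slide, tmp_path):
        model, _ = trained_fixture_model
        path = model.save(tmp_path / "model.joblib")
        back = md.TrainedModel.load(path)
        patch = small_slide.image.pixels[:256, :256]
        np.testing.assert_array_equal(model.predict_patch(patch), back.predict_patch(patch))
        assert back.class_map == model.class_map
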