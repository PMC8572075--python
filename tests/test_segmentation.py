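"""Segmentation: architecture contract, Dice, classical segmenter, training."""

import dataclasses

import numpy as np
import pytest

from scoutrange.core import Mask2D, Projection2D
from scoutrange.phantom import PhantomConfig, generate_phantom
from scoutrange.projection import normalize_resize, project_mask, project_volume
from scoutrange.ranges import mask_to_range
from scoutrange.segmentation import (
    SegModelConfig,
    build_model,
    classical_segment,
    dice,
    load_model,
    make_dataset,
    predict_mask,
    save_model,
    train,
)


class TestBuildModel:
    def test_twenty_layers_make_ten_residual_blocks(self):
        model = build_model(SegModelConfig())
        assert model.n_blocks == 10
        assert model.n_layers == 20 and model.span == 2
        assert model.n_parameters() > 0

    def test_forward_pass_bounded_probabilities(self):
        model = build_model(SegModelConfig())
        probs = model.predict_proba(np.zeros((256, 256), dtype=np.float32))
        assert probs.shape == (256, 256)
        assert np.all(np.isfinite(probs))
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_seeded_initialization_reproducible(self):
        a = build_model(SegModelConfig(seed=5))
        b = build_model(SegModelConfig(seed=5))
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa, pb)

    def test_mismatched_dilation_schedule_rejected(self):
        with pytest.raises(ValueError, match="dilation"):
            build_model(SegModelConfig(dilation_schedule=(1, 2, 4)))

    def test_odd_layer_count_rejected(self):
        with pytest.raises(ValueError):
            build_model(SegModelConfig(n_conv_layers=19))

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_model(SegModelConfig(seed=3))
        x = np.random.default_rng(0).random((64, 64)).astype(np.float32)
        save_model(model, tmp_path / "m.npz")
        clone = load_model(tmp_path / "m.npz")
        assert np.allclose(model.predict_proba(x), clone.predict_proba(x))


class TestDice:
    def _m(self, pix):
        return Mask2D(np.asarray(pix, bool), "AP", 0.0, 1.0)

    def test_identical_masks(self):
        pix = np.zeros((16, 16), bool)
        pix[4:9, 4:9] = True
        assert dice(self._m(pix), self._m(pix)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[:4], b[8:] = True, True
        assert dice(self._m(a), self._m(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(self._m(a), self._m(b)) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        assert dice(self._m(np.zeros((8, 8))), self._m(np.zeros((8, 8)))) == 1.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = self._m(rng.random((16, 16)) > 0.5)
            b = self._m(rng.random((16, 16)) > 0.8)
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(self._m(np.zeros((8, 8))), self._m(np.zeros((9, 8))))


class TestPredictMask:
    def test_threshold_monotonicity(self):
        model = build_model(SegModelConfig(seed=1))
        rng = np.random.default_rng(0)
        proj = Projection2D(
            rng.random((256, 256)).astype(np.float32), "AP", 0.0, 1.0
        )
        areas = [
            predict_mask(model, proj, threshold=t).pixels.sum()
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert np.all(np.diff(areas) <= 0)

    def test_unnormalized_input_rejected(self):
        model = build_model(SegModelConfig())
        proj = Projection2D(
            np.full((256, 256), 50.0, np.float32), "AP", 0.0, 1.0
        )
        with pytest.raises(ValueError, match="normalized"):
            predict_mask(model, proj)

    def test_mask_shares_z_mapping(self):
        model = build_model(SegModelConfig())
        proj = Projection2D(
            np.zeros((256, 256), np.float32), "AP", z0=12.5, dz=1.25
        )
        mask = predict_mask(model, proj)
        assert (mask.z0, mask.dz, mask.view) == (12.5, 1.25, "AP")


class TestClassicalSegment:
    def test_noiseless_phantom_high_dice(self, ap_projection_256):
        proj, truth = ap_projection_256
        assert dice(classical_segment(proj), truth) >= 0.95

    def test_constant_image_no_body(self):
        proj = Projection2D(np.zeros((64, 64), np.float32), "AP", 0.0, 1.0)
        with pytest.raises(ValueError, match="no body"):
            classical_segment(proj)

    def test_mild_noise_degrades_dice_slightly(self, ap_projection_256):
        _, truth = ap_projection_256
        cfg = PhantomConfig(noise_sd=20.0, pathology_fraction=0.0)
        volume, _ = generate_phantom(cfg, seed=1)
        noisy, _ = normalize_resize(project_volume(volume, "AP"), None, 256)
        clean_proj, _ = ap_projection_256
        d_clean = dice(classical_segment(clean_proj), truth)
        d_noisy = dice(classical_segment(noisy), truth)
        assert d_clean - d_noisy < 0.05

    def test_lateral_view_segments_one_region(self, noiseless_phantom):
        _, volume, mask3 = noiseless_phantom
        proj, truth = normalize_resize(
            project_volume(volume, "LAT"), project_mask(mask3, "LAT"), 256
        )
        assert dice(classical_segment(proj), truth) >= 0.90


class TestTraining:
    def _tiny_dataset(self, n=24):
        cfg = PhantomConfig(
            matrix=(64, 64, 48), spacing=(6.0, 6.0, 5.0),
            body_semi_axes=(11.0, 14.0), lung_top_mm=25.0, lung_length_mm=150.0,
            noise_sd=5.0,
        )
        pairs = []
        for seed in range(n):
            volume, mask3 = generate_phantom(cfg, seed=seed)
            pairs.append(
                normalize_resize(
                    project_volume(volume, "AP"), project_mask(mask3, "AP"), 64
                )
            )
        return pairs

    def test_zero_epochs_leaves_model_unchanged(self):
        dataset = self._tiny_dataset()
        cfg = SegModelConfig(epochs=0, input_size=64, seed=2)
        model = build_model(cfg)
        before = [p.copy() for p in model.params]
        model, report = train(model, dataset, cfg)
        for b, p in zip(before, model.params):
            assert np.array_equal(b, p)
        assert len(report.val_dice) == 1
        assert 0.0 <= report.final_val_dice <= 1.0

    def test_training_reduces_loss_and_is_seeded(self):
        dataset = self._tiny_dataset()
        cfg = SegModelConfig(epochs=2, input_size=64, seed=4)
        _, rep1 = train(build_model(cfg), dataset, cfg)
        _, rep2 = train(build_model(cfg), dataset, cfg)
        assert rep1.train_loss == rep2.train_loss
        assert rep1.train_loss[-1] < rep1.train_loss[0]

    def test_small_dataset_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            train(build_model(SegModelConfig()), self._tiny_dataset(4),
                  SegModelConfig())

    def test_shape_mismatch_rejected(self):
        dataset = self._tiny_dataset()
        proj, _ = dataset[0]
        bad_mask = Mask2D(np.zeros((32, 32), bool), "AP", 0.0, 1.0)
        dataset[0] = (proj, bad_mask)
        with pytest.raises(ValueError, match="mismatch"):
            train(build_model(SegModelConfig()), dataset, SegModelConfig())


class TestTrainedModel:
    """Checks on the shared 200-image / 10-epoch reference training run."""

    def test_predicts_noiseless_phantom_accurately(
        self, trained_model, ap_projection_256
    ):
        model, _, _ = trained_model
        proj, truth = ap_projection_256
        assert dice(predict_mask(model, proj), truth) >= 0.90

    def test_range_limits_agree_with_classical_oracle(
        self, trained_model, ap_projection_256
    ):
        model, _, _ = trained_model
        proj, _ = ap_projection_256
        r_model = mask_to_range(predict_mask(model, proj), margin_voxels=0)
        r_classic = mask_to_range(classical_segment(proj), margin_voxels=0)
        assert abs(r_model.superior_z - r_classic.superior_z) <= 2 * proj.dz
        assert abs(r_model.inferior_z - r_classic.inferior_z) <= 2 * proj.dz

    def test_scout_fine_tuning_transfers(self, trained_model):
        model, _, _ = trained_model
        scouts = make_dataset(50, seed=23, scout_mode=True)
        cfg = SegModelConfig(seed=1, epochs=3, lr=3e-4, split=(0.7, 0.3, 0.0))
        # fine-tune a copy so the session fixture stays untouched
        from scoutrange.nn import SegNet

        clone = SegNet.from_state(model.state())
        _, report = train(clone, scouts, cfg)
        assert report.final_val_dice >= 0.85
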