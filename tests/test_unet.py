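"""U-Net: architecture contracts, Dice oracle agreement, training recovery."""

import numpy as np
import pytest

from wristvein.metrics import dice_coefficient, dice_loss
from wristvein.unet import (UNet, UNetConfig, build_unet, predict_proba,
                            segment, train_unet)


class TestArchitecture:
    def test_parameter_count_invariant_to_input_size(self):
        counts = {size: UNet(UNetConfig(input_size=(size, size))).n_params()
                  for size in (64, 128, 256)}
        assert len(set(counts.values())) == 1

    def test_first_block_parameter_count_closed_form(self):
        model = build_unet(UNetConfig(input_size=(64, 64)))
        block = model.enc[0]
        n = sum(p.size for p in block["conv1"].params() + block["conv2"].params())
        assert n == 160 + 2320      # (9*1+1)*16 + (9*16+1)*16

    def test_forward_contract(self):
        model = build_unet(UNetConfig(input_size=(64, 64)))
        out = model.forward(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert out.shape == (1, 1, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(input_size=(100, 100))

    def test_filters_double_per_contracting_block(self):
        model = build_unet(UNetConfig(input_size=(64, 64)))
        outs = [b["conv2"].c_out for b in model.enc]
        assert outs == [16, 32, 64, 128]

    def test_gabor_first_block_kernels_are_oriented_band_pass(self):
        from wristvein.unet import GaborParams, gabor_bank
        bank = gabor_bank(16, GaborParams())
        assert bank.shape == (16, 3, 3)
        assert np.allclose(bank.sum(axis=(1, 2)), 0, atol=1e-5)   # zero mean
        assert not np.allclose(bank[0], bank[1])                  # orientations differ


class TestDice:
    def test_boundary_cases(self):
        a = np.zeros((4, 4)); a[0, :3] = 1
        assert dice_coefficient(a, a) == 1.0
        b = np.zeros((4, 4)); b[2, :3] = 1
        assert dice_coefficient(a, b) == 0.0
        assert dice_coefficient(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_hand_built_three_pixel_example(self):
        p = np.zeros(8); p[[0, 1, 2]] = 1
        y = np.zeros(8); y[[1, 2, 3]] = 1
        assert dice_coefficient(p, y) == pytest.approx(4 / 6)
        assert dice_loss(p, y) == pytest.approx(1 - 4 / 6)

    def test_agrees_with_pixel_counting_oracle(self):
        """2|P∩Y|/(|P|+|Y|) vs explicit pixel loops on 1000 random 8x8 masks."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.random((8, 8)) > rng.uniform(0.2, 0.9)
            y = rng.random((8, 8)) > rng.uniform(0.2, 0.9)
            inter = sum(1 for i in range(8) for j in range(8) if p[i, j] and y[i, j])
            tot = int(p.sum()) + int(y.sum())
            expected = 1.0 if tot == 0 else 2 * inter / tot
            assert dice_coefficient(p, y) == pytest.approx(expected)
            assert dice_coefficient(p, y) == pytest.approx(dice_coefficient(y, p))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))


class TestTraining:
    def _tiny_data(self, n=4, size=16, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 256, (n, size, size)).astype(np.uint8)
        y = (rng.random((n, size, size)) > 0.8).astype(np.uint8)
        return x, y

    def test_smoke_run_single_epoch(self):
        x, y = self._tiny_data()
        cfg = UNetConfig(input_size=(16, 16), epochs=1, batch_size=2, seed=1)
        report = train_unet(UNet(cfg), x, y, cfg)
        assert report.epochs_run == 1
        assert np.isfinite(report.train_loss[0])

    def test_seeded_rerun_reproduces_loss_curve(self):
        x, y = self._tiny_data()
        cfg = UNetConfig(input_size=(16, 16), epochs=2, batch_size=2, seed=5)
        r1 = train_unet(UNet(cfg), x, y, cfg)
        r2 = train_unet(UNet(cfg), x, y, cfg)
        assert r1.train_loss == r2.train_loss
        assert r1.val_metric == r2.val_metric

    def test_empty_dataset_rejected(self):
        cfg = UNetConfig(input_size=(16, 16))
        with pytest.raises(ValueError):
            train_unet(UNet(cfg), np.empty((0, 16, 16)), np.empty((0, 16, 16)), cfg)

    def test_recovery_on_synthetic_set(self, unet_recovery):
        """Scaled-down recovery: validation Dice against generator ground
        truth exceeds 0.5 and strictly beats the untrained network."""
        rec = unet_recovery
        assert rec["report"].val_metric[-1] > 0.5
        assert rec["report"].val_metric[-1] > rec["untrained_dice"]


class TestSegment:
    def test_untrained_model_deterministic_binary(self):
        model = build_unet(UNetConfig(input_size=(64, 64), seed=2))
        img = np.random.default_rng(0).integers(0, 256, (64, 64)).astype(np.uint8)
        m1 = segment(model, img)
        m2 = segment(model, img)
        assert np.array_equal(m1, m2)
        assert set(np.unique(m1)) <= {0, 1}

    def test_wrong_dims_rejected(self):
        model = build_unet(UNetConfig(input_size=(64, 64)))
        with pytest.raises(ValueError):
            segment(model, np.zeros((128, 128), dtype=np.uint8))

    def test_trained_model_beats_classical_labeling(self, unet_recovery, dataset):
        """The trained segmenter outperforms the classical chain on held-out
        synthetic images (the reason it is used to relabel the data)."""
        from wristvein.labeling import generate_mask
        rec = unet_recovery
        x, y, val_idx = rec["x"], rec["y"], rec["val_idx"]
        xv = (x.astype(np.float32) / 255.0)[val_idx][:, None]
        p = predict_proba(rec["model"], xv)
        unet_d = np.mean([dice_coefficient(p[i, 0] > 0.5, y[val_idx][i])
                          for i in range(len(val_idx))])
        classical_d = np.mean([dice_coefficient(generate_mask(x[i]), y[i])
                               for i in val_idx])
        assert unet_d > classical_d

    def test_save_load_roundtrip(self, tmp_path):
        from wristvein.app import load_model
        from wristvein.training import save_model
        model = build_unet(UNetConfig(input_size=(64, 64), seed=9))
        img = np.random.default_rng(1).integers(0, 256, (64, 64)).astype(np.uint8)
        before = segment(model, img)
        save_model(model, tmp_path / "unet")
        back = load_model(tmp_path / "unet")
        assert np.array_equal(segment(back, img), before)
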