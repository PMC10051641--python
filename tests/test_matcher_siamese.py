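"""Siamese matcher: weight sharing, contrastive-loss oracle, distance axioms,
threshold decisions, training recovery."""

import numpy as np
import pytest

from wristvein.matcher_siamese import (SiameseConfig, SiameseEmbedding,
                                       build_subnetwork, contrastive_loss,
                                       decide, embed_batch, embed_pair,
                                       euclidean_distance, train_siamese)
from wristvein.pairing import GENUINE


@pytest.fixture(scope="module")
def model():
    return build_subnetwork(SiameseConfig(input_size=(32, 32), seed=3))


class TestSubnetwork:

    @pytest.mark.parametrize("size", [(32, 32), (64, 64)])
    def test_embedding_length_128_for_any_input_size(self, size):
        m = build_subnetwork(SiameseConfig(input_size=size, seed=1))
        x = np.zeros((2, 1) + size, dtype=np.float32)
        assert m.forward(x).shape == (2, 128)

    def test_conv_layer_parameter_audit(self, model):
        convs = [l for l in model.net.layers if type(l).__name__ == "Conv2D"]
        sizes = [sum(p.size for p in c.params()) for c in convs]
        assert sizes[0] == (9 * 1 + 1) * 64          # 640
        assert sizes[1] == sizes[2] == (9 * 64 + 1) * 64   # 36,928

    def test_identical_masks_identical_embeddings(self, model):
        m = (np.random.default_rng(0).random((32, 32)) > 0.5).astype(np.uint8)
        ea, eb = embed_pair(model, m, m)
        assert np.array_equal(ea, eb)

    def test_swap_symmetry_and_self_distance_zero(self, model):
        rng = np.random.default_rng(1)
        a = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        b = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        ea, eb = embed_pair(model, a, b)
        eb2, ea2 = embed_pair(model, b, a)
        assert np.array_equal(ea, ea2) and np.array_equal(eb, eb2)
        assert euclidean_distance(ea, ea) == 0.0
        assert euclidean_distance(ea, eb) == pytest.approx(euclidean_distance(eb, ea))
        assert euclidean_distance(ea, eb) >= 0.0

    def test_finite_embedding_on_all_ones_mask(self, model):
        e = embed_batch(model, np.ones((1, 32, 32), dtype=np.uint8))
        assert np.isfinite(e).all()

    def test_dim_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            embed_pair(model, np.zeros((32, 32)), np.zeros((16, 16)))


class TestContrastiveLoss:
    def test_boundary_cases(self):
        assert contrastive_loss([0.0], [0], margin=1.0) == 0.0      # perfect match
        assert contrastive_loss([0.0], [1], margin=1.0) == 1.0      # colliding impostors
        assert contrastive_loss([1.0], [1], margin=1.0) == 0.0      # separated
        assert contrastive_loss([2.5], [1], margin=1.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss([-0.1], [0])

    def test_matches_scalar_oracle_on_random_batches(self):
        """Vectorised loss vs an explicit per-element loop over 1000 random
        batches."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            d = rng.random(n) * 3
            y = rng.integers(0, 2, n)
            m = float(rng.uniform(0.5, 2.0))
            terms = []
            for di, yi in zip(d, y):
                if yi == 0:
                    terms.append(di ** 2)
                else:
                    terms.append(max(m - di, 0.0) ** 2)
            assert contrastive_loss(d, y, m) == pytest.approx(np.mean(terms))


class TestDecide:
    def test_zero_distance_always_matches(self):
        assert decide(0.0, 0.5).verdict is True

    def test_boundary_inclusive(self):
        assert decide(0.5, 0.5).verdict is True
        assert decide(0.5000001, 0.5).verdict is False

    def test_monotone_in_distance(self):
        verdicts = [decide(d, 1.0).verdict for d in np.linspace(0, 3, 50)]
        # once rejected, never accepted again as distance grows
        assert verdicts == sorted(verdicts, reverse=True)

    def test_score_is_sigmoid_of_distance(self):
        d = 1.3
        assert decide(d, 2.0).score == pytest.approx(1 / (1 + np.exp(-d)))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            decide(1.0, 0.0)


class TestTraining:
    def _tiny_pairs(self):
        import pandas as pd
        rng = np.random.default_rng(1)
        masks = [(rng.random((32, 32)) > 0.7).astype(np.uint8) for _ in range(4)]
        pairs = pd.DataFrame({
            "index_a": [0, 0, 2, 2], "index_b": [1, 3, 3, 1],
            "label": [GENUINE, "impostor", GENUINE, "impostor"],
        })
        return pairs, masks

    def test_smoke_two_epochs_finite(self):
        pairs, masks = self._tiny_pairs()
        cfg = SiameseConfig(input_size=(32, 32), batch_size=2, seed=2)
        report = train_siamese(SiameseEmbedding(cfg), pairs, pairs.iloc[:0],
                               masks, cfg, aug=None, epochs=2)
        assert report.epochs_run == 2
        assert all(np.isfinite(report.train_loss))

    def test_seeded_rerun_identical(self):
        pairs, masks = self._tiny_pairs()
        cfg = SiameseConfig(input_size=(32, 32), batch_size=2, seed=8)
        r1 = train_siamese(SiameseEmbedding(cfg), pairs, pairs.iloc[:0], masks,
                           cfg, aug=None, epochs=2)
        r2 = train_siamese(SiameseEmbedding(cfg), pairs, pairs.iloc[:0], masks,
                           cfg, aug=None, epochs=2)
        assert r1.train_loss == r2.train_loss

    def test_weight_sharing_is_a_single_parameter_store(self):
        """Both branches are the one sub-network: a parameter update moves
        both sides' embeddings identically."""
        cfg = SiameseConfig(input_size=(32, 32), seed=5)
        model = SiameseEmbedding(cfg)
        m = (np.random.default_rng(2).random((32, 32)) > 0.5).astype(np.uint8)
        model.params()[1].value += 0.05       # perturb one shared weight
        ea, eb = embed_pair(model, m, m)
        assert np.array_equal(ea, eb)

    def test_recovery_separates_identities(self, siamese_recovery):
        """Scaled-down recovery: validation F1 > 0.7 at the calibrated
        threshold and genuine distances sit below impostor distances."""
        rec = siamese_recovery
        vy = np.asarray(rec["val_labels_dissimilar"])
        d = rec["trained"]["distances"]
        assert rec["trained"]["f1"] > 0.7
        assert d[vy == 0].mean() < d[vy == 1].mean()

    def test_training_shrinks_genuine_distances_not_below_impostors(self, siamese_recovery):
        """Along the training trajectory the genuine mean distance falls from
        its transient peak while the impostor mean never drops below it."""
        rep = siamese_recovery["report"]
        gen = np.asarray(rep.val_genuine_distance)
        imp = np.asarray(rep.val_impostor_distance)
        assert gen[-1] < gen.max()                # genuine pulled back together
        assert (imp >= gen).all()                 # impostors never the closer class

    def test_save_load_roundtrip_preserves_embeddings(self, tmp_path):
        from wristvein.app import load_model
        from wristvein.training import save_model
        cfg = SiameseConfig(input_size=(32, 32), seed=11)
        model = SiameseEmbedding(cfg)
        x = (np.random.default_rng(3).random((2, 32, 32)) > 0.5).astype(np.uint8)
        before = embed_batch(model, x)
        save_model(model, tmp_path / "siamese")
        back = load_model(tmp_path / "siamese")
        assert np.allclose(embed_batch(back, x), before)
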