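"""Synthetic vascular dataset generator: determinism, identity signal,
geometric invariants."""

import numpy as np
import pytest

from wristvein.metrics import dice_coefficient
from wristvein.synthetic import (SceneParams, SubjectSpec, apply_affine,
                                 generate_dataset, grow_vein_tree,
                                 make_registry, rasterize_tree, render_session,
                                 session_jitter_params)


class TestRegistry:
    @pytest.mark.parametrize("n_subjects,n_sessions,expected", [
        (160, 2, 640),   # the full two-session campaign cardinality
        (1, 1, 2),       # minimal: one subject, left + right
        (10, 2, 40),
    ])
    def test_cardinality(self, n_subjects, n_sessions, expected):
        reg = make_registry(n_subjects, n_sessions, seed=0)
        assert len(reg) == expected
        assert reg["subject_id"].nunique() == n_subjects
        assert set(reg["wrist"]) == {"left", "right"}

    def test_deterministic(self):
        a = make_registry(10, 2, seed=7)
        b = make_registry(10, 2, seed=7)
        assert a.equals(b)

    @pytest.mark.parametrize("n_subjects,n_sessions", [(0, 2), (2, 0), (-1, 1)])
    def test_nonpositive_counts_rejected(self, n_subjects, n_sessions):
        with pytest.raises(ValueError):
            make_registry(n_subjects, n_sessions, seed=0)


class TestVeinTree:
    def test_deterministic_given_spec(self):
        spec = SubjectSpec("S0001", "left", seed=5)
        t1 = grow_vein_tree(spec, (128, 128))
        t2 = grow_vein_tree(spec, (128, 128))
        assert np.array_equal(t1.nodes, t2.nodes)
        assert t1.edges == t2.edges
        assert np.array_equal(t1.radii, t2.radii)

    def test_structure_invariants(self):
        tree = grow_vein_tree(SubjectSpec("S0002", "right", seed=3), (256, 256))
        assert tree.n_branch_points() >= 2
        assert tree.total_length() >= 0.5 * 256
        # connected acyclic: n_edges relates to n_nodes via the branch joins
        children = [c for _p, c in tree.edges]
        assert len(children) == len(set(children))          # single parent each
        assert (tree.nodes[:, 0] >= 0).all() and (tree.nodes[:, 0] < 256).all()
        assert (tree.nodes[:, 1] >= 0).all() and (tree.nodes[:, 1] < 256).all()
        assert (tree.radii >= 1.0).all()

    def test_distinct_subjects_have_low_mask_overlap(self):
        dices = []
        for seed in range(20):
            ta = grow_vein_tree(SubjectSpec(f"A{seed}", "left", 3), (128, 128))
            tb = grow_vein_tree(SubjectSpec(f"B{seed}", "left", 3), (128, 128))
            ma, _ = rasterize_tree(ta)
            mb, _ = rasterize_tree(tb)
            dices.append(dice_coefficient(ma, mb))
        assert max(dices) < 0.5

    def test_frame_too_small_rejected(self):
        with pytest.raises(ValueError):
            grow_vein_tree(SubjectSpec("S0", "left", 0), (32, 32))


class TestRenderSession:
    def test_degenerate_scene_is_constant(self):
        params = SceneParams(noise_sigma=0, gradient_amp=0, vein_contrast=0,
                             session_jitter=(0, 0, (1, 1)))
        tree = grow_vein_tree(SubjectSpec("S0", "left", 1), (128, 128))
        img, mask = render_session(tree, params, 4)
        assert img.min() == img.max()
        base, _ = rasterize_tree(tree)
        assert np.array_equal(mask, base)

    def test_genuine_sessions_register_to_high_dice(self):
        params = SceneParams()
        tree = grow_vein_tree(SubjectSpec("S1", "right", 5), (128, 128))
        _i1, m1 = render_session(tree, params, 11)
        _i2, m2 = render_session(tree, params, 22)
        r1 = apply_affine(m1, *session_jitter_params(params, 11),
                          binary=True, inverse=True)
        r2 = apply_affine(m2, *session_jitter_params(params, 22),
                          binary=True, inverse=True)
        assert dice_coefficient(r1, r2) > 0.6

    def test_mask_fraction_in_plausible_band(self):
        params = SceneParams()
        fracs = []
        for s in range(25):
            tree = grow_vein_tree(SubjectSpec(f"S{s}", "left", 9), (256, 256))
            for sess in (1, 2):
                _img, mask = render_session(tree, params, 100 * s + sess)
                fracs.append(mask.mean())
        assert all(0.02 <= f <= 0.25 for f in fracs)

    def test_centerline_is_local_intensity_minimum_without_blur(self):
        from scipy.ndimage import minimum_filter
        params = SceneParams(noise_sigma=0, gradient_amp=0, blur_sigma=0,
                             session_jitter=(0, 0, (1, 1)))
        for s in range(3):
            tree = grow_vein_tree(SubjectSpec(f"S{s}", "left", 2), (128, 128))
            img, _ = render_session(tree, params, 7)
            _, centre = rasterize_tree(tree)
            mn = minimum_filter(img.astype(int), size=3)
            cl = centre.astype(bool)
            assert (img.astype(int)[cl] <= mn[cl]).all()


class TestDataset:
    def test_generation_is_pure_function_of_inputs(self):
        r1, i1, m1 = generate_dataset(2, 2, seed=4, frame=(64, 64))
        r2, i2, m2 = generate_dataset(2, 2, seed=4, frame=(64, 64))
        assert r1.equals(r2)
        assert all(np.array_equal(a, b) for a, b in zip(i1, i2))
        assert all(np.array_equal(a, b) for a, b in zip(m1, m2))

    def test_adding_subjects_never_perturbs_existing(self):
        _r1, i1, m1 = generate_dataset(2, 2, seed=4, frame=(64, 64))
        _r2, i2, m2 = generate_dataset(3, 2, seed=4, frame=(64, 64))
        for k in range(len(i1)):
            assert np.array_equal(i1[k], i2[k])
            assert np.array_equal(m1[k], m2[k])

    def test_identity_signal(self, dataset):
        """Genuine pairs overlap strictly more than impostor pairs (the
        property that makes matcher recovery meaningful)."""
        reg, _imgs, masks = dataset
        rng = np.random.default_rng(0)
        n_wrists = len(reg) // 2
        genuine, impostor = [], []
        for w in range(n_wrists):
            i1, i2 = 2 * w, 2 * w + 1
            assert reg.subject_id[i1] == reg.subject_id[i2]
            genuine.append(dice_coefficient(masks[i1], masks[i2]))
            o = int(rng.integers(n_wrists))
            while o == w:
                o = int(rng.integers(n_wrists))
            impostor.append(dice_coefficient(masks[i1], masks[2 * o + 1]))
        assert len(genuine) + len(impostor) >= 100
        assert np.mean(genuine) > np.mean(impostor)

    def test_save_dataset_layout(self, tmp_path):
        import imageio.v3 as iio
        from wristvein.synthetic import save_dataset
        reg, imgs, masks = generate_dataset(1, 2, seed=0, frame=(64, 64))
        out = save_dataset(tmp_path, reg, imgs, masks)
        assert (tmp_path / "registry.csv").exists()
        p = out.iloc[0]["image_path"]
        assert iio.imread(p).shape == (64, 64)
        m = iio.imread(out.iloc[0]["mask_path"])
        assert set(np.unique(m)) <= {0, 255}
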