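import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colornet.synthdata import (
    AugmentationParams,
    CRCTemplate,
    SheetSpec,
    default_template,
    make_benchmark,
    make_patch_dataset,
    render_sheet,
    render_template,
    rot90_box,
)


class TestTemplate:
    def test_default_has_exactly_one_white_and_black(self):
        tpl = default_template()
        assert np.all(tpl.grid == 255, axis=-1).sum() == 1
        assert np.all(tpl.grid == 0, axis=-1).sum() == 1

    def test_missing_black_patch_rejected(self):
        grid = np.full((2, 2, 3), 255, dtype=np.uint8)
        with pytest.raises(ValueError):
            CRCTemplate(grid=grid)

    def test_rendered_centers_hit_pure_patches(self):
        tile, mask, wc, bc = render_template(default_template())
        assert (tile[int(wc[1]), int(wc[0])] == 255).all()
        assert (tile[int(bc[1]), int(bc[0])] == 0).all()
        assert mask.all()


class TestRenderSheet:
    def test_seed_determinism_byte_identical(self):
        spec = SheetSpec(seed=99, augmentation=AugmentationParams(darken=0.7))
        img1, gt1 = render_sheet(spec)
        img2, gt2 = render_sheet(spec)
        assert np.array_equal(img1, img2)
        assert gt1 == gt2

    def test_unaugmented_chart_pixels_match_template(self, plain_sheet):
        img, gt = plain_sheet
        x, y, w, h = (int(v) for v in gt["crc_box"])
        tile, _, _, _ = render_template(default_template(
            patch_px=(gt["crc_side"] - 6) // 5))
        assert np.array_equal(img[y : y + h, x : x + w], tile)

    def test_white_patch_center_is_pure_white_pre_augmentation(self, plain_sheet):
        img, gt = plain_sheet
        wx, wy = (int(v) for v in gt["white_patch_center"])
        bx, by = (int(v) for v in gt["black_patch_center"])
        assert (img[wy, wx] == 255).all()
        assert (img[by, bx] == 0).all()

    def test_chart_that_cannot_fit_rejected(self):
        spec = SheetSpec(size=(200, 200), crc_template=default_template(patch_px=50))
        with pytest.raises(ValueError):
            render_sheet(spec)

    def test_rotation_moves_ground_truth_consistently(self):
        base = SheetSpec(crc_position=(200, 300), skew_prob=0.0, occlusion_prob=0.0,
                         seed=31)
        img0, gt0 = render_sheet(base)
        aug = AugmentationParams(rotate_k=1)
        rot = SheetSpec(crc_position=(200, 300), skew_prob=0.0, occlusion_prob=0.0,
                        seed=31, augmentation=aug)
        img1, gt1 = render_sheet(rot)
        assert np.array_equal(img1, np.rot90(img0, k=1))
        assert tuple(gt1["crc_box"]) == rot90_box(gt0["crc_box"], 1250, 1875, 1)


class TestRot90Box:
    @given(
        k=st.integers(0, 3),
        x=st.integers(0, 900), y=st.integers(0, 1400),
        w=st.integers(1, 300), h=st.integers(1, 300),
    )
    @settings(max_examples=60, deadline=None)
    def test_four_turns_identity_and_inverse(self, k, x, y, w, h):
        box = (x, y, w, h)
        assert rot90_box(box, 1250, 1875, 4) == box
        once = rot90_box(box, 1250, 1875, k)
        img_w, img_h = (1250, 1875) if k % 2 == 0 else (1875, 1250)
        back = rot90_box(once, img_w, img_h, (4 - k) % 4)
        assert back == box


class TestAugmentationParams:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AugmentationParams(darken=0.2)
        with pytest.raises(ValueError):
            AugmentationParams(wb_shift=(1.6, 1.0, 1.0))
        with pytest.raises(ValueError):
            AugmentationParams(rotate_k=5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_random_draws_respect_stated_ranges(self, seed):
        aug = AugmentationParams.random(np.random.default_rng(seed))
        assert 0.4 <= aug.darken <= 1.0
        assert 0.0 <= aug.desaturate <= 1.0
        assert all(0.6 <= g <= 1.4 for g in aug.wb_shift)
        assert aug.rotate_k in (0, 1, 2, 3)
        gains = aug.effective_gains()
        assert all(0 < g <= 1.0 for g in gains)
        assert max(gains) == pytest.approx(aug.darken)


class TestPatchDataset:
    def test_exact_balance(self):
        _, y = make_patch_dataset(100, seed=1)
        assert y.sum() == 50 and len(y) == 100

    def test_determinism(self):
        X1, y1 = make_patch_dataset(100, seed=2)
        X2, y2 = make_patch_dataset(100, seed=2)
        assert np.array_equal(X1, X2) and np.array_equal(y1, y2)

    def test_positives_keep_at_least_half_the_chart(self):
        metas = make_patch_dataset(200, seed=3, return_meta=True)[2]
        fracs = [m["visible_fraction"] for m in metas if m["label"] == 1]
        assert len(fracs) == 100
        assert min(fracs) >= 0.5

    def test_shapes_and_dtype(self):
        X, y = make_patch_dataset(10, seed=4)
        assert X.shape == (10, 125, 125, 3) and X.dtype == np.uint8

    def test_tiny_request_rejected(self):
        with pytest.raises(ValueError):
            make_patch_dataset(1, seed=0)


class TestBenchmark:
    def test_files_and_manifest_written(self, tmp_path):
        pairs = make_benchmark(3, seed=5, out_dir=tmp_path, size=(640, 960))
        assert len(pairs) == 3
        for img_path, json_path in pairs:
            assert img_path.exists() and json_path.exists()
            gt = json.loads(json_path.read_text())
            assert {"crc_box", "white_patch_center", "black_patch_center",
                    "rotation_applied", "gains_applied"} <= set(gt)
        assert (tmp_path / "manifest.csv").exists()

    def test_seed_namespaces_disjoint_from_training(self):
        # same integer seed must not reproduce the training patch stream
        X, _ = make_patch_dataset(4, seed=6)
        pairs_rng = np.random.default_rng([6, 1])
        train_rng = np.random.default_rng([6, 0])
        assert pairs_rng.integers(0, 2**31) != train_rng.integers(0, 2**31)
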