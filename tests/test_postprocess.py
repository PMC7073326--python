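import numpy as np
import pytest

from colornet.imgio import from_array
from colornet.postprocess import (
    AmbiguousQuadrantError,
    DegenerateRegionError,
    OrientationDecision,
    WhiteBalanceGains,
    apply_gains,
    compute_gains,
    orient,
    quadrant_of,
    rotation_for,
)
from colornet.synthdata import AugmentationParams, SheetSpec, render_sheet


class FakeDetection:
    def __init__(self, box):
        self._box = box

    def reported_box(self):
        return self._box


def uniform_sheet(color, size=(200, 300)):
    arr = np.zeros((size[1], size[0], 3), dtype=np.uint8)
    arr[:] = color
    return from_array(arr)


class TestComputeGains:
    def test_pure_white_region_gives_unit_gains(self):
        sheet = uniform_sheet((255, 255, 255))
        gains = compute_gains(sheet, (10, 10, 50, 50))
        assert gains.gains == (1.0, 1.0, 1.0)

    def test_closed_form_255_over_mean(self):
        sheet = uniform_sheet((204, 255, 170))
        gains = compute_gains(sheet, (0, 0, 100, 100))
        assert gains.gains == pytest.approx((1.25, 1.0, 1.5))

    def test_zero_channel_rejected(self):
        sheet = uniform_sheet((0, 128, 128))
        with pytest.raises(DegenerateRegionError):
            compute_gains(sheet, (0, 0, 20, 20))

    def test_gain_cap(self):
        sheet = uniform_sheet((1, 1, 1))
        gains = compute_gains(sheet, (0, 0, 20, 20))
        assert gains.gains == (8.0, 8.0, 8.0)


class TestApplyGains:
    def test_unit_gains_identity(self):
        sheet = uniform_sheet((120, 90, 200))
        out = apply_gains(sheet, WhiteBalanceGains((1.0, 1.0, 1.0), (0, 0, 1, 1)))
        assert np.array_equal(out.original, sheet.original)

    def test_corrected_white_region_saturates(self):
        sheet = uniform_sheet((153, 102, 204))  # a white patch seen through a cast
        gains = compute_gains(sheet, (0, 0, 50, 50))
        out = apply_gains(sheet, gains)
        means = out.original[0:50, 0:50].astype(float).mean(axis=(0, 1))
        assert (means >= 254).all()

    def test_idempotence_second_gains_near_unity(self):
        rng = np.random.default_rng(0)
        arr = np.clip(rng.normal(150, 30, (200, 200, 3)), 0, 250).astype(np.uint8)
        arr[:40, :40] = (140, 160, 120)
        sheet = from_array(arr)
        region = (0, 0, 40, 40)
        once = apply_gains(sheet, compute_gains(sheet, region))
        second = compute_gains(once, region)
        assert np.allclose(second.gains, 1.0, rtol=0.01)

    def test_darkened_render_recovers(self):
        spec = SheetSpec(crc_position=(300, 500), skew_prob=0.0, occlusion_prob=0.0,
                         seed=8, augmentation=AugmentationParams(darken=0.6))
        img, gt = render_sheet(spec)
        sheet = from_array(img)
        wx, wy = gt["white_patch_center"]
        region = (wx - 3, wy - 3, 6, 6)
        out = apply_gains(sheet, compute_gains(sheet, region))
        x0, y0 = int(wx - 3), int(wy - 3)
        assert out.original[y0 : y0 + 6, x0 : x0 + 6].astype(float).mean() >= 254


class TestQuadrants:
    @pytest.mark.parametrize("center, expected", [
        ((10, 10), "NW"), ((90, 10), "NE"), ((10, 90), "SW"), ((90, 90), "SE"),
    ])
    def test_quadrant_of(self, center, expected):
        assert quadrant_of(center, (100, 100)) == expected

    def test_center_axis_ambiguous(self):
        with pytest.raises(AmbiguousQuadrantError):
            quadrant_of((50, 20), (100, 100))

    @pytest.mark.parametrize("obs, tgt, deg", [
        ("SE", "SE", 0), ("NW", "SE", 180), ("NE", "SW", 180),
        ("NE", "SE", 270), ("SW", "SE", 90), ("NW", "NE", 270),
    ])
    def test_rotation_for(self, obs, tgt, deg):
        assert rotation_for(obs, tgt) == deg


class TestOrient:
    def _sheet_with_marker(self, quadrant):
        arr = np.full((300, 200, 3), 230, dtype=np.uint8)
        pos = {"NW": (30, 40), "NE": (150, 40), "SW": (30, 240), "SE": (150, 240)}
        x, y = pos[quadrant]
        arr[y : y + 20, x : x + 20] = 0
        return from_array(arr), FakeDetection((x, y, 20, 20))

    def test_already_in_target_no_rotation(self):
        sheet, det = self._sheet_with_marker("SE")
        out, decision = orient(sheet, det, target_quadrant="SE")
        assert decision.rotation == 0
        assert np.array_equal(out.original, sheet.original)

    def test_diagonal_gets_half_turn(self):
        sheet, det = self._sheet_with_marker("NW")
        out, decision = orient(sheet, det, target_quadrant="SE")
        assert decision.rotation == 180
        assert np.array_equal(out.original, np.rot90(sheet.original, k=2))

    def test_rotation_conserves_pixel_multiset(self):
        rng = np.random.default_rng(2)
        arr = rng.integers(0, 256, (120, 180, 3), dtype=np.uint8)
        sheet = from_array(arr)
        out, _ = orient(sheet, FakeDetection((150, 10, 20, 20)), target_quadrant="SW")
        for c in range(3):
            assert np.array_equal(
                np.bincount(arr[..., c].ravel(), minlength=256),
                np.bincount(out.original[..., c].ravel(), minlength=256),
            )

    def test_orient_twice_is_stable(self):
        sheet, det = self._sheet_with_marker("NE")
        out, decision = orient(sheet, det, target_quadrant="SE")
        assert decision.rotation in (90, 270)
        # locate the marker again on the rotated image and re-orient
        dark = np.argwhere((out.original == 0).all(axis=-1))
        y0, x0 = dark.min(axis=0)
        y1, x1 = dark.max(axis=0) + 1
        det2 = FakeDetection((x0, y0, x1 - x0, y1 - y0))
        out2, decision2 = orient(out, det2, target_quadrant="SE")
        assert decision2.rotation == 0
        assert np.array_equal(out2.original, out.original)

    def test_generator_round_trip_known_rotation(self):
        for k in range(4):
            spec = SheetSpec(crc_quadrant="SE", skew_prob=0.0, occlusion_prob=0.0,
                             seed=40 + k,
                             augmentation=AugmentationParams(rotate_k=k))
            img, gt = render_sheet(spec)
            sheet = from_array(img)
            det = FakeDetection(tuple(gt["crc_box"]))
            _, decision = orient(sheet, det, target_quadrant="SE")
            assert decision.rotation == (-k * 90) % 360
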