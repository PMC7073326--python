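import numpy as np
import pytest
from PIL import Image
from skimage.color import rgb2hsv

from colornet.imgio import (
    ImageDecodeError,
    InvalidImageError,
    from_array,
    hsv_to_rgb,
    load_image,
    save_image,
    standardize,
    to_hsv,
)


class TestLoadImage:
    def test_white_png_identity(self, tmp_path):
        path = tmp_path / "white.png"
        Image.fromarray(np.full((100, 100, 3), 255, dtype=np.uint8)).save(path)
        sheet = load_image(path)
        assert sheet.pixels.shape == (100, 100, 3)
        assert (sheet.pixels == 255).all()
        assert sheet.original_size == (100, 100)
        assert sheet.scale_factors == (1.0, 1.0)

    def test_grayscale_replicated_to_three_channels(self, tmp_path, caplog):
        path = tmp_path / "gray.png"
        arr = np.arange(100, dtype=np.uint8).reshape(10, 10)
        Image.fromarray(arr, mode="L").save(path)
        sheet = load_image(path)
        assert sheet.pixels.shape == (10, 10, 3)
        assert (sheet.pixels[..., 0] == sheet.pixels[..., 1]).all()
        assert (sheet.pixels[..., 0] == sheet.pixels[..., 2]).all()
        assert (sheet.pixels[..., 0] == arr).all()

    def test_truncated_file_raises_decode_error(self, tmp_path):
        path = tmp_path / "broken.jpg"
        good = tmp_path / "good.jpg"
        Image.fromarray(np.zeros((50, 50, 3), dtype=np.uint8)).save(good)
        path.write_bytes(good.read_bytes()[:40])
        with pytest.raises(ImageDecodeError, match="broken.jpg"):
            load_image(path)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 256, (60, 40, 3), dtype=np.uint8)
        path = tmp_path / "x.png"
        save_image(from_array(arr), path)
        assert (load_image(path).pixels == arr).all()


class TestStandardize:
    def test_archival_sheet_processing_resolution(self):
        # a 2:3 archival sheet lands exactly on the 1250 x 1875 working size
        arr = np.zeros((4500, 3000, 3), dtype=np.uint8)
        sheet = standardize(from_array(arr), 1250)
        assert sheet.processing_size == (1250, 1875)
        assert sheet.scale_factors == (2.4, 2.4)

    def test_identity_when_already_at_target(self):
        arr = np.zeros((1875, 1250, 3), dtype=np.uint8)
        sheet = standardize(from_array(arr), 1250)
        assert sheet.processing_size == (1250, 1875)
        assert sheet.scale_factors == (1.0, 1.0)
        assert sheet.pixels is sheet.original

    def test_landscape_rotated_clockwise_pixel_remap(self):
        # oracle: independent per-pixel index remap of a clockwise quarter turn
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 256, (300, 500, 3), dtype=np.uint8)  # landscape
        sheet = standardize(from_array(arr), 300)
        assert sheet.portrait_rotation_cw == 90
        assert sheet.processing_size == (300, 500)
        h0, w0 = arr.shape[:2]
        for (x, y) in [(0, 0), (499, 0), (0, 299), (123, 45), (400, 200)]:
            xr, yr = h0 - 1 - y, x
            assert (sheet.pixels[yr, xr] == arr[y, x]).all()

    def test_too_small_input_rejected(self):
        arr = np.zeros((400, 100, 3), dtype=np.uint8)
        with pytest.raises(InvalidImageError):
            standardize(from_array(arr), 1250)

    def test_box_roundtrip_within_one_pixel(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            w0 = int(rng.integers(900, 4000))
            h0 = int(rng.integers(900, 4000))
            sheet = standardize(from_array(np.zeros((h0, w0, 3), np.uint8)), 800)
            pw, ph = sheet.processing_size
            x = float(rng.uniform(0, pw - 50))
            y = float(rng.uniform(0, ph - 50))
            bw = float(rng.uniform(10, 50))
            bh = float(rng.uniform(10, 50))
            back = sheet.to_processing_box(sheet.to_original_box((x, y, bw, bh)))
            assert np.allclose(back, (x, y, bw, bh), atol=1.0)


class TestHSV:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 0, 0), (0, 255, 255)),      # pure red
            ((128, 128, 128), (0, 0, 128)),    # achromatic
            ((0, 255, 0), (85, 255, 255)),     # green: 120 deg * 255/360
        ],
    )
    def test_quantized_primaries(self, rgb, expected):
        px = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        assert tuple(int(v) for v in to_hsv(px)[0, 0]) == expected

    def test_matches_reference_conversion(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        ref = np.clip(np.rint(rgb2hsv(px) * 255.0), 0, 255).astype(int)
        assert np.abs(to_hsv(px).astype(int) - ref).max() <= 1

    def test_inverse_roundtrip_within_quantization_bound(self):
        # hue lives in 256 bins spanning 360 deg, so a saturated pixel can
        # move by up to 255 * (0.5 * 360/255) / 60 = 3 levels on reconstruction
        rng = np.random.default_rng(4)
        px = rng.integers(0, 256, (1000, 1, 3), dtype=np.uint8)
        back = hsv_to_rgb(to_hsv(px))
        err = np.abs(back.astype(int) - px.astype(int))
        assert err.max() <= 3
        assert (err <= 2).mean() > 0.99
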