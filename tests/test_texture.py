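"""Image loading, quantization, and GLCM texture extraction."""

import itertools

import numpy as np
import pytest
from PIL import Image
from skimage.feature import graycomatrix

from chemsiam import glcm, glcm_feature, load_image, quantize
from chemsiam.texture import DEFAULT_OFFSETS, GLCMExtractor, GLCMMatrix, QuantizedGrid


def brute_force_glcm(pixels, levels, offsets, symmetric):
    """Independent oracle: explicit loop over all pixel pairs."""
    h, w = pixels.shape
    counts = np.zeros((levels, levels))
    for dy, dx in offsets:
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w:
                    counts[pixels[y, x], pixels[y2, x2]] += 1
                    if symmetric:
                        counts[pixels[y2, x2], pixels[y, x]] += 1
    return counts


class TestLoadImage:
    def test_round_trip(self, tmp_path, rng):
        arr = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        p = tmp_path / "img.png"
        Image.fromarray(arr).save(p)
        assert np.array_equal(load_image(str(p)), arr)

    def test_missing_path_names_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.png"):
            load_image(str(tmp_path / "nope.png"))

    def test_grayscale_promoted_to_three_channels(self, tmp_path, rng):
        gray = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        p = tmp_path / "gray.png"
        Image.fromarray(gray, mode="L").save(p)
        out = load_image(str(p))
        assert out.shape == (16, 16, 3)
        assert np.array_equal(out[..., 0], out[..., 1])
        assert np.array_equal(out[..., 0], out[..., 2])


class TestQuantize:
    def test_black_and_white_extremes(self):
        black = np.zeros((4, 4, 3), dtype=np.uint8)
        white = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert np.all(quantize(black).pixels == 0)
        assert np.all(quantize(white).pixels == 7)

    def test_linear_gradient_one_column_per_level(self):
        # direct bin arithmetic oracle: level = floor(round(lum) * 8 / 256)
        vals = np.linspace(0, 255, 8)
        img = np.broadcast_to(vals[None, :, None], (8, 8, 3)).astype(np.uint8)
        q = quantize(img, levels=8)
        expected = np.minimum((np.rint(vals) * 8 / 256).astype(int), 7)
        assert np.array_equal(expected, np.arange(8))
        for col in range(8):
            assert np.all(q.pixels[:, col] == expected[col])

    def test_levels_below_two_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((4, 4, 3), dtype=np.uint8), levels=1)


class TestGLCM:
    def test_constant_image_single_cell(self):
        q = QuantizedGrid(levels=8, pixels=np.full((6, 6), 3))
        g = glcm(q)
        assert g.values[3, 3] == pytest.approx(1.0)
        assert g.values.sum() == pytest.approx(1.0)
        assert np.count_nonzero(g.values) == 1

    @pytest.mark.parametrize("symmetric", [True, False])
    @pytest.mark.parametrize(
        "offsets", [((0, 1),), ((1, 0), (1, 1)), DEFAULT_OFFSETS, ((2, -1),)]
    )
    def test_matches_brute_force_enumeration(self, rng, symmetric, offsets):
        for _ in range(5):
            px = rng.integers(0, 8, (5, 5))
            q = QuantizedGrid(levels=8, pixels=px)
            got = glcm(q, offsets=offsets, symmetric=symmetric, normalize=False)
            expect = brute_force_glcm(px, 8, offsets, symmetric)
            assert np.array_equal(got.values, expect)

    def test_normalized_sums_to_one_and_symmetric_mode_symmetric(self, rng):
        px = rng.integers(0, 8, (12, 9))
        g = glcm(QuantizedGrid(levels=8, pixels=px))
        assert g.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(g.values, g.values.T)

    def test_agrees_with_skimage_reference(self, rng):
        # cross-check against scikit-image for distance-1 horizontal offset
        px = rng.integers(0, 8, (10, 10)).astype(np.uint8)
        ours = glcm(
            QuantizedGrid(levels=8, pixels=px),
            offsets=((0, 1),),
            symmetric=True,
            normalize=True,
        )
        ref = graycomatrix(
            px, distances=[1], angles=[0], levels=8, symmetric=True, normed=True
        )[:, :, 0, 0]
        assert np.allclose(ours.values, ref)

    def test_transpose_convention(self, rng):
        # transposing the image and the offsets must give the same matrix
        px = rng.integers(0, 8, (7, 5))
        g1 = glcm(QuantizedGrid(8, px), offsets=((1, 2),), normalize=False)
        g2 = glcm(QuantizedGrid(8, px.T), offsets=((2, 1),), normalize=False)
        assert np.array_equal(g1.values, g2.values)

    def test_offset_errors(self):
        q = QuantizedGrid(levels=8, pixels=np.zeros((4, 4), dtype=int))
        with pytest.raises(ValueError):
            glcm(q, offsets=((0, 0),))
        with pytest.raises(ValueError):
            glcm(q, offsets=((0, 4),))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            QuantizedGrid(levels=8, pixels=np.zeros((0, 4), dtype=int))

    def test_background_masking_drops_white_pairs(self):
        px = np.full((6, 6), 7)
        px[2:4, 2:4] = 1
        masked = glcm(QuantizedGrid(8, px), mask_background=True, normalize=False)
        assert masked.values[7, 7] == 0


class TestGLCMFeature:
    def test_point_mass_vector(self):
        vals = np.zeros((8, 8))
        vals[0, 0] = 1.0
        g = GLCMMatrix(values=vals, normalized=True, offsets=((0, 1),))
        v = glcm_feature(g)
        assert v[0] == 1.0 and np.count_nonzero(v) == 1 and len(v) == 64

    def test_flatten_reshape_bijection_and_sum(self, rng):
        vals = rng.random((8, 8))
        vals /= vals.sum()
        g = GLCMMatrix(values=vals, normalized=True, offsets=((0, 1),))
        v = glcm_feature(g)
        assert np.array_equal(v.reshape(8, 8), vals)
        assert v.sum() == pytest.approx(1.0)

    def test_unnormalized_rejected(self):
        g = GLCMMatrix(values=np.ones((8, 8)), normalized=False, offsets=((0, 1),))
        with pytest.raises(ValueError, match="normalized"):
            glcm_feature(g)


class TestGLCMExtractor:
    def test_transform_shape_and_probability_rows(self, rng, tmp_path):
        imgs = [rng.integers(0, 256, (32, 32, 3), dtype=np.uint8) for _ in range(3)]
        X = GLCMExtractor().fit_transform(imgs)
        assert X.shape == (3, 64)
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_sklearn_params_round_trip(self):
        ex = GLCMExtractor(levels=4)
        assert GLCMExtractor(**ex.get_params()).levels == 4
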