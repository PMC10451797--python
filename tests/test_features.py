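"""The four soft-reference quality parameters and Otsu re-segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import cr_oracle, dice_oracle, mse_oracle, otsu_oracle, psnr_oracle
from sriqa.features import (
    FeatureVector,
    contrast_ratio,
    dice,
    extract_feature_vector,
    mse,
    otsu_segment_roi,
    otsu_threshold,
    psnr,
)
from sriqa.image import DimensionMismatchError, EmptyMaskError


def render(mask):
    return np.asarray(mask, dtype=np.uint8) * 255


class TestOtsuThreshold:
    def test_two_level_image_smallest_maximizer(self):
        img = np.array([[10] * 8, [200] * 8], dtype=np.uint8)
        # any t in [10, 199] separates the classes; tie-break -> 10
        assert otsu_threshold(img) == 10

    def test_constant_image_warns_and_returns_value(self):
        with pytest.warns(UserWarning, match="constant"):
            assert otsu_threshold(np.full((5, 5), 77, np.uint8)) == 77

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            assert otsu_threshold(img) == otsu_oracle(img)

    def test_agrees_with_skimage_on_bimodal_image(self, rng):
        from skimage.filters import threshold_otsu

        img = np.concatenate(
            [rng.normal(60, 10, 500), rng.normal(180, 10, 500)]
        ).clip(0, 255).astype(np.uint8).reshape(25, 40)
        t_ours = otsu_threshold(img)
        t_ski = threshold_otsu(img)
        assert abs(t_ours - t_ski) <= 1  # conventions differ by <= one bin


class TestOtsuSegmentRoi:
    def test_dark_disk_recovered_exactly(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        img = np.where(disk, 40, 180).astype(np.uint8)
        np.testing.assert_array_equal(otsu_segment_roi(img, median_size=0), disk)

    def test_median_prefilter_preserves_clean_disk_body(self):
        from sriqa.features import dice as dice_fn

        yy, xx = np.mgrid[0:40, 0:40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        img = np.where(disk, 40, 180).astype(np.uint8)
        seg = otsu_segment_roi(img)  # default despeckling on
        assert dice_fn(seg, disk) > 0.97

    def test_largest_component_kept(self):
        img = np.full((20, 30), 200, np.uint8)
        img[2:6, 2:6] = 30  # 16 px blob
        img[10:18, 10:24] = 30  # 112 px blob
        seg = otsu_segment_roi(img, largest_component_only=True)
        assert seg[12, 12] and not seg[3, 3]
        seg_all = otsu_segment_roi(img, largest_component_only=False)
        assert seg_all[3, 3]

    def test_all_bright_roi_gives_empty_or_tiny_foreground(self):
        img = np.full((10, 10), 200, np.uint8)
        with pytest.warns(UserWarning):
            seg = otsu_segment_roi(img)
        # constant image: everything <= its own value -> all fg is acceptable
        # only contract: result is a boolean mask of same shape
        assert seg.shape == img.shape and seg.dtype == np.bool_


class TestPixelMetrics:
    def test_identical_masks(self):
        m = np.eye(4, dtype=bool)
        assert mse(render(m), render(m)) == 0.0
        assert psnr(render(m), render(m)) == 100.0
        assert dice(m, m) == 1.0

    def test_complementary_masks(self):
        a = np.zeros((2, 2), dtype=bool)
        b = np.ones((2, 2), dtype=bool)
        assert mse(render(a), render(b)) == 65025.0
        assert psnr(render(a), render(b)) == pytest.approx(0.0)
        assert dice(a, b) == 0.0

    def test_single_pixel_difference(self):
        a = np.zeros((2, 2), dtype=bool)
        b = a.copy()
        b[0, 0] = True
        assert mse(render(a), render(b)) == pytest.approx(16256.25)

    def test_psnr_closed_form_example(self):
        # MSE = 650.25 -> PSNR = 10*log10(65025/650.25) = 20 dB
        a = np.zeros((100, 1))
        b = a.copy()
        b[:1] = 255.0  # mismatch fraction 1/100 -> MSE 650.25
        assert psnr(a, b) == pytest.approx(20.0)

    @pytest.mark.parametrize("h", [0.25, 0.1, 0.5])
    def test_binary_mask_identity(self, h):
        """For 0/255 masks: MSE = 65025*h and PSNR = -10*log10(h)."""
        n = 20
        k = int(h * n * n)
        a = np.zeros((n, n), dtype=bool)
        b = a.copy()
        b.ravel()[:k] = True
        assert mse(render(a), render(b)) == pytest.approx(65025.0 * h)
        assert psnr(render(a), render(b)) == pytest.approx(-10.0 * np.log10(h))

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            mse(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(DimensionMismatchError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_oracle_equivalence_on_random_inputs(self, rng):
        for _ in range(100):
            a = rng.integers(0, 256, (16, 16))
            b = rng.integers(0, 256, (16, 16))
            ma = rng.random((16, 16)) > 0.5
            mb = rng.random((16, 16)) > 0.5
            assert mse(a, b) == pytest.approx(mse_oracle(a, b), abs=1e-9)
            assert psnr(a, b) == pytest.approx(psnr_oracle(a, b), abs=1e-9)
            assert dice(ma, mb) == pytest.approx(dice_oracle(ma, mb), abs=1e-9)
            if 0 < ma.sum() < ma.size:
                assert contrast_ratio(a, ma) == pytest.approx(
                    cr_oracle(a, ma), abs=1e-9
                )


class TestContrastRatio:
    def test_hand_means(self):
        img = np.zeros((2, 2))
        mask = np.array([[True, True], [False, False]])
        img[0] = 50.0
        img[1] = 150.0
        assert contrast_ratio(img, mask) == pytest.approx(100.0 / 255.0)

    def test_no_contrast(self):
        img = np.full((3, 3), 90.0)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert contrast_ratio(img, mask) == 0.0

    def test_maximal_contrast(self):
        mask = np.array([[True, False]])
        img = np.array([[0.0, 255.0]])
        assert contrast_ratio(img, mask) == 1.0

    def test_degenerate_roi_rejected(self):
        img = np.zeros((2, 2))
        with pytest.raises(ValueError):
            contrast_ratio(img, np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            contrast_ratio(img, np.zeros((2, 2), dtype=bool))


class TestDiceProperties:
    def test_partial_overlap_counts(self):
        a = np.zeros((3, 4), dtype=bool)
        b = np.zeros((3, 4), dtype=bool)
        a.ravel()[:4] = True
        b.ravel()[1:7] = True  # |A|=4, |B|=6, overlap 3
        assert dice(a, b) == pytest.approx(0.6)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((10, 10)) > 0.6
        b = rng.random((10, 10)) > 0.6
        assert dice(a, b) == dice(b, a)
        assert dice(np.roll(a, 3, axis=1), np.roll(b, 3, axis=1)) == pytest.approx(
            dice(a, b)
        )

    def test_disjoint_masks(self):
        a = np.zeros((2, 2), dtype=bool)
        b = np.zeros((2, 2), dtype=bool)
        a[0, 0] = True
        b[1, 1] = True
        assert dice(a, b) == 0.0

    def test_both_empty_defined_as_one(self):
        e = np.zeros((2, 2), dtype=bool)
        assert dice(e, e) == 1.0


class TestExtractFeatureVector:
    def test_perfect_agreement_limit(self):
        """Noise-free dark ellipse: Otsu recovers the truth mask exactly."""
        yy, xx = np.mgrid[0:60, 0:60]
        disk = (yy - 30) ** 2 / 150 + (xx - 30) ** 2 / 80 <= 1
        img = np.where(disk, 40, 180).astype(np.uint8)
        fv = extract_feature_vector(img, disk, margin_fraction=0.25, median_size=0)
        assert fv.mse == 0.0
        assert fv.psnr == 100.0
        assert fv.ssim == 1.0
        assert fv.cr == pytest.approx(140.0 / 255.0)

    def test_empty_reference_mask_routes_away(self):
        with pytest.raises(EmptyMaskError):
            extract_feature_vector(
                np.zeros((8, 8), np.uint8), np.zeros((8, 8), dtype=bool)
            )

    def test_returns_feature_vector_fields(self, rng):
        from sriqa.phantom import PhantomSpec, generate_phantom

        rec = generate_phantom(PhantomSpec(), 3, seed=7)
        fv = extract_feature_vector(rec.image, rec.mask)
        assert isinstance(fv, FeatureVector)
        assert fv.mse >= 0 and 0 <= fv.ssim <= 1
        assert fv.psnr <= 100.0
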