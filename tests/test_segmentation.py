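"""Unit and property tests of the particle-counting pipeline stages."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_otsu as sk_threshold_otsu

from wpbquant.segmentation import (
    FieldImage,
    PipelineParams,
    SegmentationError,
    auto_contrast,
    auto_threshold,
    count_field,
    filter_particles,
    label_particles,
    project_stack,
    to_8bit,
)


def random_uint8(rng, shape=(64, 64)):
    """Bimodal-ish random 8-bit image (background + bright patches)."""
    img = rng.normal(60, 20, shape)
    n_spots = rng.integers(1, 8)
    for _ in range(n_spots):
        y, x = rng.integers(5, shape[0] - 5, 2)
        img[y - 3 : y + 3, x - 3 : x + 3] += rng.uniform(80, 160)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# project_stack


class TestProjectStack:
    def test_single_slice_max_is_identity(self, rng):
        stack = rng.random((1, 16, 16))
        np.testing.assert_array_equal(project_stack(stack, "max"), stack[0])

    def test_max_with_zero_slice_equals_other(self, rng):
        plane = rng.random((16, 16))
        stack = np.stack([np.zeros_like(plane), plane])
        np.testing.assert_array_equal(project_stack(stack, "max"), plane)

    def test_max_dominates_every_slice_pixelwise(self, rng):
        stack = rng.random((6, 12, 12))
        proj = project_stack(stack, "max")
        # brute-force pixel-loop oracle
        for z in range(stack.shape[0]):
            for y in range(stack.shape[1]):
                for x in range(stack.shape[2]):
                    assert proj[y, x] >= stack[z, y, x]

    def test_per_slice_returns_slices_unchanged(self, rng):
        stack = rng.random((4, 8, 8))
        planes = project_stack(stack, "per_slice")
        assert len(planes) == 4
        for z, p in enumerate(planes):
            np.testing.assert_array_equal(p, stack[z])

    def test_empty_stack_rejected(self):
        with pytest.raises(SegmentationError):
            project_stack(np.zeros((0, 4, 4)), "max")


# ---------------------------------------------------------------------------
# auto_contrast / to_8bit


class TestContrast:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 42.0)
        np.testing.assert_array_equal(auto_contrast(img), img)

    def test_zero_saturation_is_affine_stretch(self):
        img = np.linspace(10, 90, 81).reshape(9, 9)
        out = auto_contrast(img, saturated_fraction=0.0)
        np.testing.assert_allclose(out, (img - 10) / 80 * 255, atol=1e-9)

    def test_order_preserved_on_unclipped_pixels(self, rng):
        img = rng.normal(100, 30, (40, 40))
        out = auto_contrast(img, 0.01)
        unclipped = (out > 0) & (out < 255)
        a, b = img[unclipped], out[unclipped]
        # oracle: sorting either array induces the same permutation
        np.testing.assert_array_equal(np.argsort(a, kind="stable"), np.argsort(b, kind="stable"))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            auto_contrast(np.zeros((4, 4)), 0.5)

    def test_to_8bit_endpoints_and_bounds(self, rng):
        img = rng.normal(0, 50, (30, 30))
        out = to_8bit(img)
        assert out.dtype == np.uint8
        assert out.min() == 0 and out.max() == 255

    def test_to_8bit_identity_on_full_range(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        np.testing.assert_array_equal(to_8bit(img), img)

    def test_to_8bit_two_valued(self):
        img = np.array([[7, 7], [19, 19]], dtype=float)
        out = to_8bit(img)
        assert set(out.ravel()) == {0, 255}

    def test_to_8bit_constant_maps_to_zero(self):
        np.testing.assert_array_equal(to_8bit(np.full((4, 4), 9.0)), 0)


# ---------------------------------------------------------------------------
# auto_threshold


def exhaustive_otsu_set(image):
    """Independent oracle: all 256 levels tied for the maximal
    between-class variance (several levels tie when the histogram bins
    between them are empty — identical class partitions)."""
    flat = image.ravel().astype(np.float64)
    variances = np.full(256, -1.0)
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        variances[t] = w0 * w1 * (lo.mean() - hi.mean()) ** 2
    return set(np.flatnonzero(variances == variances.max()).tolist())


class TestAutoThreshold:
    @pytest.mark.parametrize("method", ["isodata", "otsu"])
    def test_bimodal_separation(self, method):
        img = np.zeros((30, 30), dtype=np.uint8)
        img[:3, :] = 255  # 10% bright
        t, mask = auto_threshold(img, method)
        assert 0 < t < 255
        np.testing.assert_array_equal(mask, img == 255)

    @pytest.mark.parametrize("method", ["isodata", "otsu"])
    def test_constant_image_empty_mask(self, method):
        img = np.full((8, 8), 99, dtype=np.uint8)
        t, mask = auto_threshold(img, method)
        assert t == 99
        assert not mask.any()

    def test_otsu_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            img = random_uint8(rng)
            t, _ = auto_threshold(img, "otsu")
            assert t in exhaustive_otsu_set(img)

    def test_otsu_agrees_with_skimage_up_to_tie_convention(self, rng):
        for _ in range(20):
            img = random_uint8(rng)
            t, _ = auto_threshold(img, "otsu")
            maximizers = exhaustive_otsu_set(img)
            assert t in maximizers
            assert int(sk_threshold_otsu(img)) in maximizers

    def test_isodata_is_intermeans_fixed_point(self, rng):
        for _ in range(20):
            img = random_uint8(rng)
            t, _ = auto_threshold(img, "isodata")
            flat = img.ravel().astype(float)
            lo, hi = flat[flat <= t], flat[flat > t]
            assert t == int(round((lo.mean() + hi.mean()) / 2))

    def test_binarization_idempotent(self, rng):
        img = (rng.random((40, 40)) < 0.2).astype(np.uint8) * 255
        if img.max() == img.min():
            img[0, 0] = 255
        _, mask = auto_threshold(img, "isodata")
        np.testing.assert_array_equal(mask, img == 255)
        remasked = auto_threshold((mask * 255).astype(np.uint8), "isodata")[1]
        np.testing.assert_array_equal(remasked, mask)

    def test_non_uint8_rejected(self):
        with pytest.raises(SegmentationError):
            auto_threshold(np.zeros((4, 4), dtype=float), "otsu")


# ---------------------------------------------------------------------------
# label_particles / filter_particles


class TestLabelParticles:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        ps = label_particles(mask)
        assert len(ps) == 2

    def test_large_disc_is_circular(self):
        yy, xx = np.mgrid[:101, :101]
        mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 40**2
        (p,) = label_particles(mask).particles
        assert p.circularity > 0.9

    def test_square_circularity_near_pi_over_4(self):
        mask = np.zeros((110, 110), dtype=bool)
        mask[5:105, 5:105] = True
        (p,) = label_particles(mask).particles
        # digital perimeter bias documented at +-10% -> ~20% on circularity
        assert p.circularity == pytest.approx(math.pi / 4, rel=0.2)

    def test_rod_circularity_near_analytic(self):
        # 5 um x 0.3 um rectangle at 0.05 um/px: A=1.5 um^2, P=10.6 um,
        # circularity = 4*pi*1.5/10.6^2 ~= 0.168
        mask = np.zeros((20, 110), dtype=bool)
        mask[7:13, 5:105] = True
        (p,) = label_particles(mask, pixel_size_um=0.05).particles
        assert p.area_um2 == pytest.approx(1.5, rel=1e-9)
        analytic = 4 * math.pi * 1.5 / 10.6**2
        assert p.circularity == pytest.approx(analytic, rel=0.2)
        # the reported circularity is exactly 4*pi*A/P^2 of the measurements
        assert p.circularity == pytest.approx(
            4 * math.pi * p.area_um2 / p.perimeter_um**2, rel=1e-12
        )

    def test_disc_more_circular_than_equal_area_rod(self):
        yy, xx = np.mgrid[:40, :40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2  # ~314 px
        rod = np.zeros((20, 120), dtype=bool)
        rod[8:11, 4:109]= True  # 315 px
        (pd,) = label_particles(disc).particles
        (pr,) = label_particles(rod).particles
        assert pd.circularity > pr.circularity

    def test_connectivity_4_vs_8_on_diagonal(self):
        mask = np.eye(5, dtype=bool)
        assert len(label_particles(mask, connectivity=8)) == 1
        assert len(label_particles(mask, connectivity=4)) == 5

    def test_empty_mask(self):
        assert len(label_particles(np.zeros((5, 5), dtype=bool))) == 0


class TestFilterParticles:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0, 1), st.floats(0, 1))
    def test_subset_and_idempotent(self, seed, c1, c2):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.15
        ps = label_particles(mask, pixel_size_um=0.2)
        lo, hi = min(c1, c2), max(c1, c2)
        out = filter_particles(ps, 0.05, 5.0, lo, hi)
        assert set(out.particles) <= set(ps.particles)
        again = filter_particles(out, 0.05, 5.0, lo, hi)
        assert again.particles == out.particles

    def test_full_range_is_identity(self, rng):
        mask = rng.random((32, 32)) < 0.2
        ps = label_particles(mask)
        out = filter_particles(ps, 0.0, float("inf"), 0.0, 1.0)
        assert out.particles == ps.particles

    def test_circularity_cut_separates_disc_from_rod(self):
        canvas = np.zeros((60, 160), dtype=bool)
        yy, xx = np.mgrid[:60, :160]
        canvas[(yy - 30) ** 2 + (xx - 30) ** 2 <= 12**2] = True
        canvas[28:33, 60:150] = True  # rod
        ps = label_particles(canvas)
        assert len(ps) == 2
        kept = filter_particles(ps, 0, float("inf"), 0, 0.8)
        assert len(kept) == 1
        assert kept.particles[0].circularity < 0.8

    def test_empty_input_empty_output(self):
        ps = label_particles(np.zeros((4, 4), dtype=bool))
        assert len(filter_particles(ps, 0, 1, 0, 1)) == 0


# ---------------------------------------------------------------------------
# count_field


class TestCountField:
    def test_counts_match_ground_truth(self, small_field, small_field_counts):
        spec, _, truth = small_field
        counts, _, _ = small_field_counts
        assert counts.nuclei_count == truth.nucleus_count == spec.nucleus_count
        assert counts.wpb_count == truth.wpb_count == spec.wpb_count

    def test_deterministic(self, small_field, small_field_counts):
        _, image, _ = small_field
        counts1, _, _ = small_field_counts
        counts2, _, _ = count_field(image)
        assert counts1 == counts2

    def test_empty_scene_counts_zero(self):
        zeros = np.zeros((3, 64, 64), dtype=np.float32)
        field = FieldImage(zeros, zeros.copy(), pixel_size_um=0.11, z_step_um=0.3)
        counts, _, _ = count_field(field)
        assert (counts.nuclei_count, counts.wpb_count) == (0, 0)

    def test_per_slice_mode_runs(self, small_field):
        _, image, truth = small_field
        counts, _, _ = count_field(image, PipelineParams(projection="per_slice"))
        # per-slice counting sums over slices, so it can only see each
        # object at least once
        assert counts.nuclei_count >= truth.nucleus_count

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FieldImage(
                np.zeros((2, 8, 8)), np.zeros((2, 8, 9)), pixel_size_um=0.1, z_step_um=0.3
            )
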