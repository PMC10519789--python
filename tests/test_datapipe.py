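"""Splitting, online augmentations and photometric robustness transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcaeffnet.datapipe import (AugmentationConfig, cutout, grid_mask,
                                photometric_transform, random_erasing,
                                robustness_protocol, split_counts_for_total,
                                split_dataset, to_model_input)

# published per-class distribution of the corn corpus: name -> (total, train,
# valid, test); every row except rust_leaf follows half-up 8:1:1 rounding
CORPUS_ROWS = {
    "fall_armyworm": (432, 346, 43, 43),
    "gray_leaf_spot": (613, 491, 61, 61),
    "leaf_blight": (688, 550, 69, 69),
    "leaf_healthy": (537, 429, 54, 54),
    "northern_leaf_spot": (551, 441, 55, 55),
    "rust_leaf": (437, 351, 43, 43),
}


class TestSplitCounts:
    def test_fall_armyworm_row(self):
        assert split_counts_for_total(432) == (346, 43, 43)

    def test_rule_reproduces_five_of_six_published_rows(self):
        matches = {name: split_counts_for_total(total) == (tr, va, te)
                   for name, (total, tr, va, te) in CORPUS_ROWS.items()}
        assert sum(matches.values()) == 5
        assert not matches["rust_leaf"]     # 437 rounds to 44/44, printed 43/43

    def test_explicit_counts_reproduce_full_published_table(self):
        items = {name: [f"{name}/{i}" for i in range(row[0])]
                 for name, row in CORPUS_ROWS.items()}
        explicit = {name: row[1:] for name, row in CORPUS_ROWS.items()}
        counts, assignment = split_dataset(items, seed=0,
                                           explicit_counts=explicit)
        for name, (_, tr, va, te) in CORPUS_ROWS.items():
            assert counts.row(name) == (tr, va, te)
        assert len(assignment) == sum(r[0] for r in CORPUS_ROWS.values())

    def test_degenerate_ratio_puts_everything_in_train(self):
        assert split_counts_for_total(57, (1.0, 0.0, 0.0)) == (57, 0, 0)

    @given(st.integers(3, 2000))
    @settings(max_examples=60, deadline=None)
    def test_counts_always_partition_the_class(self, n):
        tr, va, te = split_counts_for_total(n)
        assert tr + va + te == n and min(tr, va, te) >= 0

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_dataset({"a": [1, 2]})


class TestSplitAssignment:
    def test_partition_no_overlap_and_deterministic(self):
        items = {"a": [f"a{i}" for i in range(50)],
                 "b": [f"b{i}" for i in range(41)]}
        counts, asg1 = split_dataset(items, seed=9)
        _, asg2 = split_dataset(items, seed=9)
        assert asg1 == asg2                       # seeded permutation
        assert set(asg1) == set(items["a"]) | set(items["b"])
        for cls, lst in items.items():
            subsets = [asg1[i] for i in lst]
            assert subsets.count("train") == counts.row(cls)[0]
            assert subsets.count("valid") == counts.row(cls)[1]
            assert subsets.count("test") == counts.row(cls)[2]

    def test_different_seed_changes_assignment(self):
        items = {"a": list(range(40))}
        _, asg1 = split_dataset(items, seed=1)
        _, asg2 = split_dataset(items, seed=2)
        assert asg1 != asg2


class TestCutout:
    def test_size_zero_is_identity(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        assert np.array_equal(cutout(img, 0, rng), img)

    def test_interior_region_zeroes_exactly_size_squared_pixels(self):
        img = np.full((64, 64, 3), 255, np.uint8)
        for seed in range(50):   # find a deterministic fully-interior draw
            out = cutout(img, 16, np.random.default_rng(seed))
            zeros = int((out == 0).all(axis=2).sum())
            assert zeros <= 16 * 16          # overhang can only shrink it
            if zeros == 16 * 16:
                ys, xs = np.where((out == 0).all(axis=2))
                assert ys.max() - ys.min() == 15 and xs.max() - xs.min() == 15
                untouched = (out == 255).all(axis=2).sum()
                assert untouched == 64 * 64 - 256
                return
        pytest.fail("no interior placement found in 50 seeded draws")

    def test_region_is_filled_with_zeros_only(self, rng):
        img = rng.integers(1, 256, (40, 40, 3), dtype=np.uint8)
        out = cutout(img, 12, rng)
        changed = (out != img).any(axis=2)
        assert (out[changed] == 0).all()

    def test_oversized_region_rejected(self, rng):
        with pytest.raises(ValueError):
            cutout(np.zeros((16, 16, 3), np.uint8), 20, rng)


class TestGridMask:
    def test_zero_ratio_is_identity(self, rng):
        img = rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)
        assert np.array_equal(grid_mask(img, 0.0, 16, rng), img)

    def test_masked_fraction_matches_period_quantised_ratio(self, rng):
        img = np.full((64, 64, 3), 200, np.uint8)
        ratio, period = 0.5, 16
        out = grid_mask(img, ratio, period, rng)
        frac = (out == 0).all(axis=2).mean()
        side = round(ratio * period)
        assert frac == pytest.approx((side / period) ** 2, abs=1e-9)

    def test_output_is_mask_times_image(self, rng):
        img = rng.integers(1, 256, (32, 32, 3), dtype=np.uint8)
        out = grid_mask(img, 0.4, 8, rng)
        assert out.shape == img.shape       # mask has the image's resolution
        zeroed = (out == 0).all(axis=2)
        assert np.array_equal(out[~zeroed], img[~zeroed])

    def test_invalid_parameters_rejected(self, rng):
        img = np.zeros((8, 8, 3), np.uint8)
        with pytest.raises(ValueError):
            grid_mask(img, 1.5, 8, rng)
        with pytest.raises(ValueError):
            grid_mask(img, 0.5, 1, rng)


class TestRandomErasing:
    def test_zero_probability_is_identity(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        assert np.array_equal(random_erasing(img, 0.0, (0.02, 0.33), rng), img)

    def test_same_seed_gives_identical_output(self):
        img = np.random.default_rng(0).integers(0, 256, (32, 32, 3), dtype=np.uint8)
        a = random_erasing(img, 1.0, (0.1, 0.3), np.random.default_rng(5))
        b = random_erasing(img, 1.0, (0.1, 0.3), np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_erased_area_fraction_within_configured_range(self):
        img = np.zeros((64, 64, 3), np.uint8)   # random fill is visible on zeros
        lo, hi = 0.1, 0.3
        for seed in range(5):
            out = random_erasing(img, 1.0, (lo, hi), np.random.default_rng(seed))
            changed = (out != img).any(axis=2)
            ys, xs = np.where(changed)
            area = (ys.max() - ys.min() + 1) * (xs.max() - xs.min() + 1)
            assert lo * 64 * 64 * 0.8 <= area <= hi * 64 * 64 * 1.2


class TestPhotometric:
    def test_unit_factor_is_identity(self, rng):
        img = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
        for kind in ("brightness", "contrast"):
            assert np.array_equal(photometric_transform(img, kind, 1.0), img)

    def test_brightness_doubles_when_no_clipping(self, rng):
        img = rng.integers(0, 128, (24, 24, 3), dtype=np.uint8)
        out = photometric_transform(img, "brightness", 2.0)
        assert np.array_equal(out, (img.astype(np.int32) * 2).astype(np.uint8))

    def test_contrast_pivots_on_image_mean(self):
        img = np.full((8, 8, 3), 100, np.uint8)
        img[0, 0] = 150
        out = photometric_transform(img, "contrast", 0.5).astype(np.float64)
        mean = img.astype(np.float64).mean()
        expected = np.clip(mean + 0.5 * (img - mean), 0, 255).round()
        np.testing.assert_array_equal(out, expected)

    def test_values_clip_to_pixel_range(self):
        img = np.full((8, 8, 3), 200, np.uint8)
        out = photometric_transform(img, "brightness", 2.0)
        assert out.max() == 255

    def test_protocol_enumerates_eight_perturbed_sets(self):
        combos = robustness_protocol()
        assert len(combos) == 8
        assert {k for k, _ in combos} == {"brightness", "contrast"}
        assert sorted({f for _, f in combos}) == [0.5, 0.67, 1.5, 2.0]

    def test_invalid_inputs_rejected(self, rng):
        img = np.zeros((4, 4, 3), np.uint8)
        with pytest.raises(ValueError):
            photometric_transform(img, "brightness", 0.0)
        with pytest.raises(ValueError):
            photometric_transform(img, "hue", 1.5)


class TestShapeAndRangePreservation:
    @pytest.mark.parametrize("aug", ["cutout", "gridmask", "erasing"])
    def test_augmentations_preserve_shape_and_dtype(self, rng, aug):
        img = rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)
        if aug == "cutout":
            out = cutout(img, 16, rng)
        elif aug == "gridmask":
            out = grid_mask(img, 0.4, 12, rng)
        else:
            out = random_erasing(img, 1.0, (0.05, 0.2), rng)
        assert out.shape == img.shape and out.dtype == img.dtype

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AugmentationConfig(gridmask_ratio=1.5)
        with pytest.raises(ValueError):
            AugmentationConfig(erase_area_range=(0.5, 0.2))

    def test_model_input_standardisation(self, rng):
        img = rng.integers(0, 256, (2, 16, 16, 3), dtype=np.uint8)
        x = to_model_input(img)
        assert x.shape == (2, 3, 16, 16) and x.dtype == np.float32
        assert x.min() >= -1.0 and x.max() <= 1.0
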