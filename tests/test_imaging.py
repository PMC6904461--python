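"""Feature measurement, filtering, preprocessing, augmentation, the
synthetic pool and nearest-feature matching."""

import numpy as np
import pandas as pd
import pytest

from collidernet.imaging import (
    CROP_SIZE,
    PATCH_SIZE,
    ImagePatch,
    ImagePool,
    augment,
    filter_pool,
    generate_synthetic_pool,
    match_images,
    measure_heterogeneity,
    measure_size,
    preprocess,
)
from collidernet.scm import sample_cohort


def _patch(pixels, mask, spacing=1.0, **kw):
    return ImagePatch(np.asarray(pixels, float), np.asarray(mask, bool), spacing, **kw)


def _square_patch(side=10, spacing=0.7, value=1.0):
    return _patch(np.full((side, side), value), np.ones((side, side)), spacing)


class TestMeasurement:
    def test_size_is_count_times_pixel_area(self):
        assert measure_size(_square_patch(10, 0.7)) == pytest.approx(49.0)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert measure_size(_patch(np.zeros((5, 5)), mask, 1.0)) == 1.0

    def test_size_invariant_to_mirroring(self, rng):
        mask = rng.uniform(size=(8, 8)) > 0.5
        mask[0, 0] = True
        p = _patch(rng.normal(size=(8, 8)), mask, 0.7)
        q = _patch(p.pixels[:, ::-1], mask[:, ::-1], 0.7)
        assert measure_size(p) == measure_size(q)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ImagePatch(np.zeros((4, 4)), np.zeros((4, 4), bool))

    def test_heterogeneity_constant_is_zero(self):
        assert measure_heterogeneity(_square_patch(value=3.3)) == 0.0

    def test_heterogeneity_population_variance(self):
        mask = np.zeros((2, 2), bool)
        mask[0, :] = True
        p = _patch([[0.0, 2.0], [9.0, 9.0]], mask)
        assert measure_heterogeneity(p) == pytest.approx(1.0)  # divide by N

    def test_heterogeneity_ignores_background(self, rng):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        base = rng.normal(size=(6, 6))
        p = _patch(base, mask)
        perturbed = base.copy()
        perturbed[~mask] += rng.normal(size=(~mask).sum()) * 10
        q = _patch(perturbed, mask)
        assert measure_heterogeneity(p) == measure_heterogeneity(q)

    def test_heterogeneity_needs_two_pixels(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        with pytest.raises(ValueError):
            measure_heterogeneity(_patch(np.ones((3, 3)), mask))


class TestFilterPool:
    def _pool_with_sizes(self, sizes_mm2, spacing=1.0):
        out = []
        for s in sizes_mm2:
            n = int(round(s / spacing**2))
            mask = np.zeros((40, 40), bool)
            mask.ravel()[:n] = True
            out.append(_patch(np.zeros((40, 40)), mask, spacing))
        return out

    def test_strict_boundary(self):
        pool = self._pool_with_sizes([19.0, 20.0, 25.0])
        kept = filter_pool(pool, min_size_mm2=20.0, require_all_annotators=False)
        assert [measure_size(p) for p in kept] == [20.0, 25.0]

    def test_all_below_threshold_gives_empty(self):
        pool = self._pool_with_sizes([5.0, 10.0])
        assert filter_pool(pool, 20.0, False) == []

    def test_idempotent_and_subset(self):
        pool = self._pool_with_sizes([10.0, 30.0, 50.0])
        once = filter_pool(pool, 20.0, False)
        twice = filter_pool(once, 20.0, False)
        assert once == twice
        assert all(p in pool for p in once)

    def test_annotator_agreement(self):
        pool = self._pool_with_sizes([30.0, 30.0])
        pool[0].n_annotations = 4
        pool[1].n_annotations = 2
        kept = filter_pool(pool, 20.0, require_all_annotators=True, annotator_count=4)
        assert kept == [pool[0]]


class TestPreprocess:
    def test_output_geometry(self, rng):
        px = rng.normal(size=(200, 200))
        mask = np.zeros((200, 200), bool)
        mask[90:110, 90:110] = True
        p = preprocess(px, mask, native_spacing_mm=0.7)
        assert p.pixels.shape == (PATCH_SIZE, PATCH_SIZE)
        assert p.spacing_mm == 0.7
        assert not p.padded

    def test_resampling_identity_at_native_spacing(self, rng):
        px = rng.normal(size=(150, 150))
        mask = np.zeros((150, 150), bool)
        mask[70:80, 70:80] = True
        p = preprocess(px, mask, native_spacing_mm=0.7)
        # centroid at (74.5, 74.5) -> rounds to 74; window [24, 124)
        np.testing.assert_allclose(p.pixels, px[24:124, 24:124])

    def test_border_nodule_padded_and_flagged(self, rng):
        px = rng.normal(size=(120, 120))
        mask = np.zeros((120, 120), bool)
        mask[2:8, 2:8] = True
        p = preprocess(px, mask, native_spacing_mm=0.7)
        assert p.padded
        assert p.pixels.shape == (PATCH_SIZE, PATCH_SIZE)

    def test_normalization_constants_applied(self, rng):
        px = rng.normal(5.0, 2.0, size=(150, 150))
        mask = np.zeros((150, 150), bool)
        mask[70:80, 70:80] = True
        p = preprocess(px, mask, 0.7, norm_mean=5.0, norm_sd=2.0)
        assert abs(p.pixels.mean()) < 0.1
        assert p.pixels.std() == pytest.approx(1.0, abs=0.1)


class TestAugment:
    def test_eval_deterministic_center_crop(self, rng):
        px = rng.normal(size=(PATCH_SIZE, PATCH_SIZE))
        a = augment(px, "eval")
        b = augment(px, "eval")
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a, px[25:76, 25:76])

    def test_output_shape_and_constant_image(self, rng):
        out = augment(np.ones((PATCH_SIZE, PATCH_SIZE)), "train", rng)
        assert out.shape == (CROP_SIZE, CROP_SIZE)
        assert (out == 1.0).all()

    def test_train_crop_is_a_window_of_input(self, rng):
        px = rng.normal(size=(PATCH_SIZE, PATCH_SIZE))
        out = augment(px, "train", np.random.default_rng(5))
        # undo possible flips and search for the window
        candidates = [out, out[::-1], out[:, ::-1], out[::-1, ::-1]]
        found = False
        for cand in candidates:
            for i in range(PATCH_SIZE - CROP_SIZE + 1):
                for j in range(PATCH_SIZE - CROP_SIZE + 1):
                    if np.array_equal(px[i : i + CROP_SIZE, j : j + CROP_SIZE], cand):
                        found = True
        assert found

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            augment(np.ones((40, 40)), "eval")


class TestSyntheticPool:
    def test_measured_features_track_targets(self, small_pool):
        f = small_pool.features
        assert np.corrcoef(f.target_area_mm2, f.x_prime)[0, 1] > 0.99
        assert np.corrcoef(f.target_variance, f.z_prime)[0, 1] > 0.95

    def test_single_patch_measures_back(self):
        pool = generate_synthetic_pool(
            1, size_range_mm2=(100.0, 100.0), hetero_range=(0.5, 0.5), seed=4
        )
        assert pool.features.x_prime.iloc[0] == pytest.approx(100.0, rel=0.05)

    def test_deterministic_for_fixed_seed(self):
        a = generate_synthetic_pool(5, seed=9)
        b = generate_synthetic_pool(5, seed=9)
        for pa, pb in zip(a.patches, b.patches):
            np.testing.assert_array_equal(pa.pixels, pb.pixels)
            np.testing.assert_array_equal(pa.mask, pb.mask)
        pd.testing.assert_frame_equal(a.features, b.features)

    def test_oversized_range_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_synthetic_pool(3, size_range_mm2=(20.0, 50_000.0), seed=0)

    def test_splits_disjoint_and_constants_from_train(self, small_pool):
        f = small_pool.features
        assert set(f.split.unique()) == {"train", "validation"}
        train = f[f.split == "train"]
        lx = np.log(train.x_prime.to_numpy())
        assert small_pool.log_stats["mu_log_x"] == pytest.approx(lx.mean())
        assert small_pool.log_stats["sd_log_x"] == pytest.approx(lx.std())

    def test_roundtrip_serialization(self, small_pool, tmp_path):
        small_pool.save(tmp_path / "pool")
        loaded = ImagePool.load(tmp_path / "pool")
        assert len(loaded.patches) == len(small_pool.patches)
        np.testing.assert_array_equal(
            loaded.patches[7].pixels, small_pool.patches[7].pixels
        )
        assert loaded.log_stats["mu_log_x"] == small_pool.log_stats["mu_log_x"]


class TestMatching:
    def test_exact_match_selected(self, small_pool):
        std = small_pool.standardized_features(small_pool.split_indices("train"))
        cohort = pd.DataFrame(
            {"x": [std[17, 0]], "z": [std[17, 1]], "t": [1], "y": [0.0],
             "u1": [0.0], "u2": [0.0]}
        )
        matched = match_images(cohort, small_pool, split="train")
        assert matched.table.patch_index.iloc[0] == small_pool.split_indices("train")[17]

    def test_tie_breaks_to_lowest_index(self):
        # two identical patches: the earlier one must win
        pool = generate_synthetic_pool(
            2, size_range_mm2=(100.0, 100.0), hetero_range=(0.5, 0.5), seed=1,
            validation_fraction=0.0,
        )
        pool.patches[1] = pool.patches[0]
        f = pool.features.copy()
        f.loc[1, ["x_prime", "z_prime"]] = f.loc[0, ["x_prime", "z_prime"]].to_numpy()
        pool.features = f
        cohort = pd.DataFrame(
            {"x": [0.0], "z": [0.0], "t": [0], "y": [0.0], "u1": [0.0], "u2": [0.0]}
        )
        matched = match_images(cohort, pool, split="train")
        assert matched.table.patch_index.iloc[0] == 0

    def test_empty_pool_split_rejected(self, small_pool):
        cohort = sample_cohort(3, seed=0)
        with pytest.raises(ValueError, match="no patches"):
            match_images(cohort, small_pool, split="test")

    def test_matched_features_track_subjects(self):
        pool = generate_synthetic_pool(1500, seed=21)
        cohort = sample_cohort(800, seed=3)
        matched = match_images(cohort, pool, split="train")
        r = np.corrcoef(matched.table.x, matched.table.x_prime_std)[0, 1]
        rz = np.corrcoef(matched.table.z, matched.table.z_prime_std)[0, 1]
        assert r > 0.95
        assert rz > 0.95

    def test_validation_matches_only_validation_pool(self, small_pool):
        cohort = sample_cohort(20, seed=4)
        matched = match_images(cohort, small_pool, split="validation")
        val_idx = set(small_pool.split_indices("validation"))
        assert set(matched.table.patch_index) <= val_idx
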