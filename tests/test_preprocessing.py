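"""Image and lab preprocessing, perturbations, and the stratified split."""

import numpy as np
import pytest
from skimage.transform import resize as sk_resize

from cmapfusion.preprocessing import (
    LabStats,
    fit_lab_stats,
    perturb_image_noise,
    perturb_lab_missing,
    preprocess_image,
    preprocess_lab,
    stratified_indices,
    stratified_split,
)


class TestImagePreprocessing:
    def test_constant_image_standardises_to_zeros(self):
        img = np.full((16, 16, 3), 7.0)
        np.testing.assert_array_equal(preprocess_image(img, (16, 16)), np.zeros((16, 16, 3)))

    def test_eval_mode_zero_mean_unit_variance_per_channel(self, rng):
        img = rng.random((40, 40, 3)) * 255
        out = preprocess_image(img, (32, 32))
        np.testing.assert_allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=(0, 1)), 1.0, atol=1e-10)

    def test_eval_mode_equals_resize_then_zscore(self, rng):
        img = rng.random((64, 64, 3))
        out = preprocess_image(img, (32, 32))
        ref = sk_resize(img, (32, 32, 3), preserve_range=True, anti_aliasing=True)
        ref = (ref - ref.mean(axis=(0, 1))) / ref.std(axis=(0, 1))
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_train_mode_is_deterministic_in_rng_and_still_standardised(self, rng):
        img = rng.random((32, 32, 3))
        a = preprocess_image(img, (32, 32), train_mode=True, rng=np.random.default_rng(5))
        b = preprocess_image(img, (32, 32), train_mode=True, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.mean(axis=(0, 1)), 0.0, atol=1e-10)


class TestLabPreprocessing:
    def test_minmax_endpoints(self):
        stats = LabStats(
            mean=np.array([4.0]), sd=np.array([10.0]), median=np.array([4.0]),
            vmin=np.array([2.0]), vmax=np.array([6.0]),
        )
        out = preprocess_lab(np.array([[2.0], [4.0], [6.0]]), stats)
        np.testing.assert_allclose(out[:, 0], [0.0, 0.5, 1.0])

    def test_missing_values_imputed_with_training_median(self):
        stats = LabStats(
            mean=np.array([2.0]), sd=np.array([100.0]), median=np.array([2.0]),
            vmin=np.array([0.0]), vmax=np.array([4.0]),
        )
        out = preprocess_lab(np.array([[1.0], [np.nan], [3.0]]), stats)
        # [1, 2, 3] before scaling -> [0.25, 0.5, 0.75]
        np.testing.assert_allclose(out[:, 0], [0.25, 0.5, 0.75])

    def test_three_sigma_outliers_marked_then_imputed(self):
        stats = LabStats(
            mean=np.array([0.0]), sd=np.array([1.0]), median=np.array([0.0]),
            vmin=np.array([-1.0]), vmax=np.array([1.0]),
        )
        out = preprocess_lab(np.array([[0.5], [100.0]]), stats)
        np.testing.assert_allclose(out[:, 0], [0.75, 0.5])  # outlier -> median -> 0.5

    def test_linear_interpolation_to_target_length(self):
        stats = LabStats(
            mean=np.array([0.5]), sd=np.array([10.0]), median=np.array([0.5]),
            vmin=np.array([0.0]), vmax=np.array([1.0]),
        )
        out = preprocess_lab(np.array([[0.0], [1.0], [0.0], [1.0]]), stats, t_target=7)
        np.testing.assert_allclose(out[:, 0], [0, 0.5, 1, 0.5, 0, 0.5, 1])

    def test_constant_feature_maps_to_half(self):
        series = np.full((4, 1), 3.3)
        stats = fit_lab_stats([series])
        out = preprocess_lab(series, stats)
        np.testing.assert_array_equal(out, np.full((4, 1), 0.5))

    def test_fit_stats_frozen_from_training_split(self, rng):
        train = [rng.normal(size=(6, 3)) for _ in range(10)]
        stats = fit_lab_stats(train)
        stack = np.concatenate(train)
        np.testing.assert_allclose(stats.mean, stack.mean(axis=0))
        np.testing.assert_allclose(stats.sd, stack.std(axis=0))
        assert np.all(stats.vmin <= stats.median) and np.all(stats.median <= stats.vmax)

    def test_scaling_idempotent_when_already_unit_range(self):
        stats = LabStats(
            mean=np.array([0.5]), sd=np.array([10.0]), median=np.array([0.5]),
            vmin=np.array([0.0]), vmax=np.array([1.0]),
        )
        x = np.array([[0.0], [0.25], [1.0]])
        once = preprocess_lab(x, stats)
        twice = preprocess_lab(once, stats)
        np.testing.assert_array_equal(once, twice)


class TestPerturbations:
    def test_zero_intensity_is_identity(self, rng):
        img = rng.normal(size=(8, 8, 3))
        out = perturb_image_noise(img, 0.0, rng)
        np.testing.assert_array_equal(out, img)
        assert out is not img

    def test_noise_variance_scales_with_intensity(self):
        img = np.zeros((100, 100, 1))
        out = perturb_image_noise(img, 0.4, np.random.default_rng(0), v_max=1.0)
        assert (out - img).var() == pytest.approx(0.4, rel=0.05)

    def test_noise_deterministic_in_rng_state(self, rng):
        img = rng.normal(size=(8, 8, 3))
        a = perturb_image_noise(img, 0.3, np.random.default_rng(9))
        b = perturb_image_noise(img, 0.3, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_intensity_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb_image_noise(np.zeros((2, 2, 1)), 1.5, rng)
        with pytest.raises(ValueError):
            perturb_lab_missing(np.zeros((2, 2)), -0.1, None, rng)

    @pytest.fixture()
    def unit_stats(self):
        return LabStats(
            mean=np.full(8, 0.5), sd=np.full(8, 10.0), median=np.full(8, 0.5),
            vmin=np.zeros(8), vmax=np.ones(8),
        )

    def test_masking_counts_exact(self, unit_stats, rng):
        series = rng.random((10, 8))
        out = perturb_lab_missing(series, 0.25, unit_stats, rng)
        assert (out != series).sum() <= 20  # replaced entries (median may coincide)
        # count selected = round(0.25 * 80) = 20: verify via a median-free series
        series2 = np.full((10, 8), 0.123)
        out2 = perturb_lab_missing(series2, 0.25, unit_stats, np.random.default_rng(0))
        assert (out2 != series2).sum() == 20

    def test_full_mask_gives_training_median_everywhere(self, unit_stats, rng):
        out = perturb_lab_missing(rng.random((5, 8)), 1.0, unit_stats, rng)
        np.testing.assert_allclose(out, 0.5)

    def test_zero_fraction_unchanged(self, unit_stats, rng):
        series = rng.random((5, 8))
        np.testing.assert_array_equal(perturb_lab_missing(series, 0.0, unit_stats, rng), series)


class TestStratifiedSplit:
    def test_balanced_four_class_example(self):
        labels = np.repeat([0, 1, 2, 3], 25)
        tr, va, te = stratified_indices(labels, (0.7, 0.2, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (70, 20, 10)
        for c in range(4):
            assert labels[tr].tolist().count(c) in (17, 18)
            assert labels[va].tolist().count(c) == 5
            assert labels[te].tolist().count(c) in (2, 3)

    def test_single_class_dataset(self):
        tr, va, te = stratified_indices(np.zeros(100, dtype=int), seed=1)
        assert (len(tr), len(va), len(te)) == (70, 20, 10)

    def test_partition_properties_and_determinism(self, rng):
        labels = rng.integers(0, 3, size=83)
        parts1 = stratified_indices(labels, seed=4)
        parts2 = stratified_indices(labels, seed=4)
        allidx = np.concatenate(parts1)
        assert sorted(allidx) == list(range(83))  # disjoint cover
        for a, b in zip(parts1, parts2):
            np.testing.assert_array_equal(a, b)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            stratified_indices(np.zeros(10, dtype=int), (0.5, 0.2, 0.2))

    def test_dataset_split_wrapper(self, small_dataset):
        tr, va, te = stratified_split(small_dataset, seed=0)
        assert len(tr) + len(va) + len(te) == len(small_dataset)
        ids = {s.sample_id for s in tr} | {s.sample_id for s in va} | {s.sample_id for s in te}
        assert len(ids) == len(small_dataset)
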