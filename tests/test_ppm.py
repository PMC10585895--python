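import numpy as np
import pytest
from scipy.stats import spearmanr

from aiwrap import (
    PPMConfig,
    build_performance_dataset,
    predict_performance,
    sample_random_subsets,
    train_ppm,
)
from aiwrap.ppm import PerformanceDataset

from conftest import make_dataset


class TestSampleRandomSubsets:
    def test_default_multiplier_gives_15p(self):
        cfg = PPMConfig()
        masks = sample_random_subsets(50, cfg.k(50), seed=0)
        assert masks.shape == (750, 50)

    def test_every_mask_nonempty(self):
        masks = sample_random_subsets(8, 500, seed=1)
        assert masks.sum(axis=1).min() >= 1

    def test_mean_subset_size_matches_uniform_law(self):
        # size ~ U{1..p} => mean popcount = (p+1)/2
        masks = sample_random_subsets(50, 20000, seed=2)
        assert masks.sum(axis=1).mean() == pytest.approx(25.5, abs=1.0)

    def test_bernoulli_law_nonempty_and_half_full(self):
        masks = sample_random_subsets(20, 5000, seed=3, law="bernoulli")
        assert masks.sum(axis=1).min() >= 1
        assert masks.sum(axis=1).mean() == pytest.approx(10.0, abs=0.5)


class TestPerformanceDataset:
    def test_duplicate_masks_keep_first_performance(self):
        d = PerformanceDataset(p=3)
        mask = np.array([1, 0, 1], dtype=np.uint8)
        assert d.add(mask, 0.5, "initial")
        assert not d.add(mask, 0.9, "wrapper")
        assert len(d) == 1
        assert d.lookup(mask) == 0.5

    def test_best_returns_minimum(self):
        d = PerformanceDataset(p=2)
        d.add(np.array([1, 0]), 0.8)
        d.add(np.array([0, 1]), 0.3)
        mask, c = d.best()
        assert c == 0.3
        assert np.array_equal(mask, [0, 1])

    def test_csv_round_trip(self, tmp_path):
        d = PerformanceDataset(p=3, feature_names=["x1", "x2", "x3"])
        d.add(np.array([1, 1, 0]), 0.4, "initial")
        d.add(np.array([0, 1, 1]), 0.6, "wrapper")
        path = tmp_path / "dperf.csv"
        d.write_csv(path)
        d2 = PerformanceDataset.read_csv(path)
        assert len(d2) == 2
        assert np.array_equal(d2.masks, d.masks)
        assert np.allclose(d2.performances, d.performances)
        assert d2.provenance == ["initial", "wrapper"]

    def test_negative_performance_rejected(self):
        d = PerformanceDataset(p=2)
        with pytest.raises(ValueError):
            d.add(np.array([1, 0]), -0.1)


class TestBuildPerformanceDataset:
    def test_true_subset_beats_noise_subset(self, fast_cv):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 6))
        y = X[:, 0] - X[:, 1]  # noiseless signal in x1, x2
        data = make_dataset(X, y)
        subsets = np.array(
            [[1, 1, 0, 0, 0, 0], [0, 0, 0, 0, 1, 1]], dtype=np.uint8
        )
        dperf = build_performance_dataset(data, subsets, cv=fast_cv)
        c_true, c_noise = dperf.performances
        assert c_true < 0.1
        assert c_noise == pytest.approx(np.std(y), rel=0.25)

    def test_row_per_subset_with_counter(self, interaction_data, fast_cv):
        train, _, _ = interaction_data
        subsets = sample_random_subsets(train.p, 20, seed=4)
        counter = [0]
        dperf = build_performance_dataset(train, subsets, cv=fast_cv, fit_counter=counter)
        assert len(dperf) == len(np.unique(subsets, axis=0))
        assert counter[0] == len(dperf)


class TestPPM:
    def test_constant_performance_gives_constant_predictor(self):
        d = PerformanceDataset(p=4)
        rng = np.random.default_rng(1)
        for mask in sample_random_subsets(4, 12, seed=5):
            d.add(mask, 0.7)
        ppm = train_ppm(d, PPMConfig(n_trees=50))
        preds = predict_performance(ppm, sample_random_subsets(4, 10, seed=6))
        assert np.allclose(preds, 0.7)

    def test_learns_monotone_popcount_signal(self):
        p = 12
        rng = np.random.default_rng(2)
        train_masks = sample_random_subsets(p, 400, seed=7)
        d = PerformanceDataset(p=p)
        for mask in train_masks:
            d.add(mask, mask.sum() / p)
        ppm = train_ppm(d, PPMConfig(n_trees=200, seed=0))
        held = sample_random_subsets(p, 200, seed=8)
        preds = predict_performance(ppm, held)
        rho = spearmanr(preds, held.sum(axis=1) / p).statistic
        assert rho > 0.9

    def test_predictions_within_training_range(self):
        d = PerformanceDataset(p=6)
        rng = np.random.default_rng(3)
        for mask in sample_random_subsets(6, 50, seed=9):
            d.add(mask, float(rng.uniform(0.2, 0.9)))
        ppm = train_ppm(d, PPMConfig(n_trees=100))
        preds = predict_performance(ppm, sample_random_subsets(6, 100, seed=10))
        assert preds.min() >= d.performances.min() - 1e-9
        assert preds.max() <= d.performances.max() + 1e-9

    def test_empty_input_and_dimension_mismatch(self):
        d = PerformanceDataset(p=5)
        for mask in sample_random_subsets(5, 20, seed=11):
            d.add(mask, 0.5)
        ppm = train_ppm(d, PPMConfig(n_trees=20))
        assert predict_performance(ppm, np.zeros((0, 5))).shape == (0,)
        with pytest.raises(ValueError):
            predict_performance(ppm, np.ones((2, 4)))

    def test_prediction_performs_no_model_fits(self, interaction_data, fast_cv):
        train, _, _ = interaction_data
        counter = [0]
        subsets = sample_random_subsets(train.p, 30, seed=12)
        dperf = build_performance_dataset(train, subsets, cv=fast_cv, fit_counter=counter)
        fits_before = counter[0]
        ppm = train_ppm(dperf, PPMConfig(n_trees=50))
        predict_performance(ppm, sample_random_subsets(train.p, 1000, seed=13))
        assert counter[0] == fits_before
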