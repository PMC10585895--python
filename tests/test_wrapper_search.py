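import itertools

import numpy as np
import pytest

from aiwrap import (
    CVConfig,
    GAConfig,
    PPMConfig,
    build_performance_dataset,
    fit_model,
    ga_wrapper_search,
    sample_random_subsets,
    stw_search,
    train_ppm,
    validation_threshold,
)

from conftest import make_dataset


class TestValidationThreshold:
    def test_interpolated_quartile(self):
        assert validation_threshold(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(1.75)

    def test_two_values(self):
        assert validation_threshold(np.array([0.3, 0.5])) == pytest.approx(0.35)

    def test_all_equal(self):
        assert validation_threshold(np.array([0.7, 0.7, 0.7])) == 0.7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            validation_threshold(np.array([]))


@pytest.fixture(scope="module")
def tiny_signal():
    # p=3, noiseless y = x1: the exhaustive-subset oracle puts {x1} first
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 3))
    return make_dataset(X, X[:, 0].copy())


def exhaustive_best_subset(data, cv):
    """Brute-force oracle: CV RMSE of every nonempty subset, fewest features on ties."""
    best, best_c = None, np.inf
    for r in range(1, data.p + 1):
        for combo in itertools.combinations(data.feature_names, r):
            c = fit_model(data.X[list(combo)], data.y, "lasso", cv=cv).cv_performance
            if c < best_c - 1e-9:
                best, best_c = set(combo), c
    return best, best_c


class TestGAWrapperSearch:
    def test_finds_signal_feature_small_problem(self, tiny_signal, fast_cv):
        oracle_best, _ = exhaustive_best_subset(tiny_signal, fast_cv)
        assert "x1" in oracle_best  # sanity of the oracle itself
        subsets = sample_random_subsets(3, 20, seed=1)
        dperf = build_performance_dataset(tiny_signal, subsets, cv=fast_cv)
        ppm = train_ppm(dperf, PPMConfig(n_trees=50))
        res = ga_wrapper_search(
            tiny_signal, dperf, ppm,
            ga=GAConfig(pop_size=8, generations=10, seed=2),
            cv=fast_cv, ppm_config=PPMConfig(n_trees=50),
        )
        assert "x1" in res.q_wrap_labels

    def test_best_true_non_increasing(self, tiny_signal, fast_cv):
        subsets = sample_random_subsets(3, 15, seed=3)
        dperf = build_performance_dataset(tiny_signal, subsets, cv=fast_cv)
        res = ga_wrapper_search(
            tiny_signal, dperf, train_ppm(dperf, PPMConfig(n_trees=50)),
            ga=GAConfig(pop_size=8, generations=8, seed=4),
            cv=fast_cv, ppm_config=PPMConfig(n_trees=50),
        )
        best = res.trace["best_true"].to_numpy()
        assert np.all(np.diff(best) <= 1e-12)
        assert res.best_c_true == pytest.approx(res.dperf.performances.min())

    def test_generation_cap_respected(self, tiny_signal, fast_cv):
        subsets = sample_random_subsets(3, 15, seed=5)
        dperf = build_performance_dataset(tiny_signal, subsets, cv=fast_cv)
        res = ga_wrapper_search(
            tiny_signal, dperf, train_ppm(dperf, PPMConfig(n_trees=50)),
            ga=GAConfig(pop_size=6, generations=5, seed=6),
            cv=fast_cv, ppm_config=PPMConfig(n_trees=50),
        )
        assert len(res.trace) == 5
        assert GAConfig().generations == 100  # paper-scale default cap

    def test_gated_search_requires_seeded_dperf(self, tiny_signal):
        with pytest.raises(ValueError):
            ga_wrapper_search(tiny_signal, None, None, ga=GAConfig(pop_size=4, generations=2))


class TestStwReduction:
    def test_bypass_reproduces_stw_trace(self, tiny_signal, fast_cv):
        ga = GAConfig(pop_size=8, generations=6, seed=7)
        stw = stw_search(tiny_signal, ga=ga, cv=fast_cv)
        bypassed = ga_wrapper_search(
            tiny_signal, None, None, ga=ga, cv=fast_cv, bypass_ppm=True
        )
        assert stw.trace.equals(bypassed.trace)
        assert stw.q_wrap_labels == bypassed.q_wrap_labels
        assert stw.best_c_true == bypassed.best_c_true

    def test_stw_fit_count_is_pop_per_generation(self, tiny_signal, fast_cv):
        ga = GAConfig(pop_size=6, generations=4, seed=8)
        stw = stw_search(tiny_signal, ga=ga, cv=fast_cv)
        assert stw.n_fits_search == 6 * 4
        assert (stw.trace["n_validated"] == 6).all()

    def test_aiwrap_validates_at_most_pop_per_generation(self, tiny_signal, fast_cv):
        subsets = sample_random_subsets(3, 30, seed=9)
        dperf = build_performance_dataset(tiny_signal, subsets, cv=fast_cv)
        ga = GAConfig(pop_size=6, generations=6, seed=10)
        res = ga_wrapper_search(
            tiny_signal, dperf, train_ppm(dperf, PPMConfig(n_trees=50)),
            ga=ga, cv=fast_cv, ppm_config=PPMConfig(n_trees=50),
        )
        assert (res.trace["n_validated"] <= 6).all()
        assert res.n_fits_search <= 6 * 6

    def test_seed_determinism_of_full_trace(self, tiny_signal, fast_cv):
        subsets = sample_random_subsets(3, 20, seed=11)
        ga = GAConfig(pop_size=6, generations=5, seed=12)
        results = []
        for _ in range(2):
            dperf = build_performance_dataset(tiny_signal, subsets, cv=fast_cv)
            ppm = train_ppm(dperf, PPMConfig(n_trees=50, seed=3))
            results.append(
                ga_wrapper_search(tiny_signal, dperf, ppm, ga=ga, cv=fast_cv,
                                  ppm_config=PPMConfig(n_trees=50, seed=3))
            )
        assert results[0].trace.equals(results[1].trace)
        assert results[0].q_wrap_labels == results[1].q_wrap_labels
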