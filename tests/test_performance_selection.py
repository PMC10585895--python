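import itertools

import numpy as np
import pandas as pd
import pytest

from aiwrap import (
    GAConfig,
    fit_final_model,
    fit_model,
    loo_importance,
    r_squared,
    threshold_search,
)
from aiwrap.performance_selection import coefficient_of_variation, importance_table


@pytest.fixture(scope="module")
def strong_weak_data():
    # y driven by x1 only; x2, x3 pure noise
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.standard_normal((60, 3)), columns=["x1", "x2", "x3"])
    y = 2.0 * X["x1"].to_numpy() + rng.normal(0, 0.3, 60)
    return X, y


class TestLooImportance:
    def test_signal_feature_scores_higher_than_noise(self, strong_weak_data, fast_cv):
        X, y = strong_weak_data
        hits = 0
        for seed in range(10):
            records = loo_importance(X, y, B=20, seed=seed, cv=fast_cv)
            by_name = {r.feature: r.score for r in records}
            hits += by_name["x1"] > max(by_name["x2"], by_name["x3"])
        assert hits >= 9  # removing the signal feature destabilizes the fit

    def test_duplicate_columns_score_low_and_equal(self, fast_cv):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(80)
        X = pd.DataFrame({"x1": x, "x2": x})  # perfect redundancy
        y = x + rng.normal(0, 0.2, 80)
        records = loo_importance(X, y, B=25, seed=2, cv=fast_cv)
        scores = [r.score for r in records]
        assert abs(scores[0] - scores[1]) < 0.2
        assert max(scores) < 1.0  # removal of either barely matters

    def test_each_record_carries_B_values(self, strong_weak_data, fast_cv):
        X, y = strong_weak_data
        records = loo_importance(X, y, B=7, seed=3, cv=fast_cv)
        assert all(r.oob_r2.shape == (7,) for r in records)
        table = importance_table(records)
        assert list(table.columns) == ["feature", "mean_r2", "sd_r2", "cv_score"]

    def test_single_feature_rejected(self, fast_cv):
        X = pd.DataFrame({"x1": np.arange(10.0)})
        with pytest.raises(ValueError):
            loo_importance(X, np.arange(10.0), B=5, cv=fast_cv)

    def test_catastrophic_removal_flagged_infinite(self):
        vals = np.array([-0.5, -0.2, -0.4])
        score, degenerate = coefficient_of_variation(vals)
        assert degenerate and np.isinf(score)


class TestThresholdSearch:
    def test_noiseless_signal_keeps_only_x1(self, fast_cv):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((80, 3)), columns=["x1", "x2", "x3"])
        y = X["x1"].to_numpy().copy()
        # independent oracle: best OLS test error over all 7 subsets is {x1}
        records = loo_importance(X, y, B=25, seed=5, cv=fast_cv)
        result = threshold_search(
            records, X, y, ga=GAConfig(pop_size=8, generations=6, seed=6),
            technique="ridge", B_eval=20, seed=7, cv=fast_cv,
        )
        assert result.q_best == ["x1"]
        assert result.c_best == pytest.approx(1.0, abs=0.05)

    def test_tie_breaks_toward_smaller_set(self):
        from aiwrap.performance_selection import prefer

        # clear win beats parsimony; within tolerance the smaller set wins
        assert prefer(0.9, 5, 0.8, 2)
        assert not prefer(0.8, 2, 0.9, 5)
        assert prefer(0.8 + 1e-8, 2, 0.8, 5)
        assert not prefer(0.8, 5, 0.8 + 1e-8, 2)

    def test_all_equal_scores_return_full_set(self, fast_cv):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((50, 2)), columns=["x1", "x2"])
        y = X["x1"].to_numpy() + X["x2"].to_numpy()
        records = loo_importance(X, y, B=10, seed=9, cv=fast_cv)
        for r in records:
            r.score = 0.5  # force one shared score: only the full set is a candidate
        result = threshold_search(
            records, X, y, ga=GAConfig(pop_size=4, generations=3, seed=10),
            B_eval=10, seed=11, cv=fast_cv,
        )
        assert set(result.q_best) == {"x1", "x2"}

    def test_q_best_subset_of_records(self, strong_weak_data, fast_cv):
        X, y = strong_weak_data
        records = loo_importance(X, y, B=15, seed=12, cv=fast_cv)
        result = threshold_search(
            records, X, y, ga=GAConfig(pop_size=6, generations=4, seed=13),
            B_eval=10, seed=14, cv=fast_cv,
        )
        assert set(result.q_best) <= {r.feature for r in records}
        assert len(result.q_best) >= 1


class TestFitFinalModel:
    def test_llr_exact_recovery_on_true_support(self, fast_cv):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.standard_normal((40, 4)), columns=["x1", "x2", "x3", "x4"])
        y = 1.5 * X["x1"].to_numpy() - 0.5 * X["x3"].to_numpy()
        model = fit_final_model(X, y, ["x1", "x3"], variant="LLr", cv=fast_cv)
        assert model.technique == "ols"
        assert model.coefficients["x1"] == pytest.approx(1.5, abs=1e-8)
        assert model.coefficients["x3"] == pytest.approx(-0.5, abs=1e-8)

    def test_llr_refuses_wide_problems(self, fast_cv):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.standard_normal((5, 6)), columns=[f"x{i+1}" for i in range(6)])
        with pytest.raises(ValueError, match="LR"):
            fit_final_model(X, rng.standard_normal(5), list(X.columns), "LLr", cv=fast_cv)

    def test_lr_empty_set_predicts_mean(self, fast_cv):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["x1", "x2"])
        y = rng.normal(3.0, 1.0, 30)
        model = fit_final_model(X, y, [], variant="LR", cv=fast_cv)
        assert np.allclose(model.predict(X), y.mean())
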